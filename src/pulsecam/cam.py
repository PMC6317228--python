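"""Circular cam profile synthesis.

One revolution of the cam encodes one pulse period: the normalized period is
mapped to 360 degrees and the normalized pressure u(theta) to a radial lift
on top of a base circle,

    r(angle) = base_radius + stroke * u(angle / 360).

A knife-edge follower riding the profile therefore reproduces the pulse as a
displacement, which the playback module turns back into pressure.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError, WaveformFormatError
from .fourier import FourierSeries, series_waveform
from .waveform import SampledWaveform, normalize_pulse


@dataclass(frozen=True)
class CamProfile:
    """Polar cam profile on a uniform angle grid over [0, 360)."""

    angles_deg: np.ndarray
    radii_mm: np.ndarray
    base_radius_mm: float
    stroke_mm: float
    source_checksum: str = ""

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        radii = np.asarray(self.radii_mm, dtype=float)
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "radii_mm", radii)
        if angles.size != radii.size or angles.size < 16:
            raise ParameterError("angle and radius grids must match (>= 16 points)")
        if not (self.stroke_mm > 0 and self.base_radius_mm > self.stroke_mm):
            raise ParameterError(
                "need base_radius_mm > stroke_mm > 0 (no self-intersection): "
                f"got base {self.base_radius_mm}, stroke {self.stroke_mm}"
            )
        if np.any(radii <= 0):
            raise ParameterError("cam radii must be positive")

    @property
    def n_points(self) -> int:
        return self.angles_deg.size

    @property
    def lift_mm(self) -> np.ndarray:
        """Follower lift over the angle grid (radius above the base circle)."""
        return self.radii_mm - self.base_radius_mm


def _checksum(values: np.ndarray) -> str:
    return hashlib.sha256(np.round(values, 12).tobytes()).hexdigest()[:16]


def waveform_to_cam(
    source: FourierSeries | SampledWaveform,
    base_radius_mm: float = 20.0,
    stroke_mm: float = 5.0,
    n_points: int = 3600,
    anchor_at_foot: bool = True,
) -> CamProfile:
    """Convert a normalized pulse (or its Fourier series) to a cam profile.

    Angle 0 is anchored at the diastolic foot (waveform minimum), so one
    revolution at constant speed replays the pulse from end-diastole.  A
    non-normalized input is min-max normalized with a warning.
    """
    if not (stroke_mm > 0 and base_radius_mm > stroke_mm):
        raise ParameterError(
            f"need base_radius_mm > stroke_mm > 0, got {base_radius_mm}, {stroke_mm}"
        )
    if isinstance(source, FourierSeries):
        wave = series_waveform(source, n_points)
        checksum = _checksum(source.as_vector())
    else:
        wave = source
        checksum = _checksum(source.values)
    if wave.n != n_points:
        from .waveform import resample  # local import to avoid cycle at top

        wave = resample(wave, n_points)
    values = wave.values
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        u = np.zeros_like(values)
    elif abs(lo) > 1e-9 or abs(hi - 1.0) > 1e-9:
        if wave.units == "normalized":
            u = np.clip(values, 0.0, 1.0)
        else:
            warnings.warn(
                "cam source is not normalized to [0, 1]; min-max normalizing",
                stacklevel=2,
            )
            u = (values - lo) / (hi - lo)
    else:
        u = values
    if anchor_at_foot:
        u = np.roll(u, -int(np.argmin(u)))
    angles = 360.0 * np.arange(n_points) / n_points
    radii = base_radius_mm + stroke_mm * u
    return CamProfile(
        angles_deg=angles,
        radii_mm=radii,
        base_radius_mm=base_radius_mm,
        stroke_mm=stroke_mm,
        source_checksum=checksum,
    )


def cam_to_displacement(
    profile: CamProfile, angle_deg: float | np.ndarray
) -> float | np.ndarray:
    """Knife-edge follower lift (mm) at arbitrary angles.

    Periodic linear interpolation between profile points; the inverse of
    :func:`waveform_to_cam` up to interpolation error.
    """
    scalar = np.isscalar(angle_deg)
    ang = np.mod(np.atleast_1d(np.asarray(angle_deg, dtype=float)), 360.0)
    xp = np.concatenate([profile.angles_deg, [360.0]])
    fp = np.concatenate([profile.lift_mm, [profile.lift_mm[0]]])
    out = np.interp(ang, xp, fp)
    return float(out[0]) if scalar else out


def cam_source_waveform(profile: CamProfile, n_grid: int = 200) -> SampledWaveform:
    """The normalized pulse a cam encodes: lift/stroke over one revolution.

    This is the rotation-locked reference waveform for playback fidelity
    analysis (angle 0 maps to phase 0).
    """
    from .waveform import resample

    u = profile.lift_mm / profile.stroke_mm
    wave = SampledWaveform(
        values=u, dt=1.0 / profile.n_points, units="cam", period=1.0
    )
    return wave if n_grid == profile.n_points else resample(wave, n_grid)


def export_cam(profile: CamProfile, path: str | Path) -> None:
    """Write an (angle_deg, radius_mm) point table for CAM/CNC import.

    Six decimal places (sub-micrometre); a commented header records the
    geometry and the source-series checksum.  Convexity of the profile is
    not guaranteed and must be checked by the machining toolchain.
    """
    path = Path(path)
    lines = [
        "# cam profile point table",
        f"# base_radius_mm: {profile.base_radius_mm:.6f}",
        f"# stroke_mm: {profile.stroke_mm:.6f}",
        f"# n_points: {profile.n_points}",
        f"# source_checksum: {profile.source_checksum}",
        "# convexity_checked: no",
        "angle_deg,radius_mm",
    ]
    for ang, r in zip(profile.angles_deg, profile.radii_mm):
        lines.append(f"{ang:.6f},{r:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_cam(path: str | Path) -> CamProfile:
    """Re-import a cam point table written by :func:`export_cam`."""
    path = Path(path)
    meta: dict[str, str] = {}
    angles, radii = [], []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            continue
        if line.startswith("angle_deg"):
            continue
        try:
            a, r = line.split(",")
            angles.append(float(a))
            radii.append(float(r))
        except ValueError as exc:
            raise WaveformFormatError(f"{path}: bad cam table row {line!r}") from exc
    try:
        base = float(meta["base_radius_mm"])
        stroke = float(meta["stroke_mm"])
    except KeyError as exc:
        raise WaveformFormatError(f"{path}: missing geometry header") from exc
    return CamProfile(
        angles_deg=np.array(angles),
        radii_mm=np.array(radii),
        base_radius_mm=base,
        stroke_mm=stroke,
        source_checksum=meta.get("source_checksum", ""),
    )
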