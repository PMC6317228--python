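"""Core waveform containers and operations.

The universal currency between modules is :class:`SampledWaveform`: one
pressure trace sampled on a uniform abscissa.  A continuous tonometry
record, a single foot-to-foot pulse, and a normalized pulse on the common
analysis grid are all instances; ``units`` distinguishes raw pressure
("mmHg") from dimensionless normalized pulses ("normalized").

Normalization follows the convention used throughout the pipeline: the
period is rescaled to 1 and the amplitude is min-max scaled so the
diastolic foot sits at 0 and the systolic maximum at 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .errors import (
    DegenerateInputError,
    ParameterError,
    SegmentationError,
    WaveformFormatError,
)

#: minimum number of samples for any waveform
MIN_SAMPLES = 16

#: tolerance for "normalized" amplitude checks.  Soft by design: resampling a
#: normalized pulse can miss its exact extremes between grid points, so the
#: span may drift by up to the interpolation error; the exact [0, 1] span is
#: re-established by normalize_pulse / build_ensemble.
NORMALIZED_ATOL = 5e-3


@dataclass(frozen=True)
class SampledWaveform:
    """A uniformly sampled, periodic (or single-record) pressure trace.

    Parameters
    ----------
    values:
        Pressure samples.  For a single pulse the samples cover one period
        on the half-open grid ``k/n * period`` (the sample at phase 1 wraps
        to phase 0).
    dt:
        Uniform sample interval in seconds (``period / n`` for a single
        normalized pulse).
    units:
        ``"mmHg"`` for raw pressure, ``"normalized"`` for dimensionless
        pulses, free text otherwise.
    period:
        Duration of one cycle in seconds; 1.0 for normalized pulses.
        Defaults to the full record duration ``n * dt``.
    """

    values: np.ndarray
    dt: float
    units: str = "mmHg"
    period: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < MIN_SAMPLES:
            raise ParameterError(
                f"waveform needs at least {MIN_SAMPLES} samples, got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise WaveformFormatError("waveform contains non-finite samples")
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ParameterError(f"sample interval must be positive, got {self.dt}")
        if self.period is None:
            object.__setattr__(self, "period", values.size * self.dt)
        if self.units == "normalized":
            lo, hi = values.min(), values.max()
            if abs(lo) > NORMALIZED_ATOL or abs(hi - 1.0) > NORMALIZED_ATOL:
                raise WaveformFormatError(
                    f"normalized waveform must span [0, 1], spans [{lo:g}, {hi:g}]"
                )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) * self.dt

    @property
    def phases(self) -> np.ndarray:
        """Normalized phase of each sample on [0, 1) of one period."""
        return np.arange(self.n) / self.n

    @property
    def amplitude(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass(frozen=True)
class PulseEnsemble:
    """A set of normalized pulses resampled to one common grid."""

    pulses: tuple[SampledWaveform, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple(self.pulses))
        if len(self.pulses) < 2:
            raise ParameterError("an ensemble needs at least 2 pulses")
        n0 = self.pulses[0].n
        for i, p in enumerate(self.pulses):
            if p.n != n0:
                raise ParameterError(
                    f"pulse {i} has {p.n} samples, expected common grid of {n0}"
                )
            if p.units != "normalized":
                raise ParameterError(f"pulse {i} is not normalized")

    def __len__(self) -> int:
        return len(self.pulses)

    @property
    def n_grid(self) -> int:
        return self.pulses[0].n

    @property
    def matrix(self) -> np.ndarray:
        """(n_pulses, n_grid) array of sample values."""
        return np.stack([p.values for p in self.pulses])

    @property
    def phases(self) -> np.ndarray:
        return self.pulses[0].phases


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_waveform(
    path: str | Path,
    time_col: int = 0,
    value_col: int = 1,
    units: str = "mmHg",
) -> SampledWaveform:
    """Read a two-column (time, pressure) delimited text file.

    Comma or tab/whitespace delimited; an optional single header line and
    ``#`` comment lines are tolerated.  The time column must be strictly
    increasing with uniform spacing (relative tolerance 1e-9).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep=None, engine="python", comment="#", header=None,
            skip_blank_lines=True,
        )
    except (OSError, pd.errors.ParserError) as exc:
        raise WaveformFormatError(f"cannot parse {path}: {exc}") from exc
    # drop a single header line of non-numeric labels, if present
    first = pd.to_numeric(frame.iloc[0], errors="coerce")
    if first.isna().any():
        frame = frame.iloc[1:].reset_index(drop=True)
    if frame.shape[1] < 2:
        raise WaveformFormatError(f"{path}: need at least 2 columns, got {frame.shape[1]}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.iloc[:, [time_col, value_col]].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise WaveformFormatError(f"{path}: non-numeric value in data row {line}")
    t = numeric.iloc[:, time_col].to_numpy(float)
    v = numeric.iloc[:, value_col].to_numpy(float)
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise WaveformFormatError(f"{path}: non-monotone abscissa")
    dt = float(np.mean(steps))
    if np.max(np.abs(steps - dt)) > 1e-9 * max(abs(dt), 1.0):
        raise WaveformFormatError(f"{path}: non-uniform sampling beyond tolerance")
    return SampledWaveform(values=v, dt=dt, units=units)


def write_waveform(wave: SampledWaveform, path: str | Path) -> None:
    """Write comma-separated (time_s, pressure) with 9 significant digits."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("time_s,pressure\n")
    for t, v in zip(wave.times, wave.values):
        buf.write(f"{t:.9g},{v:.9g}\n")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters for foot-to-foot pulse segmentation.

    The diastolic foot is located as the minimum between consecutive
    systolic upstrokes, where upstrokes are the dominant positive peaks of
    the smoothed first difference.
    """

    min_period_s: float = 0.3
    #: moving-average smoothing width, as a fraction of the estimated period
    smooth_frac: float = 0.05
    #: an upstroke must reach this fraction of the largest positive slope
    upstroke_frac: float = 0.5


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    kernel = np.ones(width) / width
    # reflect-pad so the smoothed record keeps its length and edges
    pad = width // 2
    padded = np.pad(values, pad, mode="reflect")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + values.size]
    return out


def segment_pulses(
    record: SampledWaveform, config: SegmentationConfig | None = None
) -> list[SampledWaveform]:
    """Split a continuous record into consecutive foot-to-foot pulses.

    Each returned pulse runs from one diastolic minimum (just before the
    systolic upstroke) to the next.  Partial pulses at the record edges are
    dropped.
    """
    config = config or SegmentationConfig()
    v = record.values
    if record.amplitude <= 0:
        raise SegmentationError("constant record: no pulse feet detectable")
    min_dist = max(int(round(config.min_period_s / record.dt)), 2)
    smooth_w = max(int(round(config.smooth_frac * min_dist)), 1)
    smoothed = _moving_average(v, smooth_w)
    slope = np.diff(smoothed)
    top = slope.max()
    if top <= 0:
        raise SegmentationError("record has no rising edge")
    peaks, _ = signal.find_peaks(
        slope, height=config.upstroke_frac * top, distance=min_dist
    )
    if peaks.size < 2:
        raise SegmentationError(
            f"fewer than 2 systolic upstrokes found ({peaks.size})"
        )
    # foot = minimum of the raw record between consecutive upstrokes,
    # which lands just before the later upstroke
    feet = [int(np.argmin(v[a:b])) + a for a, b in zip(peaks[:-1], peaks[1:])]
    amp = record.amplitude
    foot_level = float(np.median(v[feet]))
    # leading foot: accepted only if the record genuinely descends into it
    # (a record starting mid-upstroke has no complete leading pulse)
    if peaks[0] > 0:
        lead = int(np.argmin(v[: peaks[0] + 1]))
        if v[:lead + 1].max() - v[lead] >= 0.25 * amp:
            feet.insert(0, lead)
    # trailing foot: accepted only if the record decays back to foot level
    # after the last upstroke
    trail = int(np.argmin(v[peaks[-1]:])) + int(peaks[-1])
    if trail > feet[-1] and v[trail] <= foot_level + 0.05 * amp:
        feet.append(trail)
    feet = sorted(set(feet))
    if len(feet) < 2:
        raise SegmentationError("fewer than 2 pulse feet detected")
    pulses = []
    for a, b in zip(feet[:-1], feet[1:]):
        if b - a < MIN_SAMPLES:
            continue
        pulses.append(
            SampledWaveform(
                values=v[a:b].copy(), dt=record.dt, units=record.units,
                period=(b - a) * record.dt,
            )
        )
    if not pulses:
        raise SegmentationError("no complete pulse between detected feet")
    return pulses


# ---------------------------------------------------------------------------
# normalization / resampling / averaging
# ---------------------------------------------------------------------------

def normalize_pulse(pulse: SampledWaveform) -> SampledWaveform:
    """Min-max normalize one pulse: period 1, foot at 0, maximum at 1."""
    amp = pulse.amplitude
    if amp <= 0:
        raise DegenerateInputError("cannot normalize a constant pulse")
    scaled = (pulse.values - pulse.values.min()) / amp
    return SampledWaveform(
        values=scaled, dt=1.0 / pulse.n, units="normalized", period=1.0
    )


def resample(pulse: SampledWaveform, n: int, kind: str = "cubic") -> SampledWaveform:
    """Resample one period to ``n`` uniform samples by periodic interpolation.

    The sample at phase 1 wraps to phase 0.  The default periodic cubic
    spline keeps interpolation error fourth-order in the grid spacing;
    ``kind="linear"`` switches to monotone, overshoot-free linear
    interpolation for signals with very sharp upstrokes.
    """
    if n < MIN_SAMPLES:
        raise ParameterError(f"resample target must be >= {MIN_SAMPLES}, got {n}")
    # append the wrap-around point so interpolation covers [0, 1]
    xp = np.concatenate([pulse.phases, [1.0]])
    fp = np.concatenate([pulse.values, [pulse.values[0]]])
    new_phase = np.arange(n) / n
    if kind == "linear":
        out = np.interp(new_phase, xp, fp)
    elif kind == "cubic":
        out = interpolate.CubicSpline(xp, fp, bc_type="periodic")(new_phase)
    else:
        raise ParameterError(f"unknown interpolation kind {kind!r}")
    return SampledWaveform(
        values=out, dt=pulse.period / n, units=pulse.units, period=pulse.period
    )


def build_ensemble(
    pulses: Sequence[SampledWaveform],
    n_grid: int = 200,
    source_label: str = "",
) -> PulseEnsemble:
    """Normalize raw pulses and resample them onto a common grid.

    The min-max normalization is re-applied after resampling so the ensemble
    members satisfy the normalized-amplitude invariant exactly.
    """
    prepared = [
        normalize_pulse(resample(normalize_pulse(p), n_grid)) for p in pulses
    ]
    return PulseEnsemble(pulses=tuple(prepared), source_label=source_label)


def ensemble_mean(ensemble: PulseEnsemble) -> SampledWaveform:
    """Pointwise arithmetic mean across the ensemble on the common grid."""
    mean = ensemble.matrix.mean(axis=0)
    return SampledWaveform(
        values=mean, dt=1.0 / ensemble.n_grid, units="mean", period=1.0
    )
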