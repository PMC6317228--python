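"""Truncated Fourier series: the canonical form of a representative pulse.

A pulse with normalized period 1 is represented as

    u(theta) = a0 + sum_{k=1..n} [a_k cos(2 pi k theta) + b_k sin(2 pi k theta)]

with ``theta`` the normalized phase on [0, 1).  Ten harmonics reproduce the
three-peak radial morphology; the packaged reference coefficients are the
published fit to a healthy young adult's ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .waveform import SampledWaveform


@dataclass(frozen=True)
class FourierSeries:
    """Coefficients of a truncated real Fourier series with period 1."""

    a0: float
    a: np.ndarray
    b: np.ndarray
    period: float = 1.0

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.size != b.size or a.size < 1:
            raise ParameterError(
                f"cosine/sine coefficient lengths must match and be >= 1 "
                f"(got {a.size}, {b.size})"
            )
        if not (np.isfinite(self.a0) and np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ParameterError("non-finite Fourier coefficient")

    @property
    def n(self) -> int:
        """Number of harmonics."""
        return self.a.size

    def as_vector(self) -> np.ndarray:
        """Flatten to the optimization vector [a0, a_1..a_n, b_1..b_n]."""
        return np.concatenate([[self.a0], self.a, self.b])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "FourierSeries":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 2 == 0 or vec.size < 3:
            raise ParameterError(
                f"coefficient vector must have odd length 2n+1 >= 3, got {vec.size}"
            )
        n = (vec.size - 1) // 2
        return cls(a0=float(vec[0]), a=vec[1 : n + 1], b=vec[n + 1 :])


def design_matrix(n_harmonics: int, phases: np.ndarray) -> np.ndarray:
    """Basis matrix B with columns [1, cos(2pi k th), sin(2pi k th)] so that
    ``B @ series.as_vector()`` evaluates the series at ``phases``."""
    phases = np.asarray(phases, dtype=float)
    k = np.arange(1, n_harmonics + 1)
    ang = 2.0 * np.pi * np.outer(phases, k)
    return np.hstack([np.ones((phases.size, 1)), np.cos(ang), np.sin(ang)])


def evaluate_series(series: FourierSeries, phases: np.ndarray | float) -> np.ndarray:
    """Evaluate the series at normalized phases; out-of-range phases wrap."""
    scalar = np.isscalar(phases)
    ph = np.mod(np.atleast_1d(np.asarray(phases, dtype=float)), 1.0)
    out = design_matrix(series.n, ph) @ series.as_vector()
    return float(out[0]) if scalar else out


def series_waveform(
    series: FourierSeries, n: int = 200, units: str = "series"
) -> SampledWaveform:
    """Sample one period of the series on the uniform half-open grid."""
    phases = np.arange(n) / n
    return SampledWaveform(
        values=evaluate_series(series, phases), dt=1.0 / n, units=units, period=1.0
    )


def project_to_series(waveform: SampledWaveform, n_harmonics: int) -> FourierSeries:
    """Least-squares projection of a uniformly sampled period onto the
    ``n_harmonics``-term basis.

    On a uniform periodic grid of m >= 2n+1 samples the basis is orthogonal,
    so the projection coefficients are the discrete Fourier coefficients.
    """
    m = waveform.n
    if m < 2 * n_harmonics + 1:
        raise ParameterError(
            f"need at least {2 * n_harmonics + 1} samples for {n_harmonics} "
            f"harmonics, got {m}"
        )
    spec = np.fft.rfft(waveform.values)
    a0 = float(spec[0].real) / m
    a = 2.0 * spec[1 : n_harmonics + 1].real / m
    b = -2.0 * spec[1 : n_harmonics + 1].imag / m
    return FourierSeries(a0=a0, a=a, b=b)


# ---------------------------------------------------------------------------
# packaged reference coefficients + series file I/O
# ---------------------------------------------------------------------------

def load_reference_series() -> FourierSeries:
    """The packaged 10-harmonic representative radial pulse coefficients."""
    text = resources.files("pulsecam.data").joinpath(
        "representative_series.json"
    ).read_text()
    doc = json.loads(text)
    return FourierSeries(a0=doc["a0"], a=np.array(doc["a"]), b=np.array(doc["b"]))


def write_series(series: FourierSeries, path: str | Path) -> None:
    """Write coefficients as a small structured text file (JSON)."""
    doc = {"n": series.n, "a0": series.a0,
           "a": series.a.tolist(), "b": series.b.tolist()}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_series(path: str | Path) -> FourierSeries:
    doc = json.loads(Path(path).read_text())
    return FourierSeries(a0=doc["a0"], a=np.array(doc["a"]), b=np.array(doc["b"]))
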