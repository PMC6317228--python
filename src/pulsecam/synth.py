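"""Ground-truth-known synthetic pulse data.

Emulates the steady-state region of a radial tonometry record: an ensemble
of ~40 consecutive three-peak pulses (percussion peak, late-systolic peak,
dicrotic wave) with per-pulse amplitude/period jitter, a per-pulse
perturbation of the late-systolic peak (so the ensemble has genuine AI
dispersion), and additive measurement noise.  Every draw is logged, so each
pipeline stage can be tested against the generator's own record of what it
produced.

Two base morphologies are available:

* ``"reference"`` -- the packaged 10-harmonic representative radial series.
* ``"gaussians"`` -- a sum of three periodic Gaussian bumps with fully
  controllable peak phases/heights/widths (exact closed-form ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .augmentation import PeakConfig, radial_ai
from .errors import ParameterError
from .fourier import FourierSeries, evaluate_series, load_reference_series, series_waveform
from .waveform import PulseEnsemble, SampledWaveform, build_ensemble, normalize_pulse, resample


@dataclass(frozen=True)
class GaussianPulseParams:
    """Three periodic Gaussian bumps: percussion, late-systolic, dicrotic."""

    phases: tuple[float, ...] = (0.15, 0.35, 0.60)
    heights: tuple[float, ...] = (1.0, 0.695, 0.30)
    widths: tuple[float, ...] = (0.05, 0.05, 0.07)

    def __post_init__(self) -> None:
        if not (len(self.phases) == len(self.heights) == len(self.widths)):
            raise ParameterError("phases/heights/widths must have equal length")
        if any(not (0.0 <= p < 1.0) for p in self.phases):
            raise ParameterError("Gaussian peak phases must lie in [0, 1)")
        if any(w <= 0 for w in self.widths):
            raise ParameterError("Gaussian widths must be positive")


def _gaussian_bumps(phases: np.ndarray, params: GaussianPulseParams) -> np.ndarray:
    """Periodic sum of Gaussians (images at +-1 keep the pulse periodic)."""
    out = np.zeros_like(phases)
    for p, h, w in zip(params.phases, params.heights, params.widths):
        for image in (-1.0, 0.0, 1.0):
            out += h * np.exp(-0.5 * ((phases - p - image) / w) ** 2)
    return out


@dataclass(frozen=True)
class EnsembleSpec:
    """Study conditions for one synthetic steady-state ensemble.

    Defaults mirror the target acquisition: 40 pulses around the reference
    morphology with mild physiological jitter (2% amplitude, 3% period and
    3% late-peak dispersion) and small additive sensor noise (sd 0.01 in
    normalized units).
    """

    n_pulses: int = 40
    kind: str = "reference"  # "reference" | "gaussians"
    gaussian_params: GaussianPulseParams = field(default_factory=GaussianPulseParams)
    amplitude_jitter_pct: float = 2.0
    period_jitter_pct: float = 3.0
    ai_jitter_pct: float = 3.0
    noise_sd: float = 0.01
    n_grid: int = 200
    base_period_s: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pulses < 2:
            raise ParameterError("n_pulses must be >= 2")
        for name in ("amplitude_jitter_pct", "period_jitter_pct", "ai_jitter_pct",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.kind not in ("reference", "gaussians"):
            raise ParameterError(f"unknown base pulse kind {self.kind!r}")


@dataclass(frozen=True)
class GroundTruthLog:
    """What the generator actually drew, pulse by pulse."""

    base_ai: float
    #: AI of each emitted pulse (noiseless construction), via radial_ai
    intended_ai: np.ndarray
    #: AI of each emitted pulse as measured on the final (noisy) pulse
    measured_ai: np.ndarray
    amplitude_scales: np.ndarray
    ai_scales: np.ndarray
    periods_s: np.ndarray

    @property
    def mean_ai(self) -> float:
        """Ensemble mean AI of the emitted pulses (the target RI)."""
        return float(self.measured_ai.mean())


def _series_foot_phase(series: FourierSeries, dense_n: int = 4000) -> float:
    """Phase of the diastolic foot (global minimum) of a series waveform."""
    phases = np.arange(dense_n) / dense_n
    return float(phases[np.argmin(evaluate_series(series, phases))])


def make_base_pulse(
    kind: str = "reference",
    params: GaussianPulseParams | None = None,
    n_grid: int = 200,
) -> SampledWaveform:
    """Build the noiseless, normalized, foot-anchored base pulse.

    The reference series is phase-rolled so its diastolic foot sits at
    phase 0, matching what foot-to-foot segmentation of a real record
    produces; Gaussian pulses are foot-anchored by construction.
    """
    phases = np.arange(n_grid) / n_grid
    if kind == "reference":
        series = load_reference_series()
        values = evaluate_series(series, phases + _series_foot_phase(series))
    elif kind == "gaussians":
        values = _gaussian_bumps(phases, params or GaussianPulseParams())
    else:
        raise ParameterError(f"unknown base pulse kind {kind!r}")
    raw = SampledWaveform(values=values, dt=1.0 / n_grid, units="raw", period=1.0)
    return normalize_pulse(raw)


# ---------------------------------------------------------------------------
# late-peak (AI) perturbation
# ---------------------------------------------------------------------------

#: width (in phase) of the envelope that scales the late-systolic peak of
#: reference-kind pulses; narrow enough to leave the percussion peak and
#: dicrotic wave untouched
_LATE_ENVELOPE_WIDTH = 0.05


def _perturbed_values(
    spec: EnsembleSpec, phases: np.ndarray, ai_scale: float,
    series: FourierSeries | None, foot_phase: float, late_phase: float,
) -> np.ndarray:
    """One noiseless foot-anchored pulse, late peak scaled by ``ai_scale``.

    For the reference morphology the late-systolic peak is scaled by a
    localized multiplicative Gaussian envelope centered on it, which shifts
    AI by the requested relative amount while leaving the percussion peak
    and the dicrotic wave essentially unchanged.
    """
    if spec.kind == "gaussians":
        p = spec.gaussian_params
        heights = list(p.heights)
        heights[1] = heights[1] * ai_scale
        return _gaussian_bumps(phases, replace(p, heights=tuple(heights)))
    values = evaluate_series(series, phases + foot_phase)
    floor = values.min()
    envelope = np.zeros_like(phases)
    for image in (-1.0, 0.0, 1.0):
        envelope += np.exp(
            -0.5 * ((phases - late_phase - image) / _LATE_ENVELOPE_WIDTH) ** 2
        )
    return floor + (values - floor) * (1.0 + (ai_scale - 1.0) * envelope)


def generate_ensemble(spec: EnsembleSpec) -> tuple[PulseEnsemble, GroundTruthLog]:
    """Draw one steady-state pulse ensemble plus its ground-truth log.

    Per pulse: amplitude scale ~ N(1, amp_jitter), late-peak (AI) scale
    ~ N(1, ai_jitter), additive N(0, noise_sd) noise, then min-max
    renormalization onto the common grid.  Seed-deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    phases = np.arange(spec.n_grid) / spec.n_grid
    base = make_base_pulse(spec.kind, spec.gaussian_params, spec.n_grid)
    base_ai = radial_ai(base).ai_percent

    series = load_reference_series() if spec.kind == "reference" else None
    foot_phase = _series_foot_phase(series) if series is not None else 0.0
    late_phase = radial_ai(base).late_peak_phase

    amp_scales = rng.normal(1.0, spec.amplitude_jitter_pct / 100.0, spec.n_pulses)
    ai_scales = rng.normal(1.0, spec.ai_jitter_pct / 100.0, spec.n_pulses)
    periods = spec.base_period_s * rng.normal(
        1.0, spec.period_jitter_pct / 100.0, spec.n_pulses
    )

    pulses, intended, measured = [], [], []
    for amp_s, ai_s in zip(amp_scales, ai_scales):
        clean = _perturbed_values(spec, phases, ai_s, series, foot_phase, late_phase)
        clean_pulse = normalize_pulse(
            SampledWaveform(values=clean, dt=1.0 / spec.n_grid, units="raw", period=1.0)
        )
        intended.append(radial_ai(clean_pulse).ai_percent)
        noisy = clean_pulse.values * amp_s + rng.normal(0.0, spec.noise_sd, spec.n_grid)
        pulse = normalize_pulse(
            SampledWaveform(values=noisy, dt=1.0 / spec.n_grid, units="raw", period=1.0)
        )
        measured.append(radial_ai(pulse).ai_percent)
        pulses.append(pulse)

    log = GroundTruthLog(
        base_ai=base_ai,
        intended_ai=np.array(intended),
        measured_ai=np.array(measured),
        amplitude_scales=amp_scales,
        ai_scales=ai_scales,
        periods_s=periods,
    )
    label = f"synthetic:{spec.kind}:seed={spec.seed}"
    return PulseEnsemble(pulses=tuple(pulses), source_label=label), log


def generate_continuous_record(
    spec: EnsembleSpec,
    include_ramp: bool = False,
    sample_rate_hz: float = 500.0,
    ramp_pulses: int = 5,
) -> tuple[SampledWaveform, GroundTruthLog]:
    """Concatenate the ensemble's pulses in time for segmentation tests.

    Period jitter stretches each pulse to its drawn period (rounded to the
    sample grid; the log records the realized periods).  With
    ``include_ramp`` a linearly growing run of extra pulses precedes the
    steady state, emulating the sensor pressurization phase.
    """
    ensemble, log = generate_ensemble(spec)
    segments = []
    realized = []
    for pulse, period in zip(ensemble.pulses, log.periods_s):
        n_samp = max(int(round(period * sample_rate_hz)), 16)
        stretched = resample(pulse, n_samp)
        segments.append(stretched.values)
        realized.append(n_samp / sample_rate_hz)
    if include_ramp:
        ramp = []
        base = ensemble.pulses[0]
        n_samp = max(int(round(spec.base_period_s * sample_rate_hz)), 16)
        tile = resample(base, n_samp).values
        for j in range(ramp_pulses):
            ramp.append(tile * (0.15 + 0.85 * j / ramp_pulses))
        segments = ramp + segments
    record = SampledWaveform(
        values=np.concatenate(segments),
        dt=1.0 / sample_rate_hz,
        units="normalized-record",
    )
    log = replace(log, periods_s=np.array(realized))
    return record, log
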