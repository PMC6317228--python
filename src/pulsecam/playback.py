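"""Software playback of a cam profile — a surrogate of the physical rig.

The cam spins at the commanded heart rate (one revolution per pulse) and the
follower lift is mapped affinely onto a pressure waveform with the commanded
pulse pressure and diastolic offset:

    p0(t) = diastolic + pulse_pressure * lift(theta(t)) / stroke,
    theta(t) = 360 * (heart_rate / 60) * t  (mod 360).

An optional first-order lag y' = (p0 - y) / tau stands in for the pneumatic
transmission path: air is compressible, so the real rig's upstroke is less
steep than the cam's, which shows up as a positive phase delay.  The lag is
a deliberately minimal surrogate (no cylinder volume, tube impedance or
vessel compliance is modeled) and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cam import CamProfile, cam_to_displacement
from .errors import ParameterError
from .waveform import PulseEnsemble, SampledWaveform, build_ensemble, segment_pulses, SegmentationConfig


@dataclass(frozen=True)
class PlaybackConfig:
    """Commanded operating point of the simulated rig."""

    heart_rate_bpm: float = 60.0
    pulse_pressure_mmHg: float = 50.0
    diastolic_mmHg: float = 80.0
    #: first-order pneumatic lag time constant; 0 disables
    lag_tau_s: float = 0.0
    sample_rate_hz: float = 500.0
    duration_s: float = 10.0
    #: additive Gaussian sensor noise (off by default)
    noise_sd_mmHg: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise ParameterError("heart_rate_bpm must be positive")
        if self.pulse_pressure_mmHg <= 0:
            raise ParameterError("pulse_pressure_mmHg must be positive")
        if self.lag_tau_s < 0:
            raise ParameterError("lag_tau_s must be >= 0")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ParameterError("duration and sample rate must be positive")


def _first_order_lag(p0: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exact discrete solution of y' = (p0 - y)/tau for piecewise-linear p0."""
    decay = np.exp(-dt / tau)
    # response to a linear ramp within one step: p(t) = p_k + m t
    ramp = tau / dt * (1.0 - decay)
    y = np.empty_like(p0)
    y[0] = p0[0]
    for k in range(p0.size - 1):
        m = p0[k + 1] - p0[k]
        y[k + 1] = decay * y[k] + (1.0 - decay) * p0[k] + m * (1.0 - ramp)
    return y


def simulate_pressure(profile: CamProfile, config: PlaybackConfig) -> SampledWaveform:
    """Rotate the cam and emit the resulting pressure record.

    The realized period is exactly ``60 / heart_rate_bpm`` seconds (rotation
    is kinematic); with ``lag_tau_s = 0`` the realized pulse pressure and
    diastolic level equal the commanded ones exactly.
    """
    period = 60.0 / config.heart_rate_bpm
    if config.sample_rate_hz * period < 50:
        raise ParameterError(
            f"sample rate {config.sample_rate_hz} Hz gives fewer than 50 "
            f"samples per {period:.3f} s pulse"
        )
    n = int(round(config.duration_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    theta = np.mod(360.0 * t / period, 360.0)
    lift = np.asarray(cam_to_displacement(profile, theta))
    p0 = (
        config.diastolic_mmHg
        + config.pulse_pressure_mmHg * lift / profile.stroke_mm
    )
    if config.lag_tau_s > 0:
        out = _first_order_lag(p0, 1.0 / config.sample_rate_hz, config.lag_tau_s)
    else:
        out = p0
    if config.noise_sd_mmHg > 0:
        rng = np.random.default_rng(config.seed)
        out = out + rng.normal(0.0, config.noise_sd_mmHg, out.size)
    return SampledWaveform(
        values=out, dt=1.0 / config.sample_rate_hz, units="mmHg", period=period
    )


def rotation_cycle(
    record: SampledWaveform, index: int = 2, n_grid: int = 200
) -> SampledWaveform:
    """One rotation-locked cycle of a playback record.

    Slices cycle ``index`` at the exact kinematic period boundaries (phase 0
    = cam angle 0) without re-anchoring, so transmission phase lag between
    the cam source and the output is preserved.  Foot-to-foot segmentation,
    by contrast, re-anchors every pulse at its own minimum and would absorb
    a pure delay.
    """
    period = record.period
    start = index * period
    if (index + 1) * period > record.duration + 1e-9:
        raise ParameterError(
            f"record of {record.duration:.3f} s has no complete cycle {index}"
        )
    tq = start + period * np.arange(n_grid) / n_grid
    vals = np.interp(tq, record.times, record.values)
    return SampledWaveform(
        values=vals, dt=period / n_grid, units=record.units, period=period
    )


def steady_state_extract(
    record: SampledWaveform,
    n_pulses: int,
    n_grid: int = 200,
    segmentation: SegmentationConfig | None = None,
) -> PulseEnsemble:
    """Extract the steady-state pulse ensemble from a playback record.

    Discards the leading transient (the first two segmented pulses, which
    carry the lag filter's settling and the partial first revolution) and
    returns the next ``n_pulses`` pulses normalized onto the common grid.
    """
    if n_pulses < 2:
        raise ParameterError("n_pulses must be >= 2")
    pulses = segment_pulses(record, segmentation)
    if len(pulses) < n_pulses + 2:
        raise ParameterError(
            f"record holds {len(pulses)} complete pulses; need "
            f"{n_pulses} + 2 transient"
        )
    kept = pulses[2 : 2 + n_pulses]
    return PulseEnsemble(
        pulses=tuple(
            build_ensemble(kept, n_grid=n_grid, source_label="playback").pulses
        ),
        source_label="playback",
    )
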