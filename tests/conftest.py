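import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pulsecam import (  # noqa: E402
    EnsembleSpec,
    GaussianPulseParams,
    SampledWaveform,
    generate_ensemble,
    load_reference_series,
    make_base_pulse,
    series_waveform,
)


@pytest.fixture(scope="session")
def reference_series():
    return load_reference_series()


@pytest.fixture(scope="session")
def reference_dense(reference_series):
    """The reference series sampled on a dense 2000-point grid (raw scale)."""
    return series_waveform(reference_series, 2000)


@pytest.fixture(scope="session")
def gaussian_base():
    """Foot-anchored three-bump pulse with exactly known construction."""
    return make_base_pulse("gaussians")


@pytest.fixture(scope="session")
def default_ensemble():
    """The default 40-pulse reference-morphology ensemble, seed 7."""
    return generate_ensemble(EnsembleSpec(seed=7))


def two_gaussian_pulse(
    heights=(1.0, 0.733), phases=(0.15, 0.35), width=0.05, n=400
):
    """A clean two-peak pulse (no dicrotic wave) with known peak geometry."""
    th = np.arange(n) / n
    v = np.zeros(n)
    for p, h in zip(phases, heights):
        for image in (-1.0, 0.0, 1.0):
            v += h * np.exp(-0.5 * ((th - p - image) / width) ** 2)
    return SampledWaveform(values=v, dt=1.0 / n, units="raw", period=1.0)
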