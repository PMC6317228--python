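"""Waveform I/O, segmentation, normalization, resampling, averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsecam import (
    DegenerateInputError,
    EnsembleSpec,
    SampledWaveform,
    SegmentationError,
    WaveformFormatError,
    build_ensemble,
    ensemble_mean,
    generate_continuous_record,
    normalize_pulse,
    read_waveform,
    resample,
    segment_pulses,
    write_waveform,
)
from pulsecam.errors import ParameterError

from conftest import two_gaussian_pulse


class TestReadWrite:
    def test_parses_simple_csv(self, tmp_path):
        f = tmp_path / "w.csv"
        rows = "\n".join(f"{0.01 * i},{10 + (i % 7)}" for i in range(20))
        f.write_text(rows + "\n")
        w = read_waveform(f)
        assert w.n == 20
        assert w.dt == pytest.approx(0.01)

    def test_header_line_tolerated(self, tmp_path):
        f = tmp_path / "w.csv"
        rows = "\n".join(f"{0.01 * i},{float(i)}" for i in range(20))
        f.write_text("time_s,pressure\n" + rows + "\n")
        assert read_waveform(f).n == 20

    def test_non_monotone_abscissa_rejected(self, tmp_path):
        f = tmp_path / "w.csv"
        t = list(np.arange(20) * 0.01)
        t[5], t[6] = t[6], t[5]
        f.write_text("\n".join(f"{ti},{i}" for i, ti in enumerate(t)))
        with pytest.raises(WaveformFormatError, match="non-monotone"):
            read_waveform(f)

    def test_non_numeric_row_named(self, tmp_path):
        f = tmp_path / "w.csv"
        rows = [f"{0.01 * i},{float(i)}" for i in range(20)]
        rows[7] = "0.07,oops"
        f.write_text("\n".join(rows))
        with pytest.raises(WaveformFormatError, match="row 8"):
            read_waveform(f)

    def test_round_trip_lossless(self, tmp_path, gaussian_base):
        f = tmp_path / "rt.csv"
        write_waveform(gaussian_base, f)
        back = read_waveform(f)
        np.testing.assert_allclose(back.values, gaussian_base.values, atol=1e-12)
        assert back.dt == pytest.approx(gaussian_base.dt, rel=1e-12)


class TestSegmentation:
    def test_tiled_pulse_recovers_period(self, gaussian_base):
        tile = gaussian_base.values
        record = SampledWaveform(
            values=np.tile(tile, 5), dt=1.0 / 200, units="raw"
        )
        pulses = segment_pulses(record)
        assert len(pulses) in (4, 5)
        for p in pulses:
            assert abs(p.n - 200) <= 1

    def test_constant_record_fails(self):
        rec = SampledWaveform(values=np.full(1000, 5.0), dt=0.01, units="raw")
        with pytest.raises(SegmentationError):
            segment_pulses(rec)

    def test_jittered_periods_match_generator_log(self):
        # noiseless: additive noise moves the argmin within the flat
        # diastolic foot region by a few samples, which is a property of
        # the signal, not of the segmenter
        spec = EnsembleSpec(
            n_pulses=12, period_jitter_pct=5.0, noise_sd=0.0, seed=11
        )
        record, log = generate_continuous_record(spec)
        pulses = segment_pulses(record)
        # boundary pulses may be partial and dropped
        assert len(pulses) >= spec.n_pulses - 2
        drawn = log.periods_s
        # align recovered pulses to the drawn periods by best offset
        rec_periods = np.array([p.period for p in pulses])
        for offset in range(len(drawn) - len(rec_periods) + 1):
            if np.all(
                np.abs(rec_periods - drawn[offset : offset + len(rec_periods)])
                <= record.dt + 1e-12
            ):
                break
        else:
            pytest.fail(f"recovered periods {rec_periods} do not match log {drawn}")

    def test_ramp_region_then_steady_state(self):
        spec = EnsembleSpec(n_pulses=10, seed=4)
        record, log = generate_continuous_record(spec, include_ramp=True)
        # restrict to the post-ramp region (5 ramp pulses at base period)
        start = int(5 * spec.base_period_s * 500)
        post = SampledWaveform(
            values=record.values[start:], dt=record.dt, units=record.units
        )
        pulses = segment_pulses(post)
        assert len(pulses) >= spec.n_pulses - 2

    def test_affine_invariance_of_pipeline(self, gaussian_base):
        tile = gaussian_base.values
        rec1 = SampledWaveform(values=np.tile(tile, 6), dt=1 / 200, units="raw")
        rec2 = SampledWaveform(
            values=3.5 * np.tile(tile, 6) + 40.0, dt=1 / 200, units="raw"
        )
        m1 = ensemble_mean(build_ensemble(segment_pulses(rec1)))
        m2 = ensemble_mean(build_ensemble(segment_pulses(rec2)))
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)


class TestNormalize:
    def test_definition(self):
        v = 60 + 50 * (0.5 + 0.5 * np.sin(2 * np.pi * np.arange(100) / 100))
        p = SampledWaveform(values=v, dt=0.008, units="mmHg", period=0.8)
        n = normalize_pulse(p)
        assert n.values.min() == 0.0
        assert n.values.max() == 1.0
        assert n.period == 1.0
        assert n.units == "normalized"

    def test_idempotent(self, gaussian_base):
        again = normalize_pulse(gaussian_base)
        np.testing.assert_allclose(again.values, gaussian_base.values, atol=1e-12)

    def test_constant_pulse_rejected(self):
        p = SampledWaveform(values=np.full(50, 2.0), dt=0.01, units="raw")
        with pytest.raises(DegenerateInputError):
            normalize_pulse(p)

    @given(
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=-500.0, max_value=500.0),
    )
    def test_affine_invariance(self, a, b):
        v = 0.5 + 0.5 * np.sin(2 * np.pi * np.arange(64) / 64)
        p = SampledWaveform(values=v, dt=1 / 64, units="raw", period=1.0)
        q = SampledWaveform(values=a * v + b, dt=1 / 64, units="raw", period=1.0)
        np.testing.assert_allclose(
            normalize_pulse(p).values, normalize_pulse(q).values, atol=1e-9
        )


class TestResample:
    def test_identity_grid(self, gaussian_base):
        out = resample(gaussian_base, gaussian_base.n)
        np.testing.assert_allclose(out.values, gaussian_base.values, atol=1e-9)

    def test_sine_upsampling_accuracy(self):
        th = np.arange(50) / 50
        p = SampledWaveform(
            values=np.sin(2 * np.pi * th), dt=1 / 50, units="raw", period=1.0
        )
        out = resample(p, 200)
        exact = np.sin(2 * np.pi * np.arange(200) / 200)
        assert np.abs(out.values - exact).max() < 1e-3

    def test_refinement_consistency(self, gaussian_base):
        once = resample(gaussian_base, 200)
        twice = resample(resample(gaussian_base, 400), 200)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-6)

    def test_too_few_points_rejected(self, gaussian_base):
        with pytest.raises(ParameterError):
            resample(gaussian_base, 8)


class TestEnsembleMean:
    def test_mean_of_identical_pulses(self, gaussian_base):
        ens = build_ensemble([gaussian_base] * 3)
        np.testing.assert_allclose(
            ensemble_mean(ens).values, ens.pulses[0].values, atol=1e-12
        )

    def test_matches_bruteforce_loop(self, default_ensemble):
        ens, _ = default_ensemble
        mean = ensemble_mean(ens)
        brute = np.zeros(ens.n_grid)
        for p in ens.pulses:
            for k in range(ens.n_grid):
                brute[k] += p.values[k]
        brute /= len(ens)
        np.testing.assert_allclose(mean.values, brute, atol=1e-12)
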