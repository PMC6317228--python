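"""Penalized representative-waveform minimization."""

import numpy as np
import pytest

from pulsecam import (
    EnsembleSpec,
    FitConfig,
    build_ensemble,
    ensemble_mean,
    generate_ensemble,
    minimize_representative,
    objective,
    project_to_series,
    series_ai,
)
from pulsecam.fitting import ensemble_target_ri, _periodic_trapezoid
from pulsecam.synth import GaussianPulseParams, make_base_pulse


@pytest.fixture(scope="module")
def small_ensemble():
    """A quick 12-pulse ensemble for optimizer behavior tests."""
    return generate_ensemble(EnsembleSpec(n_pulses=12, seed=5))[0]


class TestObjective:
    def test_perfect_fit_is_near_zero(self):
        # a band-limited base pulse projects exactly onto the 10-term basis
        base = make_base_pulse("reference")
        ens = build_ensemble([base] * 4)
        series = project_to_series(ensemble_mean(ens), 10)
        target = ensemble_target_ri(ens)
        e, e_l2, e_ri = objective(series, ens, alpha=100.0, target_ri=target)
        assert e_l2 < 1e-9
        # residual E_RI is only the AI instrument mismatch between the
        # 200-point pulse grid and the dense candidate grid
        assert e_ri < 5e-4
        assert e < 0.05

    def test_alpha_zero_reduces_to_l2(self, small_ensemble):
        series = project_to_series(ensemble_mean(small_ensemble), 10)
        target = ensemble_target_ri(small_ensemble)
        e, e_l2, _ = objective(series, small_ensemble, alpha=0.0, target_ri=target)
        assert e == pytest.approx(e_l2, abs=1e-15)

    def test_e_l2_matches_bruteforce_double_loop(self, default_ensemble):
        ens, _ = default_ensemble
        series = project_to_series(ensemble_mean(ens), 10)
        target = ensemble_target_ri(ens)
        _, e_l2, _ = objective(series, ens, alpha=100.0, target_ri=target)
        # independent oracle: explicit per-pulse trapezoidal integrals
        from pulsecam.fourier import series_waveform

        u = series_waveform(series, ens.n_grid).values
        total = 0.0
        for p in ens.pulses:
            sq = (p.values - u) ** 2
            closed = np.append(sq, sq[0])
            total += np.trapezoid(closed, dx=1.0 / ens.n_grid)
        brute = np.sqrt(total) / len(ens)
        assert e_l2 == pytest.approx(brute, abs=1e-12)


class TestMinimize:
    def test_identical_pulses_converge_immediately(self):
        ens = build_ensemble([make_base_pulse("reference")] * 4)
        res = minimize_representative(ens, config=FitConfig(max_iters=10))
        assert res.e_total < 1e-4
        assert res.iterations <= 10

    def test_trace_monotone_over_seeds(self):
        for seed in range(10):
            ens, _ = generate_ensemble(EnsembleSpec(n_pulses=8, seed=seed))
            res = minimize_representative(ens, config=FitConfig(max_iters=25))
            es = [t.e_total for t in res.trace]
            assert all(es[i + 1] <= es[i] for i in range(len(es) - 1)), (
                f"seed {seed}: objective trace increased"
            )

    def test_known_mean_ai_recovered(self):
        """Ensemble built around AI ~= 70%: the fitted waveform's AI matches
        the logged ensemble mean to < 0.1 points."""
        spec = EnsembleSpec(
            kind="gaussians",
            gaussian_params=GaussianPulseParams(heights=(1.0, 0.70, 0.30)),
            seed=3,
        )
        ens, log = generate_ensemble(spec)
        res = minimize_representative(ens)
        assert log.mean_ai == pytest.approx(70.0, abs=2.0)
        assert series_ai(res.series) == pytest.approx(log.mean_ai, abs=0.1)
        # relative E_RI after the full run is far below 1e-3 of the target
        assert res.e_ri_percent / 100.0 * res.target_ri < 1e-3 * res.target_ri

    def test_alpha_sweep_e_ri_non_increasing(self, small_ensemble):
        finals = []
        for alpha in (1.0, 10.0, 100.0, 1000.0):
            res = minimize_representative(
                small_ensemble, config=FitConfig(alpha=alpha, max_iters=150)
            )
            finals.append(res.e_ri_percent)
        assert all(
            finals[i + 1] <= finals[i] + 1e-12 for i in range(len(finals) - 1)
        ), f"E_RI not non-increasing over alpha sweep: {finals}"

    def test_alpha_zero_minimizer_is_mean_projection(self, small_ensemble):
        proj = project_to_series(ensemble_mean(small_ensemble), 10)
        target = ensemble_target_ri(small_ensemble)
        _, e_l2_proj, _ = objective(proj, small_ensemble, alpha=0.0, target_ri=target)
        res = minimize_representative(
            small_ensemble, config=FitConfig(alpha=0.0, max_iters=40)
        )
        assert res.e_l2_percent / 100.0 <= e_l2_proj + 1e-6

    def test_iterations_equals_trace_length(self, small_ensemble):
        res = minimize_representative(small_ensemble, config=FitConfig(max_iters=15))
        assert res.iterations == len(res.trace)


def test_periodic_trapezoid_matches_mean():
    # on a uniform periodic grid the wrapped trapezoid equals the mean
    rng = np.random.default_rng(2)
    rows = rng.normal(size=(3, 50))
    np.testing.assert_allclose(
        _periodic_trapezoid(rows), rows.mean(axis=1), atol=1e-12
    )
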