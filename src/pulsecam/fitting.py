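"""Representative-waveform fitting.

The plain ensemble mean of normalized pulses under-represents the radial
augmentation index (AI), so the representative waveform is found by
minimizing, over the truncated Fourier-series space,

    E(u) = sqrt( E_L2(u)^2 + (alpha * E_RI(u))^2 )

where

    E_L2(u) = (1/M) * sqrt( sum_i  integral_0^1 (u_i - u)^2 dtheta )
    E_RI(u) = | RI - RI(u) | / RI          (relative AI error)

with ``u_i`` the M normalized ensemble pulses, ``RI`` their mean radial AI,
and ``RI(u)`` the AI of the candidate series waveform.  A sufficiently
large penalty weight ``alpha`` turns the problem into a penalty
formulation that preserves the ensemble's mean AI while staying as close
as possible (in L2) to all pulses.

The minimizer is deliberately simple and fully monotone: a central
finite-difference gradient over the 2n+1 coefficients with a backtracking
(Armijo) line search that only ever accepts decreases, started from the
projection of the ensemble mean onto the series basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augmentation import PeakConfig, radial_ai
from .errors import OptimizationError, PeakDetectionError
from .fourier import FourierSeries, design_matrix, project_to_series, series_waveform
from .waveform import PulseEnsemble, SampledWaveform, ensemble_mean


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the penalized minimization."""

    alpha: float = 100.0
    max_iters: int = 150
    n_harmonics: int = 10
    #: grid used to evaluate the candidate's AI (dense, so peak heights are
    #: effectively grid-independent)
    ai_grid_n: int = 2000
    fd_step: float = 1e-6
    armijo_c: float = 1e-4
    backtrack_factor: float = 0.5
    max_backtracks: int = 50
    #: stop early when the relative objective decrease falls below this
    rel_tol: float = 0.0
    #: E_RI (relative, as a fraction) assigned when peak detection fails on
    #: a candidate, so the line search can retreat
    detection_penalty: float = 10.0
    peak_config: PeakConfig = field(default_factory=PeakConfig)


@dataclass(frozen=True)
class TraceEntry:
    e_total: float
    e_l2: float
    e_ri_rel: float
    detection_failed: bool = False


@dataclass(frozen=True)
class FitResult:
    """Outcome of the representative-waveform minimization.

    ``e_l2_percent`` and ``e_ri_percent`` are the final error terms on the
    percent scale (E_L2 x 100; relative AI error x 100).
    """

    series: FourierSeries
    e_total: float
    e_l2_percent: float
    e_ri_percent: float
    trace: tuple[TraceEntry, ...]
    iterations: int
    alpha: float
    target_ri: float


def series_ai(
    series: FourierSeries, grid_n: int = 2000, config: PeakConfig | None = None
) -> float:
    """Radial AI of the series waveform on a dense evaluation grid."""
    return radial_ai(series_waveform(series, grid_n), config).ai_percent


def ensemble_target_ri(
    ensemble: PulseEnsemble, config: PeakConfig | None = None
) -> float:
    """RI: the mean radial AI of the ensemble pulses."""
    return float(np.mean([radial_ai(p, config).ai_percent for p in ensemble.pulses]))


def objective(
    series: FourierSeries,
    ensemble: PulseEnsemble,
    alpha: float,
    target_ri: float,
    config: FitConfig | None = None,
) -> tuple[float, float, float]:
    """Evaluate (E, E_L2, E_RI) for one candidate series.

    The per-pulse integral is the trapezoidal rule on the periodic common
    grid (wrap-around sample appended).  E_RI is the relative AI error as a
    fraction; a failed peak detection on the candidate is mapped to the
    configured large finite penalty.
    """
    config = config or FitConfig(alpha=alpha)
    e, e_l2, e_ri, _ = _objective_impl(
        series.as_vector(), _FitWorkspace(ensemble, config), alpha, target_ri
    )
    return e, e_l2, e_ri


class _FitWorkspace:
    """Precomputed basis matrices and ensemble arrays for fast evaluation."""

    def __init__(self, ensemble: PulseEnsemble, config: FitConfig):
        self.config = config
        self.m = len(ensemble)
        grid_phases = ensemble.phases
        self.basis = design_matrix(config.n_harmonics, grid_phases)
        dense_phases = np.arange(config.ai_grid_n) / config.ai_grid_n
        self.basis_dense = design_matrix(config.n_harmonics, dense_phases)
        self.pulse_matrix = ensemble.matrix
        self.n_grid = ensemble.n_grid


def _periodic_trapezoid(sq: np.ndarray) -> np.ndarray:
    """Trapezoidal integral over one period of each row, wrap appended."""
    closed = np.concatenate([sq, sq[:, :1]], axis=1)
    x = np.arange(closed.shape[1]) / sq.shape[1]
    return np.trapezoid(closed, x=x, axis=1)


def _objective_impl(
    vec: np.ndarray, ws: _FitWorkspace, alpha: float, target_ri: float
) -> tuple[float, float, float, bool]:
    u = ws.basis @ vec
    resid_sq = (ws.pulse_matrix - u[None, :]) ** 2
    e_l2 = float(np.sqrt(_periodic_trapezoid(resid_sq).sum()) / ws.m)
    dense = ws.basis_dense @ vec
    failed = False
    try:
        wave = SampledWaveform(
            values=dense, dt=1.0 / dense.size, units="series", period=1.0
        )
        ai = radial_ai(wave, ws.config.peak_config).ai_percent
        e_ri = abs(target_ri - ai) / target_ri
    except PeakDetectionError:
        e_ri = ws.config.detection_penalty
        failed = True
    e = float(np.sqrt(e_l2**2 + (alpha * e_ri) ** 2))
    return e, e_l2, e_ri, failed


def minimize_representative(
    ensemble: PulseEnsemble,
    alpha: float | None = None,
    max_iters: int | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the representative waveform by penalized line-search descent.

    Starts from the projection of the ensemble mean onto the Fourier basis
    (the natural initial guess: it already minimizes E_L2).  Each iteration
    builds a central finite-difference gradient of E over the 2n+1
    coefficients and backtracks along the negative gradient until an Armijo
    decrease is found; only decreasing steps are ever accepted, so the
    objective trace is monotone non-increasing by construction.
    """
    config = config or FitConfig()
    if alpha is not None:
        config = FitConfig(**{**config.__dict__, "alpha": alpha})
    if max_iters is not None:
        config = FitConfig(**{**config.__dict__, "max_iters": max_iters})
    alpha = config.alpha

    target_ri = ensemble_target_ri(ensemble, config.peak_config)
    ws = _FitWorkspace(ensemble, config)
    start = project_to_series(ensemble_mean(ensemble), config.n_harmonics)
    vec = start.as_vector()

    e, e_l2, e_ri, failed = _objective_impl(vec, ws, alpha, target_ri)
    if not np.isfinite(e):
        raise OptimizationError("non-finite objective at the initial guess")
    trace: list[TraceEntry] = []
    dim = vec.size
    h = config.fd_step
    prev_vec: np.ndarray | None = None
    prev_grad: np.ndarray | None = None

    for it in range(config.max_iters):
        grad = np.empty(dim)
        for j in range(dim):
            step = np.zeros(dim)
            step[j] = h
            ep = _objective_impl(vec + step, ws, alpha, target_ri)[0]
            em = _objective_impl(vec - step, ws, alpha, target_ri)[0]
            grad[j] = (ep - em) / (2.0 * h)
        if not np.all(np.isfinite(grad)):
            raise OptimizationError(f"non-finite gradient at iteration {it}")
        gnorm_sq = float(grad @ grad)
        if gnorm_sq == 0.0:
            break
        # Barzilai-Borwein spectral step as the line-search warm start: a
        # large penalty weight makes the objective valley stiff, where a
        # unit steepest-descent step zigzags; the BB step adapts to the
        # local curvature while the Armijo backtracking keeps every
        # accepted step a strict decrease
        t = 1.0
        if prev_vec is not None:
            s = vec - prev_vec
            y = grad - prev_grad
            sy = float(s @ y)
            if sy > 0:
                t = float(s @ s) / sy
        prev_vec, prev_grad = vec.copy(), grad.copy()
        accepted = False
        for _ in range(config.max_backtracks):
            cand = vec - t * grad
            e_new, l2_new, ri_new, fail_new = _objective_impl(
                cand, ws, alpha, target_ri
            )
            if np.isfinite(e_new) and e_new <= e - config.armijo_c * t * gnorm_sq:
                accepted = True
                break
            t *= config.backtrack_factor
        if not accepted:
            break
        prev = e
        vec, e, e_l2, e_ri, failed = cand, e_new, l2_new, ri_new, fail_new
        trace.append(TraceEntry(e, e_l2, e_ri, failed))
        if config.rel_tol > 0 and prev > 0 and (prev - e) / prev < config.rel_tol:
            break

    return FitResult(
        series=FourierSeries.from_vector(vec),
        e_total=e,
        e_l2_percent=100.0 * e_l2,
        e_ri_percent=100.0 * e_ri,
        trace=tuple(trace),
        iterations=len(trace),
        alpha=alpha,
        target_ri=target_ri,
    )
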