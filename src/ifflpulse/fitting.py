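"""Derivative-free parameter estimation from normalized time courses.

The loss is an unweighted sum of squared residuals between the observed
replicate-mean signal and ``S_G * GFP_sim(t)`` over all unmasked points of
all training conditions.  Minimization is Nelder–Mead simplex: in log
parameter space (which enforces positivity) and unconstrained for the
RNA-only model; bound-constrained for the hybrid model.  Restarts jitter
the initial point in log space and the best run wins.

Parameters of a model are generally *not* identifiable from GFP output
alone — e.g. scaling ``alpha_GFP`` up and ``S_G`` down by the same factor
leaves the observable exactly unchanged.  Accuracy claims are therefore
about predicted trajectories, not about recovered parameter values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize

from .circuit_models import free_parameter_names
from .errors import AnalysisError, IntegrationError, ParameterError
from .simulate import SolverOptions, TimeCourse, TimeGrid, observed_gfp, simulate

__all__ = ["FitConfig", "FitResult", "sse_objective", "fit_rna_only",
           "fit_hybrid", "validate_fit"]

logger = logging.getLogger(__name__)

SIMULATION_FAILURE_PENALTY = 1e12


@dataclass(frozen=True)
class FitConfig:
    """Options controlling a fitting run.

    ``bounds`` maps parameter names to (lo, hi) in natural units.  The
    defaults follow a plain simplex protocol: parameter tolerance 1e-6 in
    log space, objective tolerance 1e-8, at most ``max_iterations``
    function evaluations per restart, 3 restarts with 10% log-space
    jitter.
    """

    transform: str = "log"
    bounds: dict | None = None
    max_iterations: int = 5000
    n_restarts: int = 3
    restart_jitter: float = 0.10
    seed: int = 0
    xatol: float = 1e-6
    fatol: float = 1e-8
    initial_step: float = 0.10
    audit_evaluations: bool = False

    def __post_init__(self):
        if self.transform not in ("log", "linear"):
            raise ParameterError("transform must be 'log' or 'linear'")
        if self.n_restarts < 1:
            raise ParameterError("n_restarts must be >= 1")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if not lo < hi:
                    raise ParameterError(f"bounds for {name}: need lo < hi")


@dataclass
class FitResult:
    params: dict
    objective: float
    converged: bool
    n_evaluations: int
    trace: list
    seed: int
    config: FitConfig
    model_id: str
    evaluation_log: list | None = None

    def to_json(self, path):
        doc = {
            "model_id": self.model_id,
            "params": self.params,
            "objective": self.objective,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "trace": self.trace,
            "seed": self.seed,
            "config": {k: v for k, v in asdict(self.config).items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def sse_objective(params, datasets: list[TimeCourse], model_id: str,
                  grid: TimeGrid | None = None,
                  options: SolverOptions = SolverOptions()) -> float:
    """Sum of squared residuals over all unmasked points of all conditions.

    Conditions are weighted equally (no per-condition normalization).  A
    simulation failure contributes a large penalty instead of raising, so
    that a simplex search can route around pathological corners.
    """
    if not datasets:
        raise AnalysisError("sse_objective needs at least one dataset")
    total = 0.0
    any_points = False
    for tc in datasets:
        if not tc.mask.any():
            raise AnalysisError(
                f"all points masked for condition {tc.condition.label()}")
        any_points = True
        if grid is not None:
            course_grid = grid
        else:
            # integrate only to the last unmasked point; later samples
            # cannot contribute to the objective
            t_last = tc.times[tc.mask][-1]
            course_grid = TimeGrid(tc.times[0], t_last,
                                   tc.times[1] - tc.times[0])
        try:
            traj = simulate(model_id, params, tc.condition, course_grid,
                            options=options)
        except IntegrationError as exc:
            logger.warning("simulation failed at %s: %s",
                           tc.condition.label(), exc)
            return SIMULATION_FAILURE_PENALTY
        sim = observed_gfp(traj, params.S_G).signal
        k = len(sim)
        m = tc.mask[:k]
        resid = tc.signal[:k][m] - sim[m]
        total += float(resid @ resid)
    if not any_points:
        raise AnalysisError("no unmasked points in any dataset")
    return total


def _run_simplex(objective, x0, config: FitConfig, log_bounds):
    """One Nelder–Mead run with best-so-far trace recording.

    The initial simplex is built explicitly with a uniform step per
    coordinate: scipy's default scales the step with the coordinate value,
    which collapses exploration for log-parameters near zero (natural
    values near 1).
    """
    trace = []
    best = [np.inf]
    n_eval = [0]
    audit = [] if config.audit_evaluations else None

    def wrapped(x):
        n_eval[0] += 1
        if audit is not None:
            audit.append(x.copy())
        v = objective(x)
        if v < best[0]:
            best[0] = v
            logger.debug("eval %d: objective improved to %.6g", n_eval[0], v)
        trace.append(best[0])
        return v

    simplex = np.vstack([x0] + [x0 + config.initial_step * e
                                for e in np.eye(len(x0))])
    if log_bounds is not None:
        lo = np.array([b[0] for b in log_bounds])
        hi = np.array([b[1] for b in log_bounds])
        simplex = np.clip(simplex, lo, hi)
    res = minimize(
        wrapped, x0, method="Nelder-Mead", bounds=log_bounds,
        options={"maxfev": config.max_iterations, "xatol": config.xatol,
                 "fatol": config.fatol, "adaptive": True,
                 "initial_simplex": simplex})
    return res, trace, n_eval[0], audit


def _fit(datasets, init_params, config: FitConfig, model_id: str,
         grid=None, options=SolverOptions(), require_bounds=False) -> FitResult:
    names = free_parameter_names(model_id)
    x_init = init_params.free_values()
    if np.any(x_init <= 0):
        raise ParameterError("initial parameters must be strictly positive")

    log_bounds = None
    if config.bounds is not None:
        missing = set(names) - set(config.bounds)
        if require_bounds and missing:
            raise ParameterError(f"bounds missing for parameters: {sorted(missing)}")
        lo = np.array([config.bounds.get(k, (1e-300, 1e300))[0] for k in names])
        hi = np.array([config.bounds.get(k, (1e-300, 1e300))[1] for k in names])
        if np.any(x_init < lo) or np.any(x_init > hi):
            raise ParameterError("initial parameters outside bounds")
        log_bounds = list(zip(np.log(lo), np.log(hi)))
    elif require_bounds:
        raise ParameterError("this fit requires bounds for every free parameter")

    use_log = config.transform == "log"

    def objective(x):
        values = np.exp(x) if use_log else x
        if np.any(values <= 0) or not np.all(np.isfinite(values)):
            return SIMULATION_FAILURE_PENALTY
        try:
            candidate = init_params.with_free_values(values)
        except ParameterError:
            return SIMULATION_FAILURE_PENALTY
        return sse_objective(candidate, datasets, model_id, grid, options)

    x0_base = np.log(x_init) if use_log else x_init
    f0 = objective(x0_base)
    if not np.isfinite(f0):
        raise ParameterError(
            f"objective not finite at the initial point; params: "
            f"{dict(zip(names, x_init))}")

    if not use_log and log_bounds is not None:
        log_bounds = list(zip(lo, hi))

    rng = np.random.default_rng(config.seed)
    best_res, best_trace, best_nev, best_audit = None, None, 0, None
    total_evals = 0
    for restart in range(config.n_restarts):
        if restart == 0:
            x0 = x0_base
        else:
            # re-seed a fresh simplex near the best point found so far:
            # plain Nelder-Mead stagnates in 15+ dimensions, and a jittered
            # warm restart recovers progress far faster than restarting
            # from the original init
            anchor = best_res.x if best_res is not None else x0_base
            jit = rng.normal(0.0, config.restart_jitter, size=len(x0_base))
            x0 = anchor + (jit if use_log else anchor * jit)
            if log_bounds is not None:
                x0 = np.clip(x0, [b[0] for b in log_bounds],
                             [b[1] for b in log_bounds])
        res, trace, nev, audit = _run_simplex(objective, x0, config, log_bounds)
        total_evals += nev
        logger.info("restart %d: objective %.6g after %d evaluations",
                    restart, res.fun, nev)
        if best_res is None or res.fun < best_res.fun:
            best_res, best_trace, best_nev, best_audit = res, trace, nev, audit

    values = np.exp(best_res.x) if use_log else best_res.x
    return FitResult(
        params=dict(zip(names, map(float, values))),
        objective=float(best_res.fun),
        converged=bool(best_res.success),
        n_evaluations=total_evals,
        trace=[float(v) for v in best_trace],
        seed=config.seed,
        config=config,
        model_id=model_id,
        evaluation_log=(None if best_audit is None
                        else [list(map(float, np.exp(x) if use_log else x))
                              for x in best_audit]),
    )


def fit_rna_only(datasets: list[TimeCourse], init, config: FitConfig,
                 grid=None, options=SolverOptions()) -> FitResult:
    """Fit the 15 free RNA-only parameters by unconstrained Nelder–Mead
    in log space."""
    return _fit(datasets, init, config, "rna_only", grid, options,
                require_bounds=False)


def fit_hybrid(datasets: list[TimeCourse], init, config: FitConfig,
               grid=None, options=SolverOptions()) -> FitResult:
    """Fit the hybrid model with bound-constrained Nelder–Mead; bounds are
    required for every free parameter and no candidate is evaluated
    outside them."""
    return _fit(datasets, init, config, "hybrid", grid, options,
                require_bounds=True)


def validate_fit(fit: FitResult, heldout: list[TimeCourse],
                 train_conditions=(), grid=None,
                 options=SolverOptions()) -> dict:
    """Simulate the fitted parameters at held-out conditions.

    Returns ``{label: {"rmse": ..., "nrmse": ..., "n_points": ...,
    "overlaps_train": ...}}`` with the RMSE over unmasked points and the
    RMSE normalized by the observed root-mean-square.  Overlap between
    held-out and training conditions sets a flag instead of raising.
    """
    from .circuit_models import params_from_mapping

    params = params_from_mapping(
        fit.model_id,
        {**fit.params, "P_X_total": 1.0, "P_Y_total": 1.0, "P_Z_total": 1.0})
    train_labels = {c.label() for c in train_conditions}
    out = {}
    for tc in heldout:
        label = tc.condition.label()
        course_grid = grid if grid is not None else TimeGrid(
            tc.times[0], tc.times[-1], tc.times[1] - tc.times[0])
        traj = simulate(fit.model_id, params, tc.condition, course_grid,
                        options=options)
        sim = observed_gfp(traj, params.S_G).signal
        resid = tc.signal[tc.mask] - sim[tc.mask]
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        scale = float(np.sqrt(np.mean(tc.signal[tc.mask] ** 2)))
        overlap = label in train_labels
        if overlap:
            logger.warning("held-out condition %s overlaps the training set",
                           label)
        out[label] = {"rmse": rmse,
                      "nrmse": rmse / scale if scale > 0 else np.inf,
                      "n_points": int(tc.mask.sum()),
                      "overlaps_train": overlap}
    return out
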