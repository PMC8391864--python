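"""Random-perturbation sensitivity analysis.

One draw perturbs the full free kinetic parameter vector jointly, each
component independently uniform on ``[(1-f)*nominal, (1+f)*nominal]``
(default f = 0.5, i.e. +/-50%), and the perturbed model is simulated at
every experimental condition.  Ten draws per condition is the default
ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit_models import free_parameter_names
from .errors import IntegrationError, ParameterError
from .plate_reader import ANALYSIS_WINDOWS, apply_analysis_window
from .simulate import DEFAULT_GRIDS, SolverOptions, TimeGrid, observed_gfp, simulate

__all__ = ["PerturbationEnsemble", "sample_perturbations", "run_ensemble"]


@dataclass
class PerturbationEnsemble:
    """Nominal + perturbed observed-GFP time courses per condition.

    ``trajectories[label]`` lists the nominal course first, then one per
    draw; a failed simulation is stored as ``None`` and counted in
    ``failures``.
    """

    model_id: str
    nominal: dict
    fraction: float
    n_draws: int
    seed: int
    parameter_names: list
    draws: np.ndarray
    trajectories: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, courses in self.trajectories.items():
            for i, tc in enumerate(courses):
                if tc is None:
                    continue
                kind = "nominal" if i == 0 else f"draw_{i - 1}"
                for t, s, m in zip(tc.times, tc.signal, tc.mask):
                    rows.append((label, kind, t, s, m))
        return pd.DataFrame(
            rows, columns=["condition", "trajectory", "time_min", "signal",
                           "in_window"])


def sample_perturbations(nominal: dict, fraction: float = 0.5,
                         n_draws: int = 10, seed: int = 0,
                         exclude: tuple = ()) -> np.ndarray:
    """Draw a (n_draws x n_parameters) matrix of perturbed parameter values.

    Every parameter in ``nominal`` is drawn independently uniform within
    +/-``fraction`` of its nominal value; names listed in ``exclude`` stay
    at nominal.  ``fraction`` must be < 1 so that rates stay positive.
    """
    if not (0 <= fraction < 1):
        raise ParameterError("fraction must be in [0, 1)")
    if n_draws < 1:
        raise ParameterError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(nominal)
    base = np.array([nominal[k] for k in names], dtype=float)
    u = rng.uniform(1.0 - fraction, 1.0 + fraction, size=(n_draws, len(names)))
    for j, name in enumerate(names):
        if name in exclude:
            u[:, j] = 1.0
    return base[None, :] * u


def run_ensemble(model_id: str, nominal_params, conditions=None,
                 fraction: float = 0.5, n_draws: int = 10, seed: int = 0,
                 grid: TimeGrid | None = None,
                 options: SolverOptions = SolverOptions(),
                 apply_window: bool = True) -> PerturbationEnsemble:
    """Simulate the nominal and perturbed models at every condition.

    Observed GFP courses carry the circuit's analysis-window mask (pulse
    metrics run on the window only).  A draw whose integration fails at a
    condition is recorded as failed for that condition and excluded from
    downstream fractions, never silently dropped.
    """
    if conditions is None:
        raise ParameterError("conditions list is required")
    if grid is None:
        grid = DEFAULT_GRIDS[model_id]
    free_names = free_parameter_names(model_id)
    nominal_map = {k: getattr(nominal_params, k) for k in free_names}
    draws = sample_perturbations(nominal_map, fraction, n_draws, seed)
    ens = PerturbationEnsemble(
        model_id=model_id, nominal=nominal_map, fraction=fraction,
        n_draws=n_draws, seed=seed, parameter_names=free_names, draws=draws)
    window = ANALYSIS_WINDOWS[model_id]
    param_sets = [nominal_params] + [
        nominal_params.with_free_values(row) for row in draws]
    for cond in conditions:
        label = cond.label()
        courses = []
        for i, p in enumerate(param_sets):
            try:
                traj = simulate(model_id, p, cond, grid, options=options)
                tc = observed_gfp(traj, p.S_G)
                if apply_window:
                    tc = apply_analysis_window(tc, window=window)
                courses.append(tc)
            except IntegrationError as exc:
                courses.append(None)
                ens.failures.append(
                    {"condition": label, "trajectory": i, "error": str(exc)})
        ens.trajectories[label] = courses
    return ens
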