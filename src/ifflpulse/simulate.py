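"""Integration of the circuit models over experimental time grids.

The solver contract is stiff-capable and deterministic: LSODA with tight
default tolerances, evaluated on the plate-reader sampling grid.  Small
negative excursions (below the absolute tolerance) are clamped to zero;
anything larger is treated as an integration failure rather than silently
hidden.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .circuit_models import (
    HYBRID_SPECIES,
    RNA_ONLY_SPECIES,
    CircuitVariant,
    InducerCondition,
    REGULAR,
    RNAOnlyParams,
    apply_variant,
    hill_activation,
    induced_plasmids,
)
from .errors import AnalysisError, IntegrationError, ParameterError, StateDomainError

__all__ = [
    "TimeGrid",
    "Trajectory",
    "TimeCourse",
    "SolverOptions",
    "DEFAULT_GRIDS",
    "simulate",
    "observed_gfp",
    "closed_form_steady_state_rna_only",
    "rk4_reference",
]


@dataclass(frozen=True)
class TimeGrid:
    """Sampling grid in minutes; the plate reader reads every 10 min."""

    t_start: float = 0.0
    t_end: float = 300.0
    cadence: float = 10.0

    def __post_init__(self):
        if not (self.t_end > self.t_start >= 0):
            raise ParameterError("need t_end > t_start >= 0")
        if not self.cadence > 0:
            raise ParameterError("cadence must be > 0")

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor((self.t_end - self.t_start) / self.cadence + 1e-9)) + 1
        return self.t_start + self.cadence * np.arange(n)

    @property
    def n_samples(self) -> int:
        return len(self.times)


# Default protocol grids: 5 h / 31 cycles for the RNA-only circuit,
# 8 h / 49 cycles for the hybrid circuit, both at 10-min cadence.
DEFAULT_GRIDS = {
    "rna_only": TimeGrid(0.0, 300.0, 10.0),
    "hybrid": TimeGrid(0.0, 480.0, 10.0),
}


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"
    # transcription onset delay: Hill activation is zeroed for t < tau_T7,
    # representing the build-up of T7 RNAP after induction (off by default)
    tau_t7: float = 0.0

    def __post_init__(self):
        if self.tau_t7 < 0:
            raise ParameterError("tau_t7 must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Simulated state paths on a sampling grid (species in model order)."""

    times: np.ndarray
    states: np.ndarray
    model_id: str
    condition: InducerCondition
    params_hash: str = ""

    def __post_init__(self):
        if self.states.shape[0] != len(self.times):
            raise ValueError("states must have one row per sample time")

    @property
    def species(self) -> tuple:
        return RNA_ONLY_SPECIES if self.model_id == "rna_only" else HYBRID_SPECIES

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]


@dataclass
class TimeCourse:
    """An observed (or simulated-observed) GFP signal with an analysis mask.

    Masked points keep their stored values; they are merely excluded from
    objectives and pulse metrics.
    """

    times: np.ndarray
    signal: np.ndarray
    mask: np.ndarray = None
    condition: InducerCondition = field(default_factory=InducerCondition)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.times), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.times) == len(self.signal) == len(self.mask)):
            raise ValueError("times, signal and mask must have equal length")

    def unmasked(self) -> tuple[np.ndarray, np.ndarray]:
        return self.times[self.mask], self.signal[self.mask]


def params_hash(params, cond: InducerCondition, options: SolverOptions) -> str:
    payload = json.dumps(
        [params.to_dict(), cond.label(), options.rtol, options.atol,
         options.method, options.tau_t7],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _make_rhs(model_id, params, cond, variant, tau_t7=0.0):
    """Build a fast closure for the integrator with condition constants
    precomputed (Hill terms are constant in time for constant inducers)."""
    p = apply_variant(params, variant)
    if model_id == "rna_only":
        H_ara = hill_activation(cond.arabinose, p.K_ara, p.m)
        PY, PZ = induced_plasmids(p, cond)
        aX, aY, aZ, aG = p.alpha_X, p.alpha_Y, p.alpha_Z, p.alpha_GFP
        g, w = p.gamma, p.omega
        dx, dy, dz, dg = p.delta_X, p.delta_Y, p.delta_Z, p.delta_GFP
        px = p.P_X_total
        constitutive = variant.constitutive_y
        ymult = variant.y_production_multiplier

        def rhs(t, s):
            X, Y, Z, G = s
            H = H_ara if t >= tau_t7 else 0.0
            yprod = aY * PY if constitutive else aY * g * X * PY * ymult
            return (
                aX * px * H - g * X * PY - g * X * PZ - dx * X,
                yprod - dy * Y - w * Y * Z,
                aZ * g * X * PZ - dz * Z - w * Y * Z,
                aG * Z - dg * G,
            )

        return rhs

    if model_id == "hybrid":
        H0 = hill_activation(cond.iptg, p.K_IPTG, p.n)
        aX, aY, aZ, aT, aG = p.alpha_X, p.alpha_Y, p.alpha_Z, p.alpha_T, p.alpha_G
        g, w = p.gamma, p.omega
        dx, dy, dz, dcy, dcz, dt_, dg = (
            p.delta_X, p.delta_Y, p.delta_Z, p.delta_CY, p.delta_CZ,
            p.delta_T, p.delta_G,
        )
        ka = p.k_atc * cond.atc
        ko = p.k_off
        px, py, pztot = p.P_X_total, p.P_Y_total, p.P_Z_total

        def rhs(t, s):
            X, Y, Z, CXY, CXZ, T, PZr, G = s
            H = H0 if t >= tau_t7 else 0.0
            PZf = pztot - PZr
            return (
                aX * px * H - g * X * Y - g * X * Z - dx * X,
                aY * py - g * X * Y - dy * Y,
                aZ * PZf * H - g * X * Z - dz * Z,
                g * X * Y - dcy * CXY,
                g * X * Z - dcz * CXZ,
                aT * CXY - w * T * PZf - ka * T - dt_ * T,
                w * T * PZf - ko * PZr,
                aG * CXZ - dg * G,
            )

        return rhs

    raise ParameterError(f"unknown model_id {model_id!r}")


def simulate(model_id: str, params, cond: InducerCondition,
             grid: TimeGrid | None = None, init=None,
             options: SolverOptions = SolverOptions(),
             variant: CircuitVariant = REGULAR) -> Trajectory:
    """Integrate a circuit model over a sampling grid.

    The default initial condition is the zero state at induction time
    (inducers are added to freshly diluted culture at t = 0).  Negative
    solver excursions below ``options.atol`` are clamped to 0; larger ones
    raise :class:`IntegrationError`.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[model_id]
    n_species = 4 if model_id == "rna_only" else 8
    if init is None:
        init = np.zeros(n_species)
    init = np.asarray(init, dtype=float)
    if init.shape != (n_species,):
        raise StateDomainError(f"init must have {n_species} components")
    if np.any(init < 0):
        raise StateDomainError("initial state must be non-negative")

    rhs = _make_rhs(model_id, params, cond, variant, options.tau_t7)
    times = grid.times
    sol = solve_ivp(
        rhs, (times[0], times[-1]), init, t_eval=times,
        method=options.method, rtol=options.rtol, atol=options.atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else times[0]
        raise IntegrationError(
            f"{options.method} failed for {model_id} at {cond.label()}: "
            f"{sol.message}", last_time=last)
    states = sol.y.T.copy()
    most_negative = states.min(initial=0.0)
    if most_negative < -options.atol * 10:
        raise IntegrationError(
            f"solver produced negative concentrations ({most_negative:.3e}) "
            f"beyond tolerance for {model_id} at {cond.label()}",
            last_time=float(times[-1]))
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=times, states=states, model_id=model_id,
                      condition=cond,
                      params_hash=params_hash(params, cond, options))


def observed_gfp(traj: Trajectory, S_G: float) -> TimeCourse:
    """Map the latent GFP concentration to the observed signal S_G * GFP."""
    if not S_G > 0:
        raise ParameterError(f"S_G must be > 0, got {S_G}")
    gfp = traj.column("GFP" if traj.model_id == "rna_only" else "G")
    return TimeCourse(times=traj.times, signal=S_G * gfp,
                      condition=traj.condition)


def closed_form_steady_state_rna_only(params: RNAOnlyParams,
                                      cond: InducerCondition) -> np.ndarray:
    """Analytic fixed point of the RNA-only system when omega = 0.

    With the Y–Z annihilation switched off the system is a linear cascade
    whose steady state factorizes species by species.
    """
    if params.omega != 0:
        raise AnalysisError("closed form requires omega == 0 exactly")
    H_ara = hill_activation(cond.arabinose, params.K_ara, params.m)
    PY, PZ = induced_plasmids(params, cond)
    X = params.alpha_X * params.P_X_total * H_ara / (
        params.delta_X + params.gamma * PY + params.gamma * PZ)
    Y = params.alpha_Y * params.gamma * X * PY / params.delta_Y
    Z = params.alpha_Z * params.gamma * X * PZ / params.delta_Z
    GFP = params.alpha_GFP * Z / params.delta_GFP
    return np.array([X, Y, Z, GFP])


def rk4_reference(model_id: str, params, cond: InducerCondition,
                  grid: TimeGrid, init=None, step: float = 0.01,
                  variant: CircuitVariant = REGULAR,
                  tau_t7: float = 0.0) -> Trajectory:
    """Fixed-step classical Runge–Kutta integration as an independent
    reference for validating the adaptive stiff solver.

    Deliberately naive: constant step ``step`` (min), no error control.
    """
    if model_id not in ("rna_only", "hybrid"):
        raise ParameterError(f"unknown model_id {model_id!r}")
    n_species = 4 if model_id == "rna_only" else 8
    y = np.zeros(n_species) if init is None else np.asarray(init, dtype=float).copy()
    rhs = _make_rhs(model_id, params, cond, variant, tau_t7)

    def f(t, s):
        return np.asarray(rhs(t, s))

    times = grid.times
    out = np.empty((len(times), n_species))
    t = times[0]
    out[0] = y
    for i in range(1, len(times)):
        t_target = times[i]
        while t < t_target - 1e-12:
            h = min(step, t_target - t)
            k1 = f(t, y)
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i] = y
    np.clip(out, 0.0, None, out=out)
    return Trajectory(times=times, states=out, model_id=model_id, condition=cond)
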