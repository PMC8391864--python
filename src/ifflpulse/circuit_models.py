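"""Kinetic models of the two synthetic incoherent feed-forward loop (IFFL) circuits.

Two mass-action/Hill ODE systems are defined over arbitrary concentration
units and minutes:

* **RNA-only IFFL** — a STAR trigger X activates transcription of both an
  output node Z (3WJ-repressor switch + GFP) and an intermediate node Y
  (3WJ trigger) that silences Z translation by direct RNA–RNA binding.
  State order: ``(X, Y, Z, GFP)``.

* **RNA–protein hybrid IFFL** — a toehold-switch trigger X activates
  translation of GFP from Z and of the repressor protein TetR from Y;
  TetR shuts down transcription of Z by binding its operator, and the
  inducer aTc titrates free TetR.  State order:
  ``(X, Y, Z, C_XY, C_XZ, T, PZ_rep, G)`` where ``C_XY``/``C_XZ`` are
  trigger:switch complexes, ``T`` free TetR and ``PZ_rep`` the repressed
  Z plasmid.

Inducer activation of transcription is phenomenological (Hill functions);
everything downstream is elementary mass action.  Plasmid totals are fixed
structural constants, not kinetic parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ParameterError, StateDomainError

__all__ = [
    "InducerCondition",
    "RNAOnlyParams",
    "HybridParams",
    "CircuitVariant",
    "RNA_ONLY_SPECIES",
    "HYBRID_SPECIES",
    "NOMINAL_RNA_ONLY",
    "NOMINAL_HYBRID",
    "hill_activation",
    "induced_plasmids",
    "rna_only_rhs",
    "hybrid_rhs",
    "free_parameter_names",
    "apply_variant",
    "params_from_mapping",
    "load_model_config",
    "save_model_config",
]

RNA_ONLY_SPECIES = ("X", "Y", "Z", "GFP")
HYBRID_SPECIES = ("X", "Y", "Z", "C_XY", "C_XZ", "T", "PZ_rep", "G")

# Free (fittable) parameter order.  Plasmid totals are deliberately absent:
# they are structural constants so that the RNA-only free set has exactly
# 15 entries.
_RNA_ONLY_FREE = (
    "alpha_X", "alpha_Y", "alpha_Z", "alpha_GFP",
    "gamma", "omega",
    "delta_X", "delta_Y", "delta_Z", "delta_GFP",
    "K_ara", "K_IPTG", "m", "n", "S_G",
)
_HYBRID_FREE = (
    "alpha_X", "alpha_Y", "alpha_Z", "alpha_T", "alpha_G",
    "gamma", "omega",
    "delta_X", "delta_Y", "delta_Z", "delta_CY", "delta_CZ",
    "delta_T", "delta_G",
    "K_IPTG", "n", "k_atc", "k_off", "S_G",
)


@dataclass(frozen=True)
class InducerCondition:
    """External inducer inputs applied to one well or simulation.

    iptg and arabinose are in µM, aTc in nM.  Arabinose is only read by the
    RNA-only model (it drives T7 RNAP expression in the BL21 AI strain);
    aTc is only read by the hybrid model.
    """

    iptg: float = 0.0
    arabinose: float = 0.0
    atc: float = 0.0

    def __post_init__(self):
        for name in ("iptg", "arabinose", "atc"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")

    def label(self) -> str:
        return f"iptg={self.iptg:g}uM_ara={self.arabinose:g}uM_atc={self.atc:g}nM"


def _check_positive(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not v > 0:
            raise ParameterError(f"{name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class RNAOnlyParams:
    """Kinetic parameters of the RNA-only IFFL.

    Rates are per minute; ``gamma`` (trigger–plasmid activation) and
    ``omega`` (Y–Z RNA annihilation) are second order (per conc per min).
    ``K_ara``/``K_IPTG`` are Hill constants in µM with coefficients
    ``m``/``n``.  ``S_G`` maps simulated GFP concentration to observed
    fluorescence/OD units.  Plasmid totals ``P_*_total`` are fixed
    constants and are never fitted.
    """

    alpha_X: float
    alpha_Y: float
    alpha_Z: float
    alpha_GFP: float
    gamma: float
    omega: float
    delta_X: float
    delta_Y: float
    delta_Z: float
    delta_GFP: float
    K_ara: float
    K_IPTG: float
    m: float
    n: float
    S_G: float
    P_X_total: float = 1.0
    P_Y_total: float = 1.0
    P_Z_total: float = 1.0

    def __post_init__(self):
        _check_positive(self, [f.name for f in fields(self) if f.name != "omega"])
        if self.omega < 0:
            raise ParameterError(f"omega must be >= 0, got {self.omega}")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _RNA_ONLY_FREE], dtype=float)

    def with_free_values(self, values) -> "RNAOnlyParams":
        return replace(self, **dict(zip(_RNA_ONLY_FREE, map(float, values))))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class HybridParams:
    """Kinetic parameters of the RNA–protein hybrid IFFL.

    ``alpha_X/alpha_Y/alpha_Z`` are transcription rates, ``alpha_T`` and
    ``alpha_G`` translation rates from the bound trigger:switch complexes.
    ``gamma`` is the trigger–switch binding rate, ``omega`` the
    TetR–operator binding rate.  ``k_atc`` is the second-order aTc–TetR
    sequestration rate (per nM per min); ``k_off`` an optional first-order
    relief of the repressed plasmid (default 0, i.e. repression is
    irreversible on the experiment's timescale).  ``delta_T`` is the knob
    that degradation-tag variants (ASV < AAV < LVA) move.
    """

    alpha_X: float
    alpha_Y: float
    alpha_Z: float
    alpha_T: float
    alpha_G: float
    gamma: float
    omega: float
    delta_X: float
    delta_Y: float
    delta_Z: float
    delta_CY: float
    delta_CZ: float
    delta_T: float
    delta_G: float
    K_IPTG: float
    n: float
    k_atc: float
    k_off: float
    S_G: float
    P_X_total: float = 1.0
    P_Y_total: float = 1.0
    P_Z_total: float = 1.0

    def __post_init__(self):
        positive = [f.name for f in fields(self) if f.name not in ("k_off", "alpha_T")]
        _check_positive(self, positive)
        if self.k_off < 0:
            raise ParameterError(f"k_off must be >= 0, got {self.k_off}")
        # alpha_T = 0 encodes the noTetR control variant
        if self.alpha_T < 0:
            raise ParameterError(f"alpha_T must be >= 0, got {self.alpha_T}")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _HYBRID_FREE], dtype=float)

    def with_free_values(self, values) -> "HybridParams":
        return replace(self, **dict(zip(_HYBRID_FREE, map(float, values))))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# Degradation-tag presets: protease activity increases ASV -> AAV -> LVA.
DEGRADATION_TAG_DELTA_T = {"ASV": 0.01, "AAV": 0.02, "LVA": 0.05}

_RNA_ONLY_VARIANTS = ("regular", "insulated", "decoy", "constitutive")
_HYBRID_VARIANTS = ("noTetR", "ASV", "AAV", "LVA")


@dataclass(frozen=True)
class CircuitVariant:
    """A node-Y variant, realized as parameter/structure overrides.

    RNA-only variants: ``regular`` (baseline), ``insulated`` (ribozyme-
    released 3WJ trigger; effective Y production scaled by
    ``insulation_factor`` >= 1), ``decoy`` (no functional trigger,
    omega = 0), ``constitutive`` (trigger transcribed independently of X:
    the Y production term becomes alpha_Y * PY*).

    Hybrid variants: ``noTetR`` (alpha_T = 0) and the degradation tags
    ``ASV``/``AAV``/``LVA`` selecting increasing delta_T.
    """

    variant_id: str = "regular"
    insulation_factor: float = 3.0
    override_map: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.variant_id not in _RNA_ONLY_VARIANTS + _HYBRID_VARIANTS:
            raise ParameterError(f"unknown variant_id {self.variant_id!r}")
        if self.insulation_factor < 1:
            raise ParameterError("insulation_factor must be >= 1")

    @property
    def y_production_multiplier(self) -> float:
        return self.insulation_factor if self.variant_id == "insulated" else 1.0

    @property
    def constitutive_y(self) -> bool:
        return self.variant_id == "constitutive"


REGULAR = CircuitVariant("regular")


def apply_variant(params, variant: CircuitVariant | None):
    """Return a parameter set with the variant's parameter overrides applied.

    Structural changes (constitutive Y production, insulation multiplier)
    are read from the variant at right-hand-side evaluation time; only
    plain parameter overrides are applied here.
    """
    if variant is None:
        return params
    overrides = dict(variant.override_map)
    if variant.variant_id == "decoy":
        overrides.setdefault("omega", 0.0)
    elif variant.variant_id == "noTetR":
        overrides.setdefault("alpha_T", 0.0)
    elif variant.variant_id in DEGRADATION_TAG_DELTA_T:
        overrides.setdefault("delta_T", DEGRADATION_TAG_DELTA_T[variant.variant_id])
    if not overrides:
        return params
    return replace(params, **overrides)


def hill_activation(I: float, K: float, h: float) -> float:
    """Fraction of promoters activated by inducer concentration ``I``.

    Returns ``I**h / (K**h + I**h)``; 0 at I = 0, 1/2 at I = K, and
    strictly below 1 for any finite I.
    """
    if not K > 0:
        raise ParameterError(f"Hill constant K must be > 0, got {K}")
    if not h > 0:
        raise ParameterError(f"Hill coefficient must be > 0, got {h}")
    if I < 0:
        raise ParameterError(f"inducer concentration must be >= 0, got {I}")
    if I == 0:
        return 0.0
    # (I/K)**h / (1 + (I/K)**h) is overflow-safe for large I/K
    x = (I / K) ** h
    v = float(x / (1.0 + x))
    # keep the bound strict even where x/(1+x) rounds to 1.0 in floats
    return min(v, 1.0 - 2.0 ** -53)


def induced_plasmids(params: RNAOnlyParams, cond: InducerCondition) -> tuple[float, float]:
    """IPTG-induced, transcription-ready Y and Z plasmid pools (PY*, PZ*)."""
    h = hill_activation(cond.iptg, params.K_IPTG, params.n)
    return params.P_Y_total * h, params.P_Z_total * h


def _check_state(state, n_species, model):
    state = np.asarray(state, dtype=float)
    if state.shape != (n_species,):
        raise StateDomainError(f"{model} state must have {n_species} components")
    if np.any(state < 0):
        raise StateDomainError(f"negative {model} state component: {state}")
    return state


def rna_only_rhs(t, state, params: RNAOnlyParams, cond: InducerCondition,
                 variant: CircuitVariant = REGULAR) -> np.ndarray:
    """Time derivatives of the RNA-only IFFL state ``(X, Y, Z, GFP)``.

    X is transcribed from its plasmid under arabinose Hill control and
    consumed by activating the Y and Z plasmids; Y and Z are produced
    proportionally to the activated flux ``gamma*X*P*`` and annihilate each
    other at rate ``omega`` (3WJ trigger binding its switch).  GFP is
    translated from free Z.
    """
    state = _check_state(state, 4, "rna_only")
    p = apply_variant(params, variant)
    X, Y, Z, GFP = state
    H_ara = hill_activation(cond.arabinose, p.K_ara, p.m)
    PY, PZ = induced_plasmids(p, cond)
    if variant.constitutive_y:
        y_production = p.alpha_Y * PY
    else:
        y_production = p.alpha_Y * p.gamma * X * PY * variant.y_production_multiplier
    dX = p.alpha_X * p.P_X_total * H_ara - p.gamma * X * PY - p.gamma * X * PZ - p.delta_X * X
    dY = y_production - p.delta_Y * Y - p.omega * Y * Z
    dZ = p.alpha_Z * p.gamma * X * PZ - p.delta_Z * Z - p.omega * Y * Z
    dGFP = p.alpha_GFP * Z - p.delta_GFP * GFP
    return np.array([dX, dY, dZ, dGFP])


def hybrid_rhs(t, state, params: HybridParams, cond: InducerCondition,
               variant: CircuitVariant | None = None) -> np.ndarray:
    """Time derivatives of the hybrid IFFL state.

    Order: ``(X, Y, Z, C_XY, C_XZ, T, PZ_rep, G)``.  The free Z plasmid is
    the conserved remainder ``P_Z_total - PZ_rep`` and is never integrated.
    Trigger binding to either switch is irreversible; translation of TetR
    and GFP proceeds from the complexes.  Free TetR partitions between
    operator binding (repression), aTc sequestration, and degradation.
    """
    state = _check_state(state, 8, "hybrid")
    p = apply_variant(params, variant)
    X, Y, Z, CXY, CXZ, T, PZ_rep, G = state
    if PZ_rep > p.P_Z_total * (1 + 1e-9):
        raise StateDomainError(f"PZ_rep={PZ_rep} exceeds P_Z_total={p.P_Z_total}")
    H = hill_activation(cond.iptg, p.K_IPTG, p.n)
    PZ_free = p.P_Z_total - PZ_rep
    dX = p.alpha_X * p.P_X_total * H - p.gamma * X * Y - p.gamma * X * Z - p.delta_X * X
    dY = p.alpha_Y * p.P_Y_total - p.gamma * X * Y - p.delta_Y * Y
    dZ = p.alpha_Z * PZ_free * H - p.gamma * X * Z - p.delta_Z * Z
    dCXY = p.gamma * X * Y - p.delta_CY * CXY
    dCXZ = p.gamma * X * Z - p.delta_CZ * CXZ
    dT = (p.alpha_T * CXY - p.omega * T * PZ_free
          - p.k_atc * cond.atc * T - p.delta_T * T)
    dPZ_rep = p.omega * T * PZ_free - p.k_off * PZ_rep
    dG = p.alpha_G * CXZ - p.delta_G * G
    return np.array([dX, dY, dZ, dCXY, dCXZ, dT, dPZ_rep, dG])


def free_parameter_names(model_id: str) -> list[str]:
    """Documented order of the free (fittable) parameters of a model.

    Plasmid totals are excluded for both models; the RNA-only list has
    exactly 15 entries.
    """
    if model_id == "rna_only":
        return list(_RNA_ONLY_FREE)
    if model_id == "hybrid":
        return list(_HYBRID_FREE)
    raise ParameterError(f"unknown model_id {model_id!r}")


# ---------------------------------------------------------------------------
# Nominal parameter sets.
#
# The RNA stage is shared between the two models (alpha_X, gamma,
# delta_X/Y/Z, K_IPTG, n), so the presence/absence of a pulse is
# attributable to the protein stage alone.  RNA lifetimes are a few
# minutes (delta ~ 0.2/min); untagged GFP in the RNA-only circuit turns
# over slowly (0.01/min, dilution-dominated) while the tagged hybrid
# reporter is faster (0.02/min).  The hybrid protein arm is slow by
# construction: a weak constitutive promoter on Y, slow TetR translation,
# a long-lived translating Y complex, and tight operator binding so that
# every TetR made titrates a Z plasmid.  See docs/methods.md.
# ---------------------------------------------------------------------------

NOMINAL_RNA_ONLY = RNAOnlyParams(
    alpha_X=5.0, alpha_Y=1.0, alpha_Z=1.0, alpha_GFP=0.5,
    gamma=0.5, omega=0.5,
    delta_X=0.2, delta_Y=0.2, delta_Z=0.2, delta_GFP=0.01,
    K_ara=800.0, K_IPTG=30.0, m=1.0, n=1.2, S_G=1000.0,
)

NOMINAL_HYBRID = HybridParams(
    alpha_X=5.0, alpha_Y=0.06, alpha_Z=2.0, alpha_T=0.0035, alpha_G=0.5,
    gamma=0.5, omega=100.0,
    delta_X=0.2, delta_Y=0.2, delta_Z=0.2, delta_CY=0.005, delta_CZ=0.015,
    delta_T=0.02, delta_G=0.02,
    K_IPTG=30.0, n=1.2, k_atc=0.003, k_off=0.0, S_G=1000.0,
)


def params_from_mapping(model_id: str, mapping: Mapping[str, float]):
    """Build a parameter set of the right type from a plain name->value map."""
    cls = {"rna_only": RNAOnlyParams, "hybrid": HybridParams}.get(model_id)
    if cls is None:
        raise ParameterError(f"unknown model_id {model_id!r}")
    valid = {f.name for f in fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ParameterError(f"unknown parameters for {model_id}: {sorted(unknown)}")
    try:
        return cls(**{k: float(v) for k, v in mapping.items()})
    except TypeError as exc:
        raise ParameterError(str(exc)) from exc


def save_model_config(path, model_id: str, params, variant: CircuitVariant = REGULAR):
    """Serialize a model definition (id, parameters, variant) to YAML or JSON."""
    doc = {
        "model_id": model_id,
        "parameters": params.to_dict(),
        "variant": {
            "variant_id": variant.variant_id,
            "insulation_factor": variant.insulation_factor,
            "override_map": dict(variant.override_map),
        },
    }
    path = Path(path)
    text = (json.dumps(doc, indent=2) if path.suffix == ".json"
            else yaml.safe_dump(doc, sort_keys=False))
    path.write_text(text)


def load_model_config(path):
    """Inverse of :func:`save_model_config`; returns (model_id, params, variant)."""
    path = Path(path)
    raw = path.read_text()
    doc = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    model_id = doc["model_id"]
    params = params_from_mapping(model_id, doc["parameters"])
    vdoc = doc.get("variant", {})
    variant = CircuitVariant(
        vdoc.get("variant_id", "regular"),
        vdoc.get("insulation_factor", 5.0),
        vdoc.get("override_map", {}),
    )
    return model_id, params, variant
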