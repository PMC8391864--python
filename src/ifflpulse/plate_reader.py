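"""Plate-reader table I/O, blank/OD normalization and replicate aggregation.

The observed quantity throughout the package is blank-corrected
fluorescence per OD600 unit:

    signal(t) = (F(t) - F_blank(t)) / OD600(t)

with the per-cycle blank estimated as the mean over blank (medium-only)
wells.  Early low-density cycles and the stationary phase are excluded by
masking, never by dropping points.

Two CSV dialects are supported.  Long form has one row per well and cycle
with columns::

    well_id,time_min,fluorescence,od600,iptg_uM,arabinose_uM,atc_nM,variant,replicate,is_blank

Wide form has one row per well with the same metadata columns followed by
``F_000,F_010,...`` and ``OD_000,OD_010,...`` cycle columns named by time
in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit_models import InducerCondition
from .errors import AnalysisError, SchemaError
from .simulate import TimeCourse

__all__ = [
    "Well",
    "PlateReaderDataset",
    "ANALYSIS_WINDOWS",
    "OD_FLOOR",
    "read_plate_table",
    "write_plate_table",
    "normalize",
    "apply_analysis_window",
    "aggregate_replicates",
]

# Analysis windows (min) from the experimental protocol: early points are
# unreliable at low OD600, late points once cells reach stationary phase.
ANALYSIS_WINDOWS = {"rna_only": (90.0, 200.0), "hybrid": (50.0, 300.0)}

# Safety net below which OD600 points are masked even inside the window.
OD_FLOOR = 0.02

_LONG_COLUMNS = ["well_id", "time_min", "fluorescence", "od600", "iptg_uM",
                 "arabinose_uM", "atc_nM", "variant", "replicate", "is_blank"]


@dataclass
class Well:
    well_id: str
    raw_fluorescence: np.ndarray
    od600: np.ndarray
    condition: InducerCondition
    variant: str = "regular"
    replicate: int = 0
    is_blank: bool = False

    def __post_init__(self):
        self.raw_fluorescence = np.asarray(self.raw_fluorescence, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if len(self.raw_fluorescence) != len(self.od600):
            raise SchemaError(f"well {self.well_id}: F and OD lengths differ")
        if np.any(self.od600 < 0):
            raise SchemaError(f"well {self.well_id}: negative OD600")


@dataclass
class PlateReaderDataset:
    """Raw wells x cycles fluorescence and OD600 plus per-well metadata."""

    times: np.ndarray
    wells: list[Well] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for w in self.wells:
            if len(w.raw_fluorescence) != len(self.times):
                raise SchemaError(
                    f"well {w.well_id}: {len(w.raw_fluorescence)} cycles, "
                    f"expected {len(self.times)}")

    @property
    def n_cycles(self) -> int:
        return len(self.times)

    def blank_wells(self) -> list[Well]:
        return [w for w in self.wells if w.is_blank]

    def sample_wells(self) -> list[Well]:
        return [w for w in self.wells if not w.is_blank]


def write_plate_table(dataset: PlateReaderDataset, path, dialect: str = "long"):
    """Write a dataset to CSV in the long or wide dialect."""
    if dialect == "long":
        rows = []
        for w in dataset.wells:
            for t, f, od in zip(dataset.times, w.raw_fluorescence, w.od600):
                rows.append((w.well_id, t, f, od, w.condition.iptg,
                             w.condition.arabinose, w.condition.atc,
                             w.variant, w.replicate, int(w.is_blank)))
        pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)
    elif dialect == "wide":
        fcols = [f"F_{int(round(t)):03d}" for t in dataset.times]
        odcols = [f"OD_{int(round(t)):03d}" for t in dataset.times]
        rows = []
        for w in dataset.wells:
            row = {"well_id": w.well_id, "iptg_uM": w.condition.iptg,
                   "arabinose_uM": w.condition.arabinose,
                   "atc_nM": w.condition.atc, "variant": w.variant,
                   "replicate": w.replicate, "is_blank": int(w.is_blank)}
            row.update(dict(zip(fcols, w.raw_fluorescence)))
            row.update(dict(zip(odcols, w.od600)))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")


def read_plate_table(path, dialect: str = "long") -> PlateReaderDataset:
    """Read a plate-reader CSV table and validate it into a dataset."""
    df = pd.read_csv(path)
    if dialect == "long":
        return _read_long(df, path)
    if dialect == "wide":
        return _read_wide(df, path)
    raise SchemaError(f"unknown dialect {dialect!r}")


def _require_columns(df, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _read_long(df, path) -> PlateReaderDataset:
    _require_columns(df, _LONG_COLUMNS, path)
    for col in ("fluorescence", "od600", "time_min"):
        bad = df[df[col].isna()]
        if len(bad):
            row = bad.iloc[0]
            raise SchemaError(
                f"{path}: missing {col} for well {row['well_id']} "
                f"at t={row['time_min']}")
    times = np.sort(df["time_min"].unique())
    wells = []
    for well_id, g in df.groupby("well_id", sort=False):
        g = g.sort_values("time_min")
        if len(g) != len(times) or not np.allclose(g["time_min"].to_numpy(), times):
            raise SchemaError(
                f"{path}: well {well_id} has a ragged/misaligned time vector")
        first = g.iloc[0]
        wells.append(Well(
            well_id=str(well_id),
            raw_fluorescence=g["fluorescence"].to_numpy(),
            od600=g["od600"].to_numpy(),
            condition=InducerCondition(float(first["iptg_uM"]),
                                       float(first["arabinose_uM"]),
                                       float(first["atc_nM"])),
            variant=str(first["variant"]),
            replicate=int(first["replicate"]),
            is_blank=bool(first["is_blank"]),
        ))
    return PlateReaderDataset(times=times, wells=wells)


def _read_wide(df, path) -> PlateReaderDataset:
    meta = ["well_id", "iptg_uM", "arabinose_uM", "atc_nM", "variant",
            "replicate", "is_blank"]
    _require_columns(df, meta, path)
    fcols = sorted([c for c in df.columns if c.startswith("F_")])
    odcols = sorted([c for c in df.columns if c.startswith("OD_")])
    if not fcols or [c[2:] for c in fcols] != [c[3:] for c in odcols]:
        raise SchemaError(f"{path}: F_*/OD_* cycle columns absent or misaligned")
    times = np.array([float(c[2:]) for c in fcols])
    wells = []
    for _, row in df.iterrows():
        f = row[fcols].to_numpy(dtype=float)
        od = row[odcols].to_numpy(dtype=float)
        if np.any(pd.isna(f)) or np.any(pd.isna(od)):
            raise SchemaError(f"{path}: missing cycle value in well {row['well_id']}")
        wells.append(Well(
            well_id=str(row["well_id"]), raw_fluorescence=f, od600=od,
            condition=InducerCondition(float(row["iptg_uM"]),
                                       float(row["arabinose_uM"]),
                                       float(row["atc_nM"])),
            variant=str(row["variant"]), replicate=int(row["replicate"]),
            is_blank=bool(row["is_blank"])))
    return PlateReaderDataset(times=times, wells=wells)


def normalize(dataset: PlateReaderDataset,
              od_floor: float = OD_FLOOR) -> list[TimeCourse]:
    """Blank-subtract and OD-normalize every non-blank well.

    The blank is the per-cycle mean over blank wells (medium
    autofluorescence drifts over a run, so a scalar blank would bias late
    cycles).  Cycles with OD600 below ``od_floor`` are masked, which also
    protects the division.  Returns one TimeCourse per sample well, in
    dataset order.
    """
    blanks = dataset.blank_wells()
    if not blanks:
        raise AnalysisError("normalization requires at least one blank well")
    samples = dataset.sample_wells()
    if not samples:
        raise AnalysisError("dataset contains only blank wells")
    blank = np.mean([w.raw_fluorescence for w in blanks], axis=0)
    out = []
    for w in samples:
        ok = w.od600 >= od_floor
        od_safe = np.where(ok, w.od600, 1.0)
        signal = (w.raw_fluorescence - blank) / od_safe
        signal = np.where(ok, signal, 0.0)
        out.append(TimeCourse(times=dataset.times, signal=signal, mask=ok,
                              condition=w.condition))
    return out


def apply_analysis_window(tc: TimeCourse, circuit: str = None,
                          window: tuple[float, float] = None) -> TimeCourse:
    """Mask points outside the circuit's analysis window.

    The defaults follow the experimental protocol: the RNA-only circuit is
    analyzed on [90, 200] min, the hybrid circuit on [50, 300] min.  The
    returned course keeps the original values; the mask is the
    intersection with the existing one.
    """
    if window is None:
        if circuit not in ANALYSIS_WINDOWS:
            raise AnalysisError(
                f"circuit must be one of {sorted(ANALYSIS_WINDOWS)} "
                "when no explicit window is given")
        window = ANALYSIS_WINDOWS[circuit]
    lo, hi = window
    mask = tc.mask & (tc.times >= lo) & (tc.times <= hi)
    if not mask.any():
        raise AnalysisError(f"analysis window [{lo}, {hi}] excludes every point")
    return TimeCourse(times=tc.times, signal=tc.signal, mask=mask,
                      condition=tc.condition)


def aggregate_replicates(tcs: list[TimeCourse]) -> tuple[TimeCourse, np.ndarray, bool]:
    """Pointwise mean and sample s.d. across replicate time courses.

    All inputs must share the time grid; the output mask is the
    intersection of the input masks.  Returns ``(mean_course, sd,
    single_replicate_flag)`` — with a single replicate the s.d. is
    reported as 0 and the flag is set.
    """
    if not tcs:
        raise AnalysisError("cannot aggregate an empty replicate list")
    times = tcs[0].times
    for tc in tcs[1:]:
        if len(tc.times) != len(times) or not np.allclose(tc.times, times):
            raise AnalysisError("replicates are on mismatched time grids")
    signals = np.stack([tc.signal for tc in tcs])
    mask = np.logical_and.reduce([tc.mask for tc in tcs])
    mean = signals.mean(axis=0)
    single = len(tcs) == 1
    sd = (np.zeros(len(times)) if single
          else signals.std(axis=0, ddof=1))
    return (TimeCourse(times=times, signal=mean, mask=mask,
                       condition=tcs[0].condition), sd, single)
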