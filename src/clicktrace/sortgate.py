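"""Hierarchical flow-cytometry gating on event tables.

Reproduces the sort logic used to separate analog-assimilating microbes
from the rest of a gut-content suspension:

1. *debris gate* — rectangle on (FSC-A, SSC-A) excluding low-scatter debris;
2. *singlet gates* — axis-aligned bounds on SSC-W vs SSC-H, then FSC-W vs
   FSC-H, excluding doublets/aggregates (doublets carry inflated width);
3. *fluorescence split* — an AF647-A threshold, typically derived from a
   no-stain control quantile, separating labelled (AF647+) from unlabelled
   (AF647−) cells.

Events enter as a plain CSV-backed table (one row per event); native FCS
binary parsing is out of scope and fluorescence is treated on a linear
scale — transforms are display-only and never change fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H", "SSC-W", "AF647-A")


@dataclass
class EventTable:
    """Flow-cytometry events: one row per event, scatter + fluorescence columns."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        vals = self.df[list(REQUIRED_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("event table contains non-finite values")

    @property
    def n_events(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path, column_map: Optional[dict[str, str]] = None) -> "EventTable":
        df = pd.read_csv(path)
        if column_map:
            df = df.rename(columns=column_map)
        return cls(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.4f")


@dataclass(frozen=True)
class Bounds:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise ValueError(f"bounds must satisfy low < high, got [{self.low}, {self.high}]")

    def contains(self, x: np.ndarray) -> np.ndarray:
        return (x >= self.low) & (x <= self.high)


@dataclass(frozen=True)
class GateTree:
    """The hierarchical gate definition.

    ``debris_fsc_a``/``debris_ssc_a`` bound the cell cloud on scatter area;
    the singlet gates bound width and height per scatter channel; the AF647
    threshold splits the final singlet population.
    """

    debris_fsc_a: Bounds
    debris_ssc_a: Bounds
    ssc_singlet_w: Bounds
    ssc_singlet_h: Bounds
    fsc_singlet_w: Bounds
    fsc_singlet_h: Bounds
    af647_threshold: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.af647_threshold):
            raise ValueError("AF647 threshold must be finite")


GATE_ORDER = ("cells", "ssc_singlets", "fsc_singlets")


@dataclass
class GateResult:
    """Counts and parent-relative fractions at each level of the hierarchy."""

    counts: dict[str, int]          # gate name -> events surviving
    fractions: dict[str, float]     # gate name -> fraction of parent gate
    af647_pos_fraction: float       # of final singlet population
    af647_neg_fraction: float
    threshold: float
    masks: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        for name, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction for {name!r} outside [0, 1]")
        if self.af647_pos_fraction + self.af647_neg_fraction > 1.0 + 1e-12:
            raise ValueError("AF647 fractions exceed 1")


def threshold_from_negative_control(
    control: EventTable, quantile: float = 0.995
) -> float:
    """AF647 threshold as a high quantile of a no-stain control.

    With the default 0.995 quantile, unlabelled events exceed the threshold
    at a ~0.5% false-positive rate.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    if control.n_events < 100:
        raise ValueError(
            f"negative control needs ≥100 events, got {control.n_events}"
        )
    return float(np.quantile(control.df["AF647-A"].to_numpy(dtype=float), quantile))


def apply_gates(events: EventTable, gates: GateTree, keep_masks: bool = False) -> GateResult:
    """Run the debris → SSC singlet → FSC singlet → AF647 hierarchy.

    Each reported fraction is relative to its parent gate; the AF647+/−
    split is reported as fractions of the final singlet population.
    """
    if events.n_events == 0:
        raise ValueError("empty event table")
    df = events.df
    cells = gates.debris_fsc_a.contains(df["FSC-A"].to_numpy()) & gates.debris_ssc_a.contains(
        df["SSC-A"].to_numpy()
    )
    ssc_singlets = cells & gates.ssc_singlet_w.contains(
        df["SSC-W"].to_numpy()
    ) & gates.ssc_singlet_h.contains(df["SSC-H"].to_numpy())
    fsc_singlets = ssc_singlets & gates.fsc_singlet_w.contains(
        df["FSC-W"].to_numpy()
    ) & gates.fsc_singlet_h.contains(df["FSC-H"].to_numpy())

    counts = {
        "cells": int(cells.sum()),
        "ssc_singlets": int(ssc_singlets.sum()),
        "fsc_singlets": int(fsc_singlets.sum()),
    }
    parents = {"cells": events.n_events, "ssc_singlets": counts["cells"],
               "fsc_singlets": counts["ssc_singlets"]}
    fractions = {
        name: (counts[name] / parents[name]) if parents[name] else 0.0
        for name in GATE_ORDER
    }

    af = df["AF647-A"].to_numpy()[fsc_singlets]
    n_final = len(af)
    pos = float(np.sum(af > gates.af647_threshold) / n_final) if n_final else 0.0
    neg = float(np.sum(af <= gates.af647_threshold) / n_final) if n_final else 0.0
    masks = None
    if keep_masks:
        masks = {"cells": cells, "ssc_singlets": ssc_singlets, "fsc_singlets": fsc_singlets}
    return GateResult(
        counts=counts,
        fractions=fractions,
        af647_pos_fraction=pos,
        af647_neg_fraction=neg,
        threshold=gates.af647_threshold,
        masks=masks,
    )


def default_gate_tree(af647_threshold: float) -> GateTree:
    """Gate bounds matched to the synthetic event generator's populations.

    Real gate geometries are instrument- and prep-specific and are supplied
    by the analyst; these defaults bracket the generator's cell cloud and
    exclude its debris (low scatter) and doublets (inflated width).
    """
    return GateTree(
        debris_fsc_a=Bounds(10_000.0, 1e7),
        debris_ssc_a=Bounds(5_000.0, 1e7),
        ssc_singlet_w=Bounds(40.0, 100.0),
        ssc_singlet_h=Bounds(0.0, 1e7),
        fsc_singlet_w=Bounds(40.0, 100.0),
        fsc_singlet_h=Bounds(0.0, 1e7),
        af647_threshold=af647_threshold,
    )
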