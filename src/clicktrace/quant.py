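"""Targeted quantification: EIC peak areas and group comparisons.

Quantification follows the targeted re-integration pattern: extract an ion
chromatogram at a target m/z, integrate the peak (trapezoid rule, optional
linear baseline), tabulate per-sample areas by biological group, then test
group differences with one-way ANOVA followed by Tukey's HSD at a
family-wise alpha.  Areas are compared on the raw AUC scale by default; a
log10 option exists for heavy-tailed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import MetaboliteSpecies
from .feature_io import FeatureTable

DEFAULT_QUANT_TOL_PPM = 10.0


@dataclass
class EIC:
    """An extracted ion chromatogram: intensity vs time at a target m/z."""

    target_mz: float
    tol_ppm: float
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise ValueError("an EIC needs at least two points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class PeakArea:
    """An integrated chromatographic peak."""

    auc: float
    t_start: float
    t_end: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.auc < 0:
            raise ValueError("auc must be non-negative")


def integrate_eic(
    eic: EIC,
    window: tuple[float, float],
    baseline_mode: str = "none",
) -> PeakArea:
    """Trapezoidal integral of (intensity − baseline), clipped at 0.

    ``baseline_mode="linear_endpoints"`` subtracts the straight line through
    the trace values at the window edges before integrating; ``"none"``
    integrates the raw trace.  The window must lie inside the EIC's time
    range, and edge points are obtained by linear interpolation so the
    integral is exact for piecewise-linear traces.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("degenerate integration window")
    if t0 < eic.time[0] - 1e-12 or t1 > eic.time[-1] + 1e-12:
        raise ValueError("integration window outside EIC time range")
    if baseline_mode not in ("none", "linear_endpoints"):
        raise ValueError(f"unknown baseline mode {baseline_mode!r}")

    inside = (eic.time > t0) & (eic.time < t1)
    t = np.concatenate(([t0], eic.time[inside], [t1]))
    y = np.interp(t, eic.time, eic.intensity)
    if baseline_mode == "linear_endpoints":
        base = np.interp(t, [t0, t1], [y[0], y[-1]])
        baseline_level = float(0.5 * (y[0] + y[-1]))
    else:
        base = np.zeros_like(t)
        baseline_level = 0.0
    corrected = np.clip(y - base, 0.0, None)
    auc = float(np.trapezoid(corrected, t))
    return PeakArea(auc=max(auc, 0.0), t_start=float(t0), t_end=float(t1), baseline=baseline_level)


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD over ≥2 groups of AUC values."""

    analyte: str
    groups: dict[str, list[float]]
    f_statistic: float
    p_value: float
    pairwise: list[tuple[str, str, float]]  # (groupA, groupB, Tukey-adjusted p)
    alpha: float = 0.05
    # unadjusted pooled-variance pairwise p (Fisher LSD); the Tukey-adjusted
    # p is never smaller than this
    pairwise_raw: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, p in self.pairwise if p < self.alpha]

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, "p_adj": p, "significant": p < self.alpha}
            for a, b, p in self.pairwise
        ]
        return pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj", "significant"])


def compare_groups(
    analyte: str,
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    log_transform: bool = False,
) -> GroupComparison:
    """Classical one-way ANOVA with Tukey HSD post-hoc comparisons.

    Tukey-adjusted p-values come from the studentized-range distribution and
    use the Tukey–Kramer form for unequal group sizes.  The degenerate case
    of zero variance everywhere (all observations identical) reports F = 0,
    p = 1 and no significant pairs rather than NaN.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for lab in labels:
        a = np.asarray(groups[lab], dtype=float)
        a = a[~np.isnan(a)]
        if len(a) < 2:
            raise ValueError(f"group {lab!r} has fewer than two observations")
        arrays.append(np.log10(a) if log_transform else a)

    pooled = np.concatenate(arrays)
    pairs_idx = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]

    if np.ptp(pooled) == 0.0:
        pairwise = [(labels[i], labels[j], 1.0) for i, j in pairs_idx]
        return GroupComparison(analyte, {l: list(map(float, a)) for l, a in zip(labels, arrays)},
                               0.0, 1.0, pairwise, alpha, pairwise_raw=list(pairwise))

    within_ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if within_ss == 0.0:
        # groups internally constant but means differ: evidence is unbounded
        pairwise = [
            (labels[i], labels[j], 0.0 if arrays[i].mean() != arrays[j].mean() else 1.0)
            for i, j in pairs_idx
        ]
        return GroupComparison(analyte, {l: list(map(float, a)) for l, a in zip(labels, arrays)},
                               float("inf"), 0.0, pairwise, alpha, pairwise_raw=list(pairwise))

    f_stat, p_val = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = [
        (labels[i], labels[j], float(tukey.pvalue[i, j])) for i, j in pairs_idx
    ]
    # unadjusted pooled-variance pairwise test on the same error term
    n_total = sum(len(a) for a in arrays)
    df_within = n_total - len(arrays)
    mse = within_ss / df_within
    pairwise_raw = []
    for i, j in pairs_idx:
        se = np.sqrt(mse * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        t = (arrays[i].mean() - arrays[j].mean()) / se
        pairwise_raw.append(
            (labels[i], labels[j], float(2.0 * stats.t.sf(abs(t), df_within)))
        )
    return GroupComparison(
        analyte,
        {l: list(map(float, a)) for l, a in zip(labels, arrays)},
        float(f_stat),
        float(p_val),
        pairwise,
        alpha,
        pairwise_raw=pairwise_raw,
    )


@dataclass
class AnalyteQuant:
    """Per-target quantification outcome within a feature table."""

    analyte: str
    feature_id: Optional[str]  # None = not detected
    match_ppm: Optional[float]
    group_values: dict[str, list[float]]
    comparison: Optional[GroupComparison]

    @property
    def detected(self) -> bool:
        return self.feature_id is not None

    def elevated_group(self) -> Optional[str]:
        """The group significantly higher than every other group, if unique.

        Requires the group's mean to exceed each other group's mean with a
        Tukey-adjusted p below alpha for every such pair.
        """
        if self.comparison is None:
            return None
        means = {g: float(np.mean(v)) for g, v in self.group_values.items()}
        sig = set()
        for a, b in self.comparison.significant_pairs:
            sig.add(frozenset((a, b)))
        for g in means:
            others = [o for o in means if o != g]
            if all(means[g] > means[o] and frozenset((g, o)) in sig for o in others):
                return g
        return None


def quant_report(
    table: FeatureTable,
    targets: Sequence[MetaboliteSpecies],
    mz_tol_ppm: float = DEFAULT_QUANT_TOL_PPM,
    alpha: float = 0.05,
    log_transform: bool = False,
) -> tuple[pd.DataFrame, list[AnalyteQuant]]:
    """Targeted per-group quantification over a feature table.

    For each target species the feature with the closest m/z within
    tolerance is selected; its per-sample intensities are grouped by the
    manifest's ``group`` column and compared with ANOVA + Tukey.  Targets
    with no matching feature appear as not-detected rows.  Returns a tidy
    long-format AUC table and the per-analyte results.
    """
    if not targets:
        raise ValueError("no targets supplied")
    mz = table.features["mz"].to_numpy()
    rows = []
    results: list[AnalyteQuant] = []
    group_labels = [g for g in dict.fromkeys(table.manifest["group"]) if g != ""]
    for sp in targets:
        ppm = np.abs((mz - sp.theoretical_mz) / sp.theoretical_mz) * 1e6
        order = np.argsort(ppm, kind="stable")
        best = int(order[0]) if len(order) else None
        if best is None or ppm[best] > mz_tol_ppm:
            results.append(AnalyteQuant(sp.name, None, None, {}, None))
            rows.append({"analyte": sp.name, "feature_id": "", "group": "",
                         "sample_id": "", "auc": np.nan, "detected": False})
            continue
        fid = table.feature_ids[best]
        group_values: dict[str, list[float]] = {}
        for g in group_labels:
            samples = table.samples_in_group(g)
            vals = table.intensities.loc[fid, samples].dropna().astype(float)
            group_values[g] = list(vals)
            for sid, v in vals.items():
                rows.append({"analyte": sp.name, "feature_id": fid, "group": g,
                             "sample_id": sid, "auc": float(v), "detected": True})
        testable = {g: v for g, v in group_values.items() if len(v) >= 2}
        comparison = None
        if len(testable) >= 2:
            comparison = compare_groups(sp.name, testable, alpha=alpha,
                                        log_transform=log_transform)
        results.append(AnalyteQuant(sp.name, fid, float(ppm[best]), group_values, comparison))
    table_out = pd.DataFrame(
        rows, columns=["analyte", "feature_id", "group", "sample_id", "auc", "detected"]
    )
    return table_out, results
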