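"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes,
with ground truth returned alongside every dataset so recovery can be
scored:

* three-condition (PC/NC/NT) aligned feature tables with shared chemical
  background and planted tagged/native pairs at Δm = +24.000000 Da —
  lognormal intensity noise, normal mass jitter in ppm, normal RT jitter,
  and explicit missing values;
* grouped targeted tables (diet × colonization designs) with per-group
  fold changes planted on chosen analytes;
* Gaussian EIC traces with baseline and noise;
* two-population fluorescence event clouds with optional debris and
  doublet contamination.

Every generator is a pure function of its config: the same seed yields
byte-identical CSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chem import (
    DEFAULT_FATTY_ACIDS,
    MetaboliteSpecies,
    PROPARGYL_TAG,
    TagDefinition,
    apply_tag,
    build_acylcholine_library,
)
from .feature_io import FeatureTable
from .quant import EIC
from .sortgate import EventTable


@dataclass(frozen=True)
class PlantedPair:
    """A native species planted in NC samples with its tagged analog in PC."""

    native: MetaboliteSpecies
    mean_intensity: float
    rt: float


def default_planted_pairs() -> list[PlantedPair]:
    """The seven-acylcholine series at spread retention times."""
    natives = [s for s in build_acylcholine_library(DEFAULT_FATTY_ACIDS) if not s.tagged]
    rts = np.linspace(8.0, 16.0, len(natives))
    return [
        PlantedPair(native=sp, mean_intensity=1.0e6, rt=float(rt))
        for sp, rt in zip(natives, rts)
    ]


@dataclass
class SyntheticConfig:
    """Study-design parameters for the three-condition feature simulation.

    Defaults mirror the in-vitro design: 3 conditions × 3 replicates, the
    seven-acylcholine planted series over 90 shared background features,
    lognormal intensity noise at 20% CV, 1 ppm mass jitter and 0.05 min RT
    jitter.  ``missing_rate`` drops intensity cells independently at random;
    ``pc_replicate_missing_rate`` additionally drops planted tagged
    intensities in the first PC replicate only (single-injection dropout).
    """

    seed: int = 0
    n_background_features: int = 90
    planted_pairs: Optional[list[PlantedPair]] = None
    mass_jitter_ppm_sd: float = 1.0
    rt_jitter_sd: float = 0.05
    intensity_cv: float = 0.2
    missing_rate: float = 0.0
    pc_replicate_missing_rate: float = 0.0
    samples_per_condition: int = 3
    tag: TagDefinition = field(default_factory=lambda: PROPARGYL_TAG)
    mz_range: tuple[float, float] = (150.0, 900.0)
    rt_range: tuple[float, float] = (0.5, 20.0)
    background_mean_intensity: float = 2.0e5

    def __post_init__(self) -> None:
        for name in ("missing_rate", "pc_replicate_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.samples_per_condition < 1:
            raise ValueError("need at least one sample per condition")
        if self.planted_pairs is None:
            self.planted_pairs = default_planted_pairs()


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit median and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_feature_table(config: SyntheticConfig) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate an aligned three-condition feature table with planted pairs.

    Returns the table and a ground-truth frame (one row per planted pair:
    name, native/tagged feature ids, true m/z values, retention time).
    """
    rng = np.random.default_rng(config.seed)
    n_rep = config.samples_per_condition
    samples = {
        cond: [f"{cond}{i + 1}" for i in range(n_rep)] for cond in ("PC", "NC", "NT")
    }
    all_samples = samples["PC"] + samples["NC"] + samples["NT"]
    manifest = pd.DataFrame(
        {
            "sample_id": all_samples,
            "condition": ["PC"] * n_rep + ["NC"] * n_rep + ["NT"] * n_rep,
            "group": "",
            "replicate": list(range(1, n_rep + 1)) * 3,
        }
    ).set_index("sample_id")

    rows = []
    intens: dict[str, dict[str, float]] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:04d}"

    # shared chemical background: detected in every condition
    for _ in range(config.n_background_features):
        fid = new_id()
        mz = float(rng.uniform(*config.mz_range))
        rt = float(rng.uniform(*config.rt_range))
        base = config.background_mean_intensity * float(
            rng.lognormal(mean=0.0, sigma=0.8)
        )
        noise = _lognormal_factor(rng, config.intensity_cv, len(all_samples))
        rows.append({"feature_id": fid, "mz": mz, "rt": rt})
        intens[fid] = {s: base * noise[i] for i, s in enumerate(all_samples)}

    truth_rows = []
    for pair in config.planted_pairs:
        native_true = pair.native.theoretical_mz
        tagged_true = native_true + config.tag.mass_delta
        jit = rng.normal(0.0, config.mass_jitter_ppm_sd, size=2) * 1e-6
        native_mz = native_true * (1.0 + jit[0])
        tagged_mz = tagged_true * (1.0 + jit[1])
        native_rt = pair.rt
        tagged_rt = pair.rt + float(rng.normal(0.0, config.rt_jitter_sd))

        nid = new_id()
        rows.append({"feature_id": nid, "mz": native_mz, "rt": native_rt})
        noise = _lognormal_factor(rng, config.intensity_cv, n_rep)
        intens[nid] = {s: pair.mean_intensity * noise[i] for i, s in enumerate(samples["NC"])}

        tid = new_id()
        rows.append({"feature_id": tid, "mz": tagged_mz, "rt": tagged_rt})
        noise = _lognormal_factor(rng, config.intensity_cv, n_rep)
        intens[tid] = {s: pair.mean_intensity * noise[i] for i, s in enumerate(samples["PC"])}
        if config.pc_replicate_missing_rate > 0.0:
            if rng.uniform() < config.pc_replicate_missing_rate:
                intens[tid].pop(samples["PC"][0], None)

        truth_rows.append(
            {
                "name": pair.native.name.replace("-NC", ""),
                "native_id": nid,
                "tagged_id": tid,
                "native_mz": native_true,
                "tagged_mz": tagged_true,
                "rt": pair.rt,
            }
        )

    if config.missing_rate > 0.0:
        for fid in list(intens):
            for s in list(intens[fid]):
                if rng.uniform() < config.missing_rate:
                    del intens[fid][s]

    features = pd.DataFrame(rows).set_index("feature_id")[["mz", "rt"]]
    intensities = pd.DataFrame.from_dict(intens, orient="index").reindex(
        index=features.index, columns=all_samples
    )
    table = FeatureTable(features=features, intensities=intensities, manifest=manifest)
    truth = pd.DataFrame(
        truth_rows,
        columns=["name", "native_id", "tagged_id", "native_mz", "tagged_mz", "rt"],
    )
    return table, truth


def score_pairs(result_pairs, truth: pd.DataFrame) -> tuple[float, float]:
    """Precision and recall of recovered (tagged, native) id pairs."""
    found = {(p.tagged_feature_id, p.native_feature_id) for p in result_pairs}
    expected = set(zip(truth["tagged_id"], truth["native_id"]))
    if not found:
        return (1.0 if not expected else 0.0), 0.0 if expected else 1.0
    tp = len(found & expected)
    precision = tp / len(found)
    recall = tp / len(expected) if expected else 1.0
    return precision, recall


# ---------------------------------------------------------------------------
# Grouped targeted design (diet × colonization)
# ---------------------------------------------------------------------------

DEFAULT_GROUPS = ("choline-LR", "choline-GF", "MCD-LR", "MCD-GF")


@dataclass
class GroupDesignConfig:
    """Targeted four-group design with planted per-group fold changes.

    ``group_effects`` maps (group, analyte name) to a multiplicative fold
    change on that analyte's mean intensity in that group.  Defaults mirror
    a 4-group × 4-replicate animal design.
    """

    seed: int = 0
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 4
    targets: Optional[list[MetaboliteSpecies]] = None
    base_intensity: float = 1.0e6
    intensity_cv: float = 0.2
    mass_jitter_ppm_sd: float = 1.0
    group_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    n_background_features: int = 30

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ValueError("group comparisons need ≥2 replicates per group")


def generate_group_table(config: GroupDesignConfig) -> FeatureTable:
    """Simulate a grouped feature table for targeted quantification."""
    if not config.targets:
        raise ValueError("group design needs at least one target analyte")
    rng = np.random.default_rng(config.seed)
    sample_ids, conditions, groups_col, reps = [], [], [], []
    for g in config.groups:
        for r in range(1, config.replicates_per_group + 1):
            sample_ids.append(f"{g}-{r}")
            conditions.append("NT")
            groups_col.append(g)
            reps.append(r)
    manifest = pd.DataFrame(
        {"sample_id": sample_ids, "condition": conditions, "group": groups_col,
         "replicate": reps}
    ).set_index("sample_id")

    rows, intens = [], {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"G{counter:04d}"

    for _ in range(config.n_background_features):
        fid = new_id()
        rows.append({"feature_id": fid, "mz": float(rng.uniform(150, 900)),
                     "rt": float(rng.uniform(0.5, 20.0))})
        base = 1e5 * float(rng.lognormal(0.0, 0.8))
        noise = _lognormal_factor(rng, config.intensity_cv, len(sample_ids))
        intens[fid] = {s: base * noise[i] for i, s in enumerate(sample_ids)}

    for sp in config.targets:
        fid = new_id()
        jitter = float(rng.normal(0.0, config.mass_jitter_ppm_sd)) * 1e-6
        rows.append({"feature_id": fid, "mz": sp.theoretical_mz * (1 + jitter),
                     "rt": float(rng.uniform(1.0, 18.0))})
        vals = {}
        for i, s in enumerate(sample_ids):
            g = groups_col[i]
            fold = config.group_effects.get((g, sp.name), 1.0)
            vals[s] = config.base_intensity * fold * float(
                _lognormal_factor(rng, config.intensity_cv, 1)[0]
            )
        intens[fid] = vals

    features = pd.DataFrame(rows).set_index("feature_id")[["mz", "rt"]]
    intensities = pd.DataFrame.from_dict(intens, orient="index").reindex(
        index=features.index, columns=sample_ids
    )
    return FeatureTable(features=features, intensities=intensities, manifest=manifest)


# ---------------------------------------------------------------------------
# EIC traces
# ---------------------------------------------------------------------------

def generate_eic(
    amplitude: float,
    center: float,
    sigma: float,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    t_start: float = 0.0,
    t_end: float = 2.0,
    dt: float = 0.005,
    seed: int = 0,
    target_mz: float = 366.3367,
    tol_ppm: float = 10.0,
) -> EIC:
    """A Gaussian chromatographic peak plus constant baseline and noise."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if dt <= 0:
        raise ValueError("sampling interval must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(t_start, t_end + dt / 2, dt)
    y = amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2) + baseline
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(t))
    return EIC(target_mz=target_mz, tol_ppm=tol_ppm, time=t, intensity=np.clip(y, 0.0, None))


# ---------------------------------------------------------------------------
# Flow-cytometry event clouds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventPopulationParams:
    """Log-space locations/spreads for the synthetic event clouds."""

    fsc_a_mean: float = 50_000.0
    fsc_a_sigma: float = 0.25          # lognormal sigma
    ssc_a_mean: float = 30_000.0
    ssc_a_sigma: float = 0.30
    singlet_w_mean: float = 70.0
    singlet_w_sd: float = 5.0
    doublet_w_mean: float = 140.0
    doublet_w_sd: float = 10.0
    af647_neg_median: float = 100.0
    af647_neg_sigma: float = 0.4
    af647_pos_median: float = 5_000.0
    af647_pos_sigma: float = 0.5
    debris_fsc_a_median: float = 2_000.0
    debris_sigma: float = 0.5


def generate_events(
    n: int,
    pos_fraction: float,
    seed: int = 0,
    debris_fraction: float = 0.0,
    doublet_fraction: float = 0.0,
    params: EventPopulationParams = EventPopulationParams(),
) -> tuple[EventTable, np.ndarray]:
    """A labelled/unlabelled event mixture with optional contamination.

    ``pos_fraction`` is the labelled share *among intact single cells*;
    debris and doublets are added on top as fractions of ``n``.  Returns
    the table and per-event ground-truth labels
    (``pos``/``neg``/``debris``/``doublet``).
    """
    if n < 1:
        raise ValueError("need at least one event")
    if not (0.0 <= pos_fraction <= 1.0):
        raise ValueError("pos_fraction must be in [0, 1]")
    if debris_fraction + doublet_fraction > 1.0:
        raise ValueError("contamination fractions exceed 1")
    rng = np.random.default_rng(seed)

    n_debris = int(round(n * debris_fraction))
    n_doublet = int(round(n * doublet_fraction))
    n_cells = n - n_debris - n_doublet
    n_pos = int(round(n_cells * pos_fraction))
    n_neg = n_cells - n_pos

    labels = np.array(
        ["pos"] * n_pos + ["neg"] * n_neg + ["doublet"] * n_doublet + ["debris"] * n_debris
    )

    def cell_block(count: int, pos: bool, doublet: bool) -> pd.DataFrame:
        fsc_a = rng.lognormal(np.log(params.fsc_a_mean), params.fsc_a_sigma, count)
        ssc_a = rng.lognormal(np.log(params.ssc_a_mean), params.ssc_a_sigma, count)
        if doublet:
            fsc_a = fsc_a + rng.lognormal(np.log(params.fsc_a_mean), params.fsc_a_sigma, count)
            ssc_a = ssc_a + rng.lognormal(np.log(params.ssc_a_mean), params.ssc_a_sigma, count)
            w = rng.normal(params.doublet_w_mean, params.doublet_w_sd, count)
        else:
            w = rng.normal(params.singlet_w_mean, params.singlet_w_sd, count)
        w = np.clip(w, 1.0, None)
        fsc_h = fsc_a / w * rng.normal(1.0, 0.02, count) * params.singlet_w_mean
        ssc_h = ssc_a / w * rng.normal(1.0, 0.02, count) * params.singlet_w_mean
        if pos:
            af = rng.lognormal(np.log(params.af647_pos_median), params.af647_pos_sigma, count)
        else:
            af = rng.lognormal(np.log(params.af647_neg_median), params.af647_neg_sigma, count)
        return pd.DataFrame(
            {"FSC-A": fsc_a, "FSC-H": fsc_h, "FSC-W": w,
             "SSC-A": ssc_a, "SSC-H": ssc_h, "SSC-W": w, "AF647-A": af}
        )

    def debris_block(count: int) -> pd.DataFrame:
        fsc_a = rng.lognormal(np.log(params.debris_fsc_a_median), params.debris_sigma, count)
        ssc_a = rng.lognormal(np.log(params.debris_fsc_a_median / 2), params.debris_sigma, count)
        w = np.clip(rng.normal(params.singlet_w_mean, params.singlet_w_sd * 2, count), 1.0, None)
        af = rng.lognormal(np.log(params.af647_neg_median), params.af647_neg_sigma, count)
        return pd.DataFrame(
            {"FSC-A": fsc_a, "FSC-H": fsc_a / w * params.singlet_w_mean, "FSC-W": w,
             "SSC-A": ssc_a, "SSC-H": ssc_a / w * params.singlet_w_mean, "SSC-W": w,
             "AF647-A": af}
        )

    blocks = [
        cell_block(n_pos, pos=True, doublet=False),
        cell_block(n_neg, pos=False, doublet=False),
        cell_block(n_doublet, pos=rng.uniform() < pos_fraction, doublet=True),
        debris_block(n_debris),
    ]
    df = pd.concat([b for b in blocks if len(b)], ignore_index=True)
    return EventTable(df), labels


def generate_negative_control(
    n: int = 5_000, seed: int = 0, params: EventPopulationParams = EventPopulationParams()
) -> EventTable:
    """A no-stain control: unlabelled single cells only."""
    table, _ = generate_events(n, pos_fraction=0.0, seed=seed, params=params)
    return table
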