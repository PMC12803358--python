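"""Aligned LC-MS feature tables, sample manifests, and report writers.

A feature table is the aligned output of upstream peak detection (one row
per (m/z, retention time) feature, one intensity column per sample) plus a
manifest mapping each sample to its treatment condition — PC
(propargyl-analog treated), NC (native-compound treated), NT (untreated) —
and optionally a biological group for targeted comparisons.

Missing intensities stay missing (NaN), never zero: absence of a peak is
the signal the exclusivity filter keys on, so nothing is imputed at I/O
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("PC", "NC", "NT")

# Column aliases tolerated on read (MZmine exporter dialect and similar).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "row id": "feature_id",
    "row ID": "feature_id",
    "id": "feature_id",
    "row m/z": "mz",
    "row retention time": "rt",
    "m/z": "mz",
    "retention time": "rt",
    "rt (min)": "rt",
}


@dataclass
class FeatureTable:
    """Aligned features with per-sample intensities and a sample manifest.

    Attributes
    ----------
    features : DataFrame indexed by ``feature_id`` with columns ``mz`` (Da)
        and ``rt`` (minutes).
    intensities : DataFrame indexed by ``feature_id``, one column per
        sample; NaN marks a peak not detected in that sample.
    manifest : DataFrame indexed by ``sample_id`` with columns
        ``condition`` (PC/NC/NT), ``group`` (optional label) and
        ``replicate``.
    ms2 : optional mapping feature_id -> list of (fragment m/z, intensity).
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    manifest: pd.DataFrame
    ms2: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.features.index.duplicated().any():
            dupes = self.features.index[self.features.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.manifest.index.duplicated().any():
            raise ValueError("duplicate sample ids in manifest")
        unknown = set(self.intensities.columns) - set(self.manifest.index)
        if unknown:
            raise ValueError(f"intensity columns absent from manifest: {sorted(unknown)}")
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities must share the same feature ids")
        if (self.features["mz"] <= 0).any():
            raise ValueError("all m/z values must be positive")
        if (self.features["rt"] < 0).any():
            raise ValueError("retention times must be non-negative")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")
        bad = set(self.manifest["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions in manifest: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    def samples_in_condition(self, condition: str) -> list[str]:
        return list(self.manifest.index[self.manifest["condition"] == condition])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.manifest.index[self.manifest["group"] == group])

    def detected(self, min_intensity: float = 0.0) -> pd.DataFrame:
        """Boolean detection matrix: intensity present and > min_intensity."""
        vals = self.intensities
        return vals.notna() & (vals > min_intensity)

    def mz(self, feature_id: str) -> float:
        return float(self.features.at[feature_id, "mz"])

    def rt(self, feature_id: str) -> float:
        return float(self.features.at[feature_id, "rt"])


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing required columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = ""
    df["group"] = df["group"].fillna("")
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby("condition").cumcount() + 1
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in manifest")
    return df.set_index("sample_id")


def read_feature_table(
    path,
    manifest_path,
    column_map: Optional[Mapping[str, str]] = None,
    ms2_path=None,
) -> FeatureTable:
    """Read an aligned feature-table CSV and its sample manifest.

    The CSV needs ``feature_id``, ``mz`` and ``rt`` columns (exporter
    aliases such as "row m/z" are remapped) plus one intensity column per
    sample.  Empty cells become NaN, preserving missingness.
    """
    manifest = read_manifest(manifest_path)
    df = pd.read_csv(path)
    rename = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        rename.update(column_map)
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    required = {"feature_id", "mz", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing required columns: {sorted(missing)}")
    df["feature_id"] = df["feature_id"].astype(str)
    if df["feature_id"].duplicated().any():
        raise ValueError("duplicate feature ids in feature table")
    sample_cols = [c for c in df.columns if c not in ("feature_id", "mz", "rt")]
    unknown = set(sample_cols) - set(manifest.index)
    if unknown:
        raise ValueError(f"sample columns absent from manifest: {sorted(unknown)}")
    features = df.set_index("feature_id")[["mz", "rt"]].astype(float)
    intensities = df.set_index("feature_id")[sample_cols].astype(float)
    ms2 = read_ms2(ms2_path) if ms2_path else {}
    return FeatureTable(features=features, intensities=intensities, manifest=manifest, ms2=ms2)


def write_feature_table(table: FeatureTable, path, manifest_path=None) -> None:
    """Write a feature table (and optionally its manifest) back to CSV."""
    out = pd.concat([table.features, table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, float_format="%.6f")
    if manifest_path is not None:
        table.manifest.to_csv(manifest_path)


def read_ms2(path) -> dict[str, list[tuple[float, float]]]:
    """Read MS2 fragment lists from an MGF-like plain-text file.

    Blocks look like::

        BEGIN IONS
        FEATURE=F0012
        104.1070 350.0
        60.0808 120.0
        END IONS
    """
    spectra: dict[str, list[tuple[float, float]]] = {}
    current: Optional[str] = None
    frags: list[tuple[float, float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.upper() == "BEGIN IONS":
                current, frags = None, []
            elif line.upper() == "END IONS":
                if current is None:
                    raise ValueError("MS2 block without FEATURE= identifier")
                spectra[current] = frags
            elif "=" in line:
                key, value = line.split("=", 1)
                if key.strip().upper() in ("FEATURE", "TITLE"):
                    current = value.strip()
            else:
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"malformed fragment line: {line!r}")
                frags.append((float(parts[0]), float(parts[1])))
    return spectra


def write_ms2(spectra: Mapping[str, Sequence[tuple[float, float]]], path) -> None:
    with open(path, "w") as fh:
        for feature_id, frags in spectra.items():
            fh.write("BEGIN IONS\n")
            fh.write(f"FEATURE={feature_id}\n")
            for mz, inten in frags:
                fh.write(f"{mz:.6f} {inten:.4f}\n")
            fh.write("END IONS\n")


PAIR_REPORT_COLUMNS = [
    "tagged_feature_id",
    "native_feature_id",
    "tagged_mz",
    "native_mz",
    "delta_mz",
    "ppm_error_vs_tag",
    "rt_offset",
    "annotation",
    "ambiguous",
    "ms2_diagnostic",
    "score",
]


def write_pair_report(pairs: Iterable, path) -> pd.DataFrame:
    """Write tagged/native pairs to CSV in deterministic order.

    Rows are sorted by descending score, ties broken by ascending tagged
    m/z; an empty pair list yields a header-only file.  Returns the frame
    written.
    """
    rows = []
    for p in pairs:
        rows.append(
            {
                "tagged_feature_id": p.tagged_feature_id,
                "native_feature_id": p.native_feature_id if p.native_feature_id else "",
                "tagged_mz": p.tagged_mz,
                "native_mz": p.native_mz if p.native_mz is not None else np.nan,
                "delta_mz": p.delta_mz if p.delta_mz is not None else np.nan,
                "ppm_error_vs_tag": p.ppm_error_vs_tag if p.ppm_error_vs_tag is not None else np.nan,
                "rt_offset": p.rt_offset if p.rt_offset is not None else np.nan,
                "annotation": p.annotation.name if p.annotation is not None else "",
                "ambiguous": ";".join(s.name for s in p.ambiguous_annotations),
                "ms2_diagnostic": p.ms2_diagnostic.value if p.ms2_diagnostic is not None else "",
                "score": p.score,
            }
        )
    df = pd.DataFrame(rows, columns=PAIR_REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["score", "tagged_mz"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return df
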