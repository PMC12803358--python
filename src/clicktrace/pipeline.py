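"""End-to-end pipeline orchestration with deterministic, hashed outputs.

A single config drives the fixed stage order: ingest (or simulate) →
exclusivity filter → Δm pairing → library annotation → MS2 diagnostics →
pair report → optional targeted quantification.  Every output file records
the config hash so a run can be tied to its exact parameters; rerunning
with the same config and inputs reproduces identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

from . import chem, feature_io, quant, synthetic, tagfinder


@dataclass
class PipelineConfig:
    """Validated parameters for a full run; serialised verbatim to the log."""

    seed: int = 0
    features_path: Optional[str] = None   # None -> simulate
    manifest_path: Optional[str] = None
    ms2_path: Optional[str] = None
    library_path: Optional[str] = None    # None -> built-in acylcholine library
    targets: list[str] = field(default_factory=list)  # names from the library
    mz_tol_ppm: float = tagfinder.DEFAULT_MZ_TOL_PPM
    rt_tol_min: float = tagfinder.DEFAULT_RT_TOL_MIN
    quant_tol_ppm: float = quant.DEFAULT_QUANT_TOL_PPM
    min_detected_fraction_in: float = 0.75
    max_detected_fraction_out: float = 0.0
    min_intensity: float = 0.0
    alpha: float = 0.05
    require_partner: bool = True

    def validate(self) -> None:
        if self.mz_tol_ppm <= 0 or self.quant_tol_ppm <= 0:
            raise ValueError("mass tolerances must be positive")
        if self.rt_tol_min < 0:
            raise ValueError("RT tolerance must be non-negative")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if (self.features_path is None) != (self.manifest_path is None):
            raise ValueError("features and manifest must be given together")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir) -> dict[str, Any]:
    """Run all stages and write reports + a structured JSON log.

    Returns the log dict (also written to ``run_log.json``), which records
    the config, its hash, and the feature counts surviving each stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log: dict[str, Any] = {"config": asdict(config), "config_hash": chash, "stages": {}}

    # --- ingest -----------------------------------------------------------
    try:
        if config.features_path is None:
            table, truth = synthetic.generate_feature_table(
                synthetic.SyntheticConfig(seed=config.seed)
            )
            truth.to_csv(out / "ground_truth.csv", index=False)
        else:
            table = feature_io.read_feature_table(
                config.features_path, config.manifest_path, ms2_path=config.ms2_path
            )
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise StageError("ingest", exc) from exc
    log["stages"]["ingest"] = {
        "n_features": len(table.features),
        "n_samples": len(table.manifest),
    }

    # --- library ----------------------------------------------------------
    try:
        if config.library_path:
            library = chem.read_library_csv(config.library_path)
        else:
            library = chem.build_acylcholine_library()
    except Exception as exc:
        raise StageError("library", exc) from exc

    # --- exclusivity ------------------------------------------------------
    try:
        rule = tagfinder.ExclusivityRule(
            min_detected_fraction_in=config.min_detected_fraction_in,
            max_detected_fraction_out=config.max_detected_fraction_out,
            min_intensity=config.min_intensity,
        )
        candidates = tagfinder.condition_presence_filter(table, rule)
    except Exception as exc:
        raise StageError("exclusivity", exc) from exc
    log["stages"]["exclusivity"] = {"n_candidates": len(candidates)}

    # --- pairing / annotation / MS2 --------------------------------------
    try:
        result = tagfinder.find_tag_pairs(
            candidates,
            table,
            mz_tol_ppm=config.mz_tol_ppm,
            rt_tol=config.rt_tol_min,
            min_intensity=config.min_intensity,
            require_partner=config.require_partner,
        )
        records = tagfinder.annotate_pairs(
            result.all_records(), library, mz_tol_ppm=config.mz_tol_ppm
        )
        records = tagfinder.attach_ms2_diagnostics(records, table)
    except Exception as exc:
        raise StageError("pairing", exc) from exc
    n_paired = sum(1 for r in records if r.is_paired)
    log["stages"]["pairing"] = {
        "n_pairs": n_paired,
        "n_tagged_only": len(records) - n_paired,
        "n_annotated": sum(1 for r in records if r.annotation is not None),
    }
    pairs_path = out / "pairs.csv"
    feature_io.write_pair_report(records, pairs_path)

    # --- targeted quantification -----------------------------------------
    if config.targets:
        try:
            by_name = {s.name: s for s in library}
            missing = [t for t in config.targets if t not in by_name]
            if missing:
                raise ValueError(f"targets not in library: {missing}")
            qtable, qresults = quant.quant_report(
                table,
                [by_name[t] for t in config.targets],
                mz_tol_ppm=config.quant_tol_ppm,
                alpha=config.alpha,
            )
        except Exception as exc:
            raise StageError("quant", exc) from exc
        qtable.to_csv(out / "quant.csv", index=False, float_format="%.6f")
        log["stages"]["quant"] = {
            "n_targets": len(config.targets),
            "n_detected": sum(1 for r in qresults if r.detected),
        }

    for path in out.glob("*.csv"):
        _stamp_hash(path, chash)
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return log


def _stamp_hash(path: Path, chash: str) -> None:
    """Prefix a CSV report with a comment line carrying the config hash."""
    text = path.read_text()
    if text.startswith("# config_hash"):
        return
    path.write_text(f"# config_hash={chash}\n{text}")
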