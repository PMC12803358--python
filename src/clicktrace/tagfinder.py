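"""Comparative tag detection: exclusivity filtering and +24 Da pairing.

The operative definition of a tag-derived metabolite is comparative:

1. *Exclusivity* — a feature must be detected in (nearly all) analog-treated
   (PC) samples and in (essentially) none of the native-treated (NC) or
   untreated (NT) samples.  Shared chemical background fails this
   immediately.
2. *Pairing* — a surviving candidate gains confidence if the table contains
   a native partner: a feature detected in NC samples whose m/z sits exactly
   one tag mass below (Δm = +24.000000 Da for the propargyl tag) at a
   similar retention time.

Candidates with no partner are reported as *tagged-only*; in host-tissue
extracts the analog itself (propargylcholine) appears without a co-detected
native counterpart, so partnerless detection is first-class, not a failure
mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .chem import MetaboliteSpecies, TagDefinition, PROPARGYL_TAG, ppm_error
from .feature_io import FeatureTable

DEFAULT_MZ_TOL_PPM = 5.0
DEFAULT_RT_TOL_MIN = 0.5


@dataclass(frozen=True)
class ExclusivityRule:
    """Detection-pattern filter for candidate tagged features.

    ``min_detected_fraction_in`` is the fraction of PC samples in which a
    feature must be detected; the required count is ``max(1,
    floor(fraction * n_PC))``, so with three replicates the default 0.75
    demands two — a single dropped injection is not fatal.
    ``max_detected_fraction_out`` bounds detections among NC and NT samples
    (the default 0 permits none).  "Detected" means present (not missing)
    and strictly above ``min_intensity``.
    """

    min_detected_fraction_in: float = 0.75
    max_detected_fraction_out: float = 0.0
    min_intensity: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_detected_fraction_in <= 1.0):
            raise ValueError("min_detected_fraction_in must be in [0, 1]")
        if not (0.0 <= self.max_detected_fraction_out <= 1.0):
            raise ValueError("max_detected_fraction_out must be in [0, 1]")

    def required_in(self, n_in: int) -> int:
        return max(1, math.floor(self.min_detected_fraction_in * n_in + 1e-9))

    def allowed_out(self, n_out: int) -> int:
        return math.floor(self.max_detected_fraction_out * n_out + 1e-9)


class MS2Diagnostic(str, Enum):
    SUPPORTED = "supported"
    UNSUPPORTED = "unsupported"
    NO_MS2 = "no_ms2"


@dataclass
class TagPair:
    """A matched tagged/native feature pair (or a tagged-only record).

    ``ppm_error_vs_tag`` is the deviation of the observed Δm from the tag's
    exact mass delta, expressed in ppm of the tagged m/z.  ``score`` is
    1 − |ppm error|/tolerance for paired records (1 = perfect mass match)
    and 0 for tagged-only records.
    """

    tagged_feature_id: str
    tagged_mz: float
    tagged_rt: float
    native_feature_id: Optional[str] = None
    native_mz: Optional[float] = None
    native_rt: Optional[float] = None
    delta_mz: Optional[float] = None
    ppm_error_vs_tag: Optional[float] = None
    rt_offset: Optional[float] = None
    annotation: Optional[MetaboliteSpecies] = None
    ambiguous_annotations: tuple[MetaboliteSpecies, ...] = ()
    ms2_diagnostic: Optional[MS2Diagnostic] = None
    score: float = 0.0

    @property
    def is_paired(self) -> bool:
        return self.native_feature_id is not None

    def check_invariants(self, mz_tol_ppm: float) -> None:
        if not np.isfinite(self.score):
            raise AssertionError("pair score must be finite")
        if self.is_paired and abs(self.ppm_error_vs_tag) > mz_tol_ppm + 1e-9:
            raise AssertionError("paired Δm error exceeds tolerance")


@dataclass
class PairingResult:
    """Outcome of a pairing run: matched pairs plus tagged-only candidates."""

    pairs: list[TagPair]
    tagged_only: list[TagPair]

    def all_records(self) -> list[TagPair]:
        return self.pairs + self.tagged_only


def condition_presence_filter(
    table: FeatureTable, rule: ExclusivityRule = ExclusivityRule()
) -> list[str]:
    """Feature ids detected per the exclusivity rule, in table order."""
    pc = table.samples_in_condition("PC")
    if not pc:
        raise ValueError("manifest contains no PC samples")
    out_samples = table.samples_in_condition("NC") + table.samples_in_condition("NT")
    detected = table.detected(rule.min_intensity)
    need_in = rule.required_in(len(pc))
    allow_out = rule.allowed_out(len(out_samples))
    n_in = detected[pc].sum(axis=1)
    n_out = detected[out_samples].sum(axis=1) if out_samples else 0
    keep = (n_in >= need_in) & (n_out <= allow_out)
    return [fid for fid in table.feature_ids if keep[fid]]


def _native_candidates(table: FeatureTable, min_intensity: float) -> list[str]:
    """Features detected in at least one NC sample (potential native partners)."""
    nc = table.samples_in_condition("NC")
    if not nc:
        return []
    det = table.detected(min_intensity)[nc].any(axis=1)
    return [fid for fid in table.feature_ids if det[fid]]


def find_tag_pairs(
    candidates: Sequence[str],
    table: FeatureTable,
    tag: TagDefinition = PROPARGYL_TAG,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol: float = DEFAULT_RT_TOL_MIN,
    min_intensity: float = 0.0,
    require_partner: bool = True,
) -> PairingResult:
    """Match candidate tagged features to native partners one tag mass below.

    For each candidate the search spans features detected in ≥1 NC sample
    whose m/z satisfies ``|(candidate.mz − partner.mz) − Δm_tag| ≤ tol`` (in
    ppm of the candidate m/z) and ``|ΔRT| ≤ rt_tol``.  Among several
    admissible partners the winner is deterministic: minimum |Δm error|,
    then minimum |ΔRT|, then lowest native m/z.  Candidates without a
    partner become tagged-only records; with ``require_partner=False``
    (tissue mode) they are still scored for annotation downstream.
    """
    if mz_tol_ppm <= 0:
        raise ValueError("mz_tol_ppm must be positive")
    if rt_tol < 0:
        raise ValueError("rt_tol must be non-negative")

    natives = _native_candidates(table, min_intensity)
    native_mz = np.array([table.mz(f) for f in natives])
    native_rt = np.array([table.rt(f) for f in natives])

    pairs: list[TagPair] = []
    tagged_only: list[TagPair] = []
    for cid in candidates:
        cmz, crt = table.mz(cid), table.rt(cid)
        tol_da = mz_tol_ppm * 1e-6 * cmz
        best: Optional[tuple] = None
        if len(natives):
            dm_err = np.abs((cmz - native_mz) - tag.mass_delta)
            rt_off = np.abs(crt - native_rt)
            ok = (dm_err <= tol_da) & (rt_off <= rt_tol)
            for idx in np.flatnonzero(ok):
                if natives[idx] == cid:
                    continue
                key = (dm_err[idx], rt_off[idx], native_mz[idx])
                if best is None or key < best[0]:
                    best = (key, idx)
        if best is None:
            tagged_only.append(TagPair(tagged_feature_id=cid, tagged_mz=cmz, tagged_rt=crt))
            continue
        idx = best[1]
        delta = cmz - native_mz[idx]
        ppm = 1e6 * (delta - tag.mass_delta) / cmz
        pairs.append(
            TagPair(
                tagged_feature_id=cid,
                tagged_mz=cmz,
                tagged_rt=crt,
                native_feature_id=natives[idx],
                native_mz=float(native_mz[idx]),
                native_rt=float(native_rt[idx]),
                delta_mz=float(delta),
                ppm_error_vs_tag=float(ppm),
                rt_offset=float(crt - native_rt[idx]),
                score=1.0 - abs(ppm) / mz_tol_ppm,
            )
        )
    for p in pairs:
        p.check_invariants(mz_tol_ppm)
    return PairingResult(pairs=pairs, tagged_only=tagged_only)


def annotate_pairs(
    records: Sequence[TagPair],
    library: Sequence[MetaboliteSpecies],
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
) -> list[TagPair]:
    """Attach the closest-m/z library species (within tolerance) to each record.

    Only tagged library entries are candidates for the tagged feature's m/z.
    Two entries at exactly equal |ppm| make the match ambiguous: both are
    reported and no single annotation is chosen.
    """
    if not library:
        raise ValueError("annotation library is empty")
    tagged_entries = [s for s in library if s.tagged]
    out: list[TagPair] = []
    for rec in records:
        matches: list[tuple[float, MetaboliteSpecies]] = []
        for sp in tagged_entries:
            ppm = abs(ppm_error(rec.tagged_mz, sp.theoretical_mz))
            if ppm <= mz_tol_ppm:
                matches.append((ppm, sp))
        if not matches:
            out.append(replace(rec, annotation=None, ambiguous_annotations=()))
            continue
        matches.sort(key=lambda t: (t[0], t[1].theoretical_mz, t[1].name))
        best_ppm = matches[0][0]
        tied = [sp for ppm, sp in matches if abs(ppm - best_ppm) < 1e-12]
        if len(tied) > 1:
            out.append(replace(rec, annotation=None, ambiguous_annotations=tuple(tied)))
        else:
            out.append(replace(rec, annotation=tied[0], ambiguous_annotations=()))
    return out


def ms2_tag_check(
    fragments: Optional[Sequence[tuple[float, float]]],
    tag: TagDefinition = PROPARGYL_TAG,
    frag_tol_ppm: float = 10.0,
) -> MS2Diagnostic:
    """Classify an MS2 spectrum by its headgroup diagnostic fragment.

    ``supported`` if any fragment matches the tagged headgroup (128.1070 for
    the propargylcholine headgroup) within tolerance; ``unsupported`` if
    only the native headgroup (104.1070) or neither is present; ``no_ms2``
    when no spectrum is attached.
    """
    if frag_tol_ppm <= 0:
        raise ValueError("frag_tol_ppm must be positive")
    if fragments is None or len(fragments) == 0:
        return MS2Diagnostic.NO_MS2
    for mz, _ in fragments:
        if abs(ppm_error(mz, tag.diagnostic_fragment_tagged)) <= frag_tol_ppm:
            return MS2Diagnostic.SUPPORTED
    return MS2Diagnostic.UNSUPPORTED


def attach_ms2_diagnostics(
    records: Sequence[TagPair],
    table: FeatureTable,
    tag: TagDefinition = PROPARGYL_TAG,
    frag_tol_ppm: float = 10.0,
) -> list[TagPair]:
    return [
        replace(
            rec,
            ms2_diagnostic=ms2_tag_check(
                table.ms2.get(rec.tagged_feature_id), tag, frag_tol_ppm
            ),
        )
        for rec in records
    ]


def decoy_delta_scan(
    candidates: Sequence[str],
    table: FeatureTable,
    tag: TagDefinition = PROPARGYL_TAG,
    decoy_offsets: Sequence[float] = (-1.0, +1.0),
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol: float = DEFAULT_RT_TOL_MIN,
) -> dict[float, int]:
    """Optional diagnostic: pair counts at off-by-one mass deltas.

    Searching Δm = tag ± 1 Da gives an empirical null for chance pairing;
    comparable counts at the decoy deltas would flag the true-delta pairs as
    unreliable.  Off by default in the pipeline.
    """
    counts: dict[float, int] = {}
    for off in decoy_offsets:
        decoy = TagDefinition(
            name=f"decoy{off:+g}",
            formula_delta=tag.formula_delta,
            diagnostic_fragment_native=tag.diagnostic_fragment_native,
            diagnostic_fragment_tagged=tag.diagnostic_fragment_tagged,
        )
        # shift the searched delta without touching formula bookkeeping
        result = _find_pairs_at_delta(
            candidates, table, tag.mass_delta + off, mz_tol_ppm, rt_tol
        )
        counts[tag.mass_delta + off] = len(result)
    return counts


def _find_pairs_at_delta(
    candidates: Sequence[str],
    table: FeatureTable,
    delta: float,
    mz_tol_ppm: float,
    rt_tol: float,
) -> list[tuple[str, str]]:
    natives = _native_candidates(table, 0.0)
    out = []
    for cid in candidates:
        cmz, crt = table.mz(cid), table.rt(cid)
        tol_da = mz_tol_ppm * 1e-6 * cmz
        for nid in natives:
            if nid == cid:
                continue
            if abs((cmz - table.mz(nid)) - delta) <= tol_da and abs(crt - table.rt(nid)) <= rt_tol:
                out.append((cid, nid))
                break
    return out
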