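"""Exclusivity filtering, Δm pairing vs an exhaustive oracle, annotation, MS2."""

import numpy as np
import pytest

from clicktrace import synthetic, tagfinder
from clicktrace.chem import PROPARGYL_TAG, build_acylcholine_library
from clicktrace.tagfinder import (
    ExclusivityRule,
    MS2Diagnostic,
    annotate_pairs,
    condition_presence_filter,
    find_tag_pairs,
    ms2_tag_check,
)

from conftest import make_manifest, make_table


# ---------------------------------------------------------------------------
# Exhaustive all-pairs oracle: applies the documented predicates directly.
# ---------------------------------------------------------------------------

def oracle_pairs(candidates, table, tag, mz_tol_ppm, rt_tol, min_intensity=0.0):
    nc = table.samples_in_condition("NC")
    det = table.detected(min_intensity)
    natives = [f for f in table.feature_ids if det.loc[f, nc].any()]
    result = {}
    for cid in candidates:
        cmz, crt = table.mz(cid), table.rt(cid)
        admissible = []
        for nid in natives:
            if nid == cid:
                continue
            dm_err = abs((cmz - table.mz(nid)) - tag.mass_delta)
            rt_off = abs(crt - table.rt(nid))
            if dm_err <= mz_tol_ppm * 1e-6 * cmz and rt_off <= rt_tol:
                admissible.append((dm_err, rt_off, table.mz(nid), nid))
        if admissible:
            result[cid] = min(admissible)[3]
    return result


def simple_table():
    manifest = make_manifest(
        [(f"{c}{i}", c, "") for c in ("PC", "NC", "NT") for i in (1, 2, 3)]
    )
    pc = {"PC1": 1e6, "PC2": 1e6, "PC3": 1e6}
    nc = {"NC1": 1e6, "NC2": 1e6, "NC3": 1e6}
    everywhere = {f"{c}{i}": 1e5 for c in ("PC", "NC", "NT") for i in (1, 2, 3)}
    return make_table(
        [
            ("tagged", 366.3368, 9.8, pc),
            ("native", 342.3368, 9.75, nc),
            ("bg", 250.0, 5.0, everywhere),
            ("orphan", 500.0001, 12.0, pc),
        ],
        manifest,
    )


class TestExclusivity:
    def test_pc_exclusive_retained_background_rejected(self):
        table = simple_table()
        kept = condition_presence_filter(table)
        assert kept == ["tagged", "orphan"]

    def test_planted_vs_background_brute_force(self):
        cfg = synthetic.SyntheticConfig(seed=7, n_background_features=90)
        table, truth = synthetic.generate_feature_table(cfg)
        rule = ExclusivityRule()
        kept = condition_presence_filter(table, rule)
        # brute force: re-derive the expected set feature by feature
        pc = table.samples_in_condition("PC")
        out = table.samples_in_condition("NC") + table.samples_in_condition("NT")
        expected = []
        for fid in table.feature_ids:
            row = table.intensities.loc[fid]
            n_in = int(((row[pc].notna()) & (row[pc] > 0)).sum())
            n_out = int(((row[out].notna()) & (row[out] > 0)).sum())
            if n_in >= 2 and n_out == 0:
                expected.append(fid)
        assert kept == expected
        assert set(kept) == set(truth["tagged_id"])

    def test_requires_pc_samples(self):
        manifest = make_manifest([("NC1", "NC", ""), ("NT1", "NT", "")])
        table = make_table([("a", 100.0, 1.0, {"NC1": 1.0})], manifest)
        with pytest.raises(ValueError, match="PC"):
            condition_presence_filter(table)

    def test_min_intensity_threshold_is_strict(self):
        manifest = make_manifest([("PC1", "PC", ""), ("NC1", "NC", "")])
        table = make_table([("a", 100.0, 1.0, {"PC1": 10.0})], manifest)
        assert condition_presence_filter(table, ExclusivityRule(min_intensity=10.0)) == []
        assert condition_presence_filter(table, ExclusivityRule(min_intensity=9.9)) == ["a"]

    def test_single_pc_dropout_tolerated_at_default_fraction(self):
        """With 3 PC replicates and the 0.75 default, 2 detections suffice."""
        manifest = make_manifest(
            [(f"{c}{i}", c, "") for c in ("PC", "NC") for i in (1, 2, 3)]
        )
        table = make_table(
            [("a", 100.0, 1.0, {"PC1": 1e5, "PC2": 1e5})], manifest
        )
        assert condition_presence_filter(table) == ["a"]


class TestPairing:
    def test_canonical_pair(self):
        table = simple_table()
        res = find_tag_pairs(["tagged", "orphan"], table)
        assert len(res.pairs) == 1
        p = res.pairs[0]
        assert (p.tagged_feature_id, p.native_feature_id) == ("tagged", "native")
        assert p.delta_mz == pytest.approx(24.0, abs=1e-4)
        assert abs(p.ppm_error_vs_tag) < 1.0
        assert [t.tagged_feature_id for t in res.tagged_only] == ["orphan"]

    def test_matches_exhaustive_oracle_on_synthetic_tables(self):
        for seed in range(5):
            cfg = synthetic.SyntheticConfig(seed=seed, n_background_features=90)
            table, _ = synthetic.generate_feature_table(cfg)
            cands = condition_presence_filter(table)
            res = find_tag_pairs(cands, table)
            got = {p.tagged_feature_id: p.native_feature_id for p in res.pairs}
            assert got == oracle_pairs(cands, table, PROPARGYL_TAG, 5.0, 0.5)

    def test_tie_break_ppm_then_rt_then_native_mz(self):
        manifest = make_manifest([("PC1", "PC", ""), ("NC1", "NC", "")])
        # two partners with identical |Δm error|; closer RT must win
        table = make_table(
            [
                ("cand", 400.0, 10.0, {"PC1": 1e5}),
                ("near_rt", 376.0, 10.1, {"NC1": 1e5}),
                ("far_rt", 376.0, 10.4, {"NC1": 1e5}),
            ],
            manifest,
        )
        res = find_tag_pairs(["cand"], table, mz_tol_ppm=10.0, rt_tol=0.5)
        assert res.pairs[0].native_feature_id == "near_rt"
        # identical Δm and RT: lowest native m/z wins
        table2 = make_table(
            [
                ("cand", 400.0, 10.0, {"PC1": 1e5}),
                ("heavy", 376.001, 10.0, {"NC1": 1e5}),
                ("light", 375.999, 10.0, {"NC1": 1e5}),
            ],
            manifest,
        )
        res2 = find_tag_pairs(["cand"], table2, mz_tol_ppm=10.0, rt_tol=0.5)
        assert res2.pairs[0].native_feature_id == "light"

    def test_widening_tolerances_never_removes_pairs(self):
        cfg = synthetic.SyntheticConfig(seed=3, mass_jitter_ppm_sd=2.0)
        table, _ = synthetic.generate_feature_table(cfg)
        cands = condition_presence_filter(table)
        narrow = find_tag_pairs(cands, table, mz_tol_ppm=2.0, rt_tol=0.1)
        wide = find_tag_pairs(cands, table, mz_tol_ppm=10.0, rt_tol=1.0)
        narrow_ids = {p.tagged_feature_id for p in narrow.pairs}
        wide_ids = {p.tagged_feature_id for p in wide.pairs}
        assert narrow_ids <= wide_ids

    def test_invalid_tolerances(self):
        table = simple_table()
        with pytest.raises(ValueError):
            find_tag_pairs([], table, mz_tol_ppm=0.0)
        with pytest.raises(ValueError):
            find_tag_pairs([], table, rt_tol=-1.0)


class TestAnnotation:
    def test_closest_species_wins(self):
        table = simple_table()
        res = find_tag_pairs(["tagged"], table)
        lib = build_acylcholine_library()
        annotated = annotate_pairs(res.pairs, lib)
        assert annotated[0].annotation.name == "C16:0-PC"

    def test_out_of_range_unannotated(self):
        table = simple_table()
        res = find_tag_pairs(["orphan"], table, rt_tol=0.5)
        annotated = annotate_pairs(res.tagged_only, build_acylcholine_library())
        assert annotated[0].annotation is None

    def test_exact_tie_flagged_ambiguous(self):
        from clicktrace.chem import MetaboliteSpecies, parse_formula

        sp_a = MetaboliteSpecies("iso-A", parse_formula("C23H44NO2"), tagged=True)
        sp_b = MetaboliteSpecies("iso-B", parse_formula("C23H44NO2"), tagged=True)
        table = simple_table()
        res = find_tag_pairs(["tagged"], table)
        annotated = annotate_pairs(res.pairs, [sp_a, sp_b])
        assert annotated[0].annotation is None
        assert {s.name for s in annotated[0].ambiguous_annotations} == {"iso-A", "iso-B"}

    def test_empty_library_errors(self):
        with pytest.raises(ValueError):
            annotate_pairs([], [])


class TestMS2:
    def test_tagged_headgroup_supported(self):
        assert ms2_tag_check([(128.1071, 350.0), (86.0964, 100.0)]) is MS2Diagnostic.SUPPORTED

    def test_native_headgroup_only_unsupported(self):
        assert ms2_tag_check([(104.1070, 50.0)]) is MS2Diagnostic.UNSUPPORTED

    def test_no_spectrum(self):
        assert ms2_tag_check(None) is MS2Diagnostic.NO_MS2
        assert ms2_tag_check([]) is MS2Diagnostic.NO_MS2

    def test_diagnostic_fragments_differ_by_tag_mass(self):
        assert PROPARGYL_TAG.diagnostic_fragment_tagged - \
            PROPARGYL_TAG.diagnostic_fragment_native == pytest.approx(24.0, abs=1e-9)
        assert PROPARGYL_TAG.diagnostic_fragment_native == pytest.approx(104.1070, abs=5e-4)
        assert PROPARGYL_TAG.diagnostic_fragment_tagged == pytest.approx(128.1070, abs=5e-4)


def test_decoy_deltas_find_no_partners_in_clean_table():
    cfg = synthetic.SyntheticConfig(seed=11)
    table, _ = synthetic.generate_feature_table(cfg)
    cands = condition_presence_filter(table)
    counts = tagfinder.decoy_delta_scan(cands, table)
    assert all(v == 0 for v in counts.values())
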