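# clicktrace

Comparative mass-tag metabolomics for bioorthogonal dietary tracers, plus the
flow-sort gating that accompanies click-chemistry labeling experiments.

## The problem

Feeding a host (or a bacterial culture) an alkyne-bearing analog of a
nutrient — here propargylcholine, choline with one N-methyl replaced by a
propargyl group — marks every downstream metabolite of that nutrient with a
fixed monoisotopic mass offset. For the propargyl tag the offset is a formula
delta of two carbons, hence **Δm = +24.000000 Da exactly** (carbon-12 defines
the mass scale). Tag-derived metabolites in an aligned LC-MS feature table can
then be found with no prior knowledge of their identity:

1. **Exclusivity** — the feature is detected in the analog-treated condition
   (PC) and absent from native-treated (NC) and untreated (NT) controls;
2. **Pairing** — its native counterpart, made when the unmodified nutrient is
   fed, sits exactly one tag mass below at a similar retention time:
   `|(m/z_tagged − m/z_native) − 24.000000| ≤ tol_ppm` and `|ΔRT| ≤ tol_RT`;
3. **Annotation** — the tagged m/z is matched against an exact-mass candidate
   library (long-chain acylcholines by default, e.g. palmitoylcholine
   C21H44NO2⁺ at m/z 342.3367 and its propargyl analog C23H44NO2⁺ at
   366.3367), with an MS2 headgroup diagnostic (104.1070 native / 128.1070
   tagged) as confirmation.

The package also covers the two supporting analyses such experiments use:
targeted quantification (trapezoidal EIC peak areas compared across diet ×
colonization groups with one-way ANOVA + Tukey HSD) and the hierarchical
flow-cytometry gating used to sort labeled from unlabeled cells
(debris → SSC singlets → FSC singlets → AF647 threshold from a no-stain
control quantile). A seeded synthetic-data module generates every input with
ground truth, so precision/recall of the whole pipeline is measurable.

Intended users: microbiome / metabolomics researchers running click-chemistry
tracer studies who have MZmine-style aligned feature tables and want a
reproducible, testable implementation of the comparative analysis.

## Worked example

Simulate the in-vitro design (3 conditions × 3 replicates, 90 background
features, the seven-acylcholine planted series), then run the detection:

```sh
$ clicktrace simulate features --seed 1 --out demo
wrote 104 features, 9 samples -> demo
$ clicktrace pairs --features demo/features.csv --manifest demo/manifest.csv --out demo/pairs.csv
7 candidates, 7 paired, 0 tagged-only -> demo/pairs.csv
$ head -3 demo/pairs.csv
tagged_feature_id,native_feature_id,tagged_mz,native_mz,delta_mz,ppm_error_vs_tag,rt_offset,annotation,ambiguous,ms2_diagnostic,score
F0096,F0095,394.367797,370.367916,23.999881,-0.301749,0.036767,C18:0-PC,,no_ms2,0.939650
F0094,F0093,366.336525,342.336338,24.000187,0.510460,0.042178,C16:0-PC,,no_ms2,0.897908
```

All seven planted tagged/native pairs are recovered: each row shows the
observed mass difference (`delta_mz` ≈ 24 Da, within ~0.5 ppm of exact), the
retention-time offset, and the exact-mass annotation (here stearoyl- and
palmitoyl-propargylcholine). `score` is 1 − |ppm error|/tolerance.

Gating a synthetic 60% labeled event cloud:

```sh
$ clicktrace simulate events --n 20000 --pos-fraction 0.6 --seed 2 --out demo_ev
$ clicktrace gate --events demo_ev/events.csv --control demo_ev/control.csv --out demo_ev/gates.json
AF647+ 0.603 / AF647- 0.397 -> demo_ev/gates.json
```

The AF647 threshold (267.7 intensity units) is the 99.5% quantile of the
no-stain control; the recovered positive fraction 0.603 matches the planted
0.6 within binomial sampling error at n = 20,000.

The full pipeline (`clicktrace run --seed 7 --out run/`) chains simulation or
ingest, exclusivity, pairing, annotation, MS2 diagnostics and targeted
quantification, stamping every report with the config hash so reruns are
verifiably identical.

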