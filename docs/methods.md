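# Methods

## Exact-mass model

All theoretical m/z values are computed from an embedded CODATA/NIST
monoisotopic atomic mass table (C = 12 exactly, H = 1.00782503207,
N = 14.0030740048, O = 15.9949146196, P = 30.97376163, …) with electron-mass
correction for ions:

    m/z = (Σ nᵢ·Mᵢ − z·mₑ) / |z|,   mₑ = 0.000548580 Da.

Choline and its fatty-acid esters (acylcholines) are permanent
quaternary-ammonium cations detected as [M]⁺, so no adduct enumeration is
performed. The electron-mass correction matters: omitting it shifts a
~350 Da cation by ~1.6 ppm, which is visible at the sub-ppm agreement this
package reaches against observed values (theory 342.33666 vs observed
342.3368 for palmitoylcholine, +0.4 ppm).

The propargyl tag is a formula delta of C2 (propargyl C3H3 replacing methyl
CH3), giving a mass delta of exactly +24.000000 Da; this exactness is what
makes the pairing step a near-zero-tolerance test rather than a fuzzy match.
Acyl esters are built as choline + fatty acid − H2O; the hydroxylated chain
"C18(OH)" is modelled as hydroxy-stearoyl (18:0 + one O) because the degree
of unsaturation of that species is not constrained by exact mass alone — the
hydroxyl flag and double-bond count are configurable if a different reading
is wanted. Lysophosphatidylcholines are zwitterions, not permanent cations;
they are represented through their protonated [M+H]⁺ cation formula
(glycerophosphocholine + fatty acid − H2O + H) so that the single `charge`
convention covers them too. Both monoisotopic and average-mass m/z are
exposed: low-resolution targeted methods quote averaged values (choline at
m/z ≈ 104.2) while the pipeline itself always works monoisotopically
(104.1070).

## Exclusivity and pairing

"Detected" means an intensity that is present (not missing) and strictly
greater than `min_intensity`; missing cells are never imputed because
absence is exactly the information the comparative filter uses.

A candidate tagged feature must be detected in at least
`max(1, floor(min_detected_fraction_in × n_PC))` PC samples (default
fraction 0.75, i.e. 2 of 3 replicates) and in at most
`floor(max_detected_fraction_out × n_out)` NC/NT samples (default 0, i.e.
none). The floor reading of the PC threshold is deliberate: with small
replicate counts, requiring the ceiling would make a single dropped
injection disqualify a genuinely exclusive feature, and the pipeline's
recall target under single-replicate dropout depends on tolerating exactly
that failure mode.

Partner search is restricted to features detected in at least one NC sample
— the native counterpart can only exist where the native nutrient was fed.
Defaults are 5 ppm mass tolerance (on the tagged m/z) and 0.5 min RT
tolerance; typical for a 140,000-resolution Orbitrap and sub-minute
alignment, since no instrument-specific values are forced by the method
itself. Ties between admissible partners are broken deterministically:
smallest |Δm error|, then smallest |ΔRT|, then lowest native m/z. Candidates
without a partner are reported as *tagged-only* rather than dropped: in host
tissues the analog itself appears without a co-detected native partner, so
partnerless detection is a first-class outcome. An optional decoy scan at
Δm ± 1 Da provides an empirical chance-pairing null; no FDR over pairs is
estimated beyond that.

Annotation assigns the closest library species by |ppm| within tolerance,
considering only tagged library entries for tagged features (this matters:
C16:0-PC and C18:2-NC share the formula C23H44NO2 and are exactly isobaric).
An exact |ppm| tie is flagged ambiguous and both candidates are reported.
The MS2 diagnostic checks for the choline headgroup fragments: 128.1070
(tagged) ⇒ supported, 104.1070 only or neither ⇒ unsupported, no spectrum ⇒
no_ms2.

## Quantification and testing

EIC peaks are integrated with the trapezoid rule on (intensity − baseline)
clipped at zero; window endpoints are linearly interpolated so the integral
is exact for piecewise-linear traces, and the truncation error is O(h²) in
the sampling interval. `linear_endpoints` baseline mode subtracts the
straight line through the trace values at the window edges.

Group comparisons follow the standard targeted-metabolomics pattern: one-way
ANOVA (scipy `f_oneway`) followed by Tukey's HSD (scipy `tukey_hsd`,
studentized-range based, Tukey–Kramer for unequal n) at a family-wise alpha
(default 0.05). The unadjusted pairwise p reported alongside is the
pooled-variance (Fisher LSD) test on the same error term — the correct
comparator for the guarantee that the Tukey-adjusted p is never smaller.
Intensities are compared on the raw AUC scale by default (matching
Prism-style analyses); a log10 option exists. Degenerate inputs are defined
rather than NaN: all observations identical ⇒ F = 0, p = 1, no significant
pairs; zero within-group variance with unequal means ⇒ p = 0 for the
differing pairs. An analyte is called *elevated* in a group only when that
group's mean exceeds every other group's with a Tukey-adjusted p below
alpha for each such pair. The default EIC extraction width for targeted
matching is 10 ppm, configurable.

## Gating

Gates are axis-aligned bounds applied hierarchically — debris rectangle on
(FSC-A, SSC-A), singlet bounds on SSC-W/SSC-H then FSC-W/FSC-H, and finally
an AF647-A threshold — with each fraction reported relative to its parent
gate, so counts are monotone non-increasing down the hierarchy by
construction. The threshold is the 0.995 quantile of a no-stain control by
default, i.e. a ~0.5% accepted false-positive rate that must be kept in mind
when interpreting small positive fractions. Fluorescence is handled on the
linear scale; any display transform never changes fractions. Native FCS
binary parsing is out of scope — events enter as CSV with configurable
column names.

## Synthetic data: what it emulates and what it does not

The feature generator mirrors the in-vitro comparative design: 3 conditions
(PC/NC/NT) × 3 replicates, 90 shared background features, and the
seven-acylcholine planted series (14:0, 16:0, 18:0, 18:1, 18:2, 18(OH),
19:1), each pair a native feature in NC and a tagged feature at native m/z
+ 24.000000 in PC. Noise structure is the standard LC-MS error model:
multiplicative lognormal intensity noise (default CV 0.2), normal mass
jitter in ppm (default σ = 1 ppm), normal RT jitter (default σ = 0.05 min),
and iid missing-value dropout; `pc_replicate_missing_rate` models dropout of
a single PC injection. The grouped generator mirrors a 4-group × 4-replicate
diet × colonization animal design with multiplicative per-group fold changes
on chosen analytes. Event clouds are lognormal scatter/fluorescence
mixtures with optional debris (low scatter) and doublets (summed area,
inflated width).

What the generators do **not** model — and hence what passing recovery tests
do not demonstrate about real data: correlated (batch/drift) intensity
error, intensity-dependent missingness, co-eluting isomers and isotope
envelopes, chromatographic peak-shape pathology, ion suppression,
fluorescence spillover/compensation, and instrument-specific gate
geometries. Printed experimental percentages and gene lists from sorted
in-vivo material depend on deposited instrument data and are outside what
synthetic recovery can or should reproduce; the tests instead verify the
*procedures* (recovery of planted truth at known noise, calibration of the
test statistics under the null, qualitative reproduction of the
four-LPC-in-one-group pattern on planted effects).

All generators are pure functions of their config: one integer seed drives
`numpy.random.default_rng`, and identical configs give byte-identical CSV.

## Problem sizes and numerical choices

Default simulated problem sizes — 104-feature tables, 2,000-replicate null
calibrations for the ANOVA/Tukey machinery, 20,000-event clouds across 5
seeds — were chosen as the smallest designs at which the binomial/KS
acceptance bands are meaningful. Statistical recovery assertions use 3
standard-error bands (plus the threshold's designed false-positive rate
where it applies). Tie-breaks throughout (partner choice, annotation,
report ordering) are fully deterministic so reports are reproducible
byte-for-byte; report rows order by descending score then ascending tagged
m/z.

## Known limitations

- Exact mass alone cannot distinguish isomers (e.g. positional acyl
  isomers, or the saturation state of the hydroxylated C18 chain);
  annotation is a candidate assignment, not an identification — MS2 and
  standards remain the arbiter.
- The exclusivity filter is binary on detection; a tagged metabolite that
  leaks into controls at trace level (carry-over) would be rejected.
- Tukey HSD assumes within-group normality and homoscedasticity; raw-scale
  AUC comparisons inherit whatever skew the data carry unless the log
  option is used.
- Gate bounds are user- or control-derived; the package does not infer gate
  geometry from data.
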