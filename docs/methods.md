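# Methods

This note documents the models behind `uromark`, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Coordinate and data conventions

All internal coordinates are 0-based, half-open; conversions to the
1-based bismark-coverage and GFF3 dialects happen only in `uromark.io`.
CpGs are keyed by cytosine position; duplicate records for one position
(e.g. strand-split extractor output) are merged by summing counts rather
than rejected. Missing values (age, stage, marker concentration) are
explicit NaN/None, never silent zeros; a missing marker measurement
propagates to a missing marker call.

## DMR discovery

The scan tiles each chromosome with non-overlapping windows at each
configured scale (defaults 200 bp and 1000 bp). "Sliding" window scans
are sometimes run with sub-window steps; tiling was chosen as the
default because it is deterministic, cheap, and the cross-scale merge
already provides overlapping coverage of any signal region — a smaller
step per scale remains available through `WindowConfig.steps`.

A window is emitted only if **every** sample contributes at least
`min_cpgs_per_window` (4) CpGs at coverage ≥ `min_coverage_per_cpg`
(10); this guarantees group means are computed over the same genomic
support in all samples rather than over shifting sample subsets. The
per-sample window level is the **unweighted mean of per-CpG β values**,
not the pooled-count ratio, so a single high-coverage CpG cannot
dominate a window.

The filter keeps windows with β ≥ `min_target_beta` (0.4) in at least
`min_target_fraction` (75%) of target lines and β > `max_offtarget_beta`
(0.1) in at most `max_offtarget_fraction` (0%) of off-target lines.
These four numbers are exposed as configuration: they encode the
qualitative published design (methylated in the target tumor type,
silent in off-target tumor types) with explicit, testable defaults.

Overlap-merging is strict on half-open intervals: windows sharing ≥ 1 bp
merge (transitively, across scales); abutting windows do not. The merge
is idempotent and order-invariant, verified against an O(n²) union-find
oracle. TSS distance is 0 for a TSS inside the candidate and otherwise
the gap to the nearest interval edge; a candidate is *distal* when the
distance strictly exceeds 1500 bp. Candidates on chromosomes absent
from the annotation carry a missing distance, not a zero.

## Marker statistics

AUC is the Mann–Whitney *U* statistic normalized by n₁·n₂ (ties count
0.5) with the two-sided rank-sum p-value; the degenerate all-equal input
returns AUC 0.5, p 1. Threshold calibration searches the midpoints
between consecutive distinct pooled values plus one candidate beyond
each extreme, keeps those with specificity **strictly** greater than the
floor (default 0.95), and among them maximizes sensitivity, breaking
ties toward higher specificity and then the higher threshold. The
strict inequality is deliberate: with 20 controls, 19/20 = 0.95 fails
"> 0.95", so the threshold must clear every control. Marker positivity
is `value > threshold`; ties at the threshold are negative. Both
choices must be fixed somewhere for reproducibility; they are fixed
here, and the calibration is verified against exhaustive search.

Calibration controls default to healthy controls only; other-cancer
controls enter evaluation, not calibration.

## Panel scoring

With complete calls, the count of methylated markers partitions into
NEGATIVE (0), INCONCLUSIVE (1..k−1) and POSITIVE (≥ k), default k = 2 of
8. With missing calls the rule is conservative and asymmetric: POSITIVE
stands as soon as observed positives reach k (more data cannot retract
it), but NEGATIVE is never assigned in the presence of a missing call,
because only a certain 0/8 result spares a cystoscopy; everything else
is INCONCLUSIVE. `cutoff_search` evaluates every k with
conclusive-only sensitivity/specificity and the conclusive rate; the
recommended k maximizes Youden's J × conclusive rate by default. That
utility is an explicit stand-in for the informal "best combination of
sensitivity, specificity and conclusive results" criterion; the full
table is always returned so callers can apply their own rule.

## Diagnostic evaluation

Sensitivity and specificity are computed over conclusive results only;
an empty conclusive group leaves the metric undefined (None), never 0.
Confidence intervals are exact Clopper–Pearson (95%); exact coverage at
n = 89, p = 0.92 is 0.952, verified by enumeration over the binomial
pmf. Predictive values always come from the Bayes identities

    PPV = sens·π / (sens·π + (1−spec)(1−π))
    NPV = spec·(1−π) / (spec·(1−π) + (1−sens)·π)

at the assumed prevalence π (default 0.20 for gross-hematuria
patients), never from cohort column totals — the cohort case fraction
(34.1% in the hematuria composition) is not the clinical prevalence.
Note that at sens = 82/89 and spec = 154/165 the formula gives
NPV = 97.94%; published summaries of these operating points sometimes
quote 98.1%, which does not follow from the formula at π = 0.20 — this
package reports the formula value. The spared-cystoscopy fraction is
true negatives over **all** tested patients; inconclusive patients
count as requiring cystoscopy.

The age-dependence check splits cases at the median age into two
equally sized groups (median ties to the lower group) and runs a
two-sided Wilcoxon rank-sum test per marker; fewer than 4 cases is
flagged underpowered with no p-values. Its type-I error is verified by
null simulation.

## Synthetic data

### Cell-line methylomes (`simulate_rrbs`)

Sixteen lines by default (8 target-cancer, 8 off-target-cancer). CpG
positions are shared across lines: gaps are a two-component exponential
mixture (60% short gaps, mean 20 bp, emulating CpG-dense islands; the
rest long, tuned so the overall mean gap is 150 bp). Coverage is
negative-binomial with mean 111.6× and dispersion 5 — the study-scale
depth — and per-CpG counts are beta-binomial around the CpG's latent β
with concentration 30. Background β is a two-mode Beta mixture
(unmethylated Beta(1.5, 15), methylated Beta(12, 3), 40% methylated),
giving a genome-wide mean near 37%. Planted DMRs override the latent β
per group (defaults: target 0.85, off-target 0.03, 600–1000 bp spans,
one CpG per ~40 bp). The off-target default of 0.03 keeps the planted
truth cleanly inside the 0.1 off-target filter ceiling given
beta-binomial noise; at 0.05 a few percent of clean windows would fail
the zero-tolerance off-target rule by sampling noise alone, which is a
property of the filter, not of the generator. The default of 20,000
CpGs (6,000 in the recovery tests) is a desk-scale genome: per-window
statistics are unaffected by total genome size.

What this generator does *not* emulate: read-level artifacts,
incomplete bisulfite conversion, copy-number effects, strand-specific
biases, and the enzymatic fragment-selection footprint of real RRBS.
Passing recovery tests therefore demonstrate correctness of the window
arithmetic and filter logic under realistic count noise, not robustness
to these artifacts.

### Urine cohorts (`simulate_urine_cohort`)

A two-part model per marker: positivity, then concentration. Each case
carries a latent shedding variable z ~ N(0, 1); marker i is truly
positive with probability sigmoid(bᵢ + σ·z), where the intercept bᵢ is
solved by Gauss–Hermite quadrature so the **marginal** sensitivity
equals the configured value exactly (defaults 0.54–0.73 across the 8
markers). The shared z induces the within-patient marker correlation
that the panel exploits; σ defaults to 2.0, chosen by quadrature of the
conclusive-sensitivity integral so the ≥ 2/8 rule attains ≈ 0.94
cohort sensitivity (the 0.92–0.96 design band) at the default marker
sensitivities. With σ = 0 markers are conditionally independent and
the panel would be implausibly near-perfect.

Control false positives are independent assay noise at rate
1 − specificity (healthy-control defaults 0.95–0.96; other-cancer
controls get a 1.5× false-positive odds multiplier, widening evaluation
specificity toward the 0.94–0.98 range without touching calibration).
Concentrations: true positives are log-normal (median 300, σ 0.8)
boosted by 0.8·z; control false positives log-normal (median 15);
negative markers are zero with probability 0.7 and trace background
(median 1.5) otherwise. Units are methylated copies per reaction,
arbitrary but internally consistent — only threshold ordering matters.

Cohort presets mirror the two study arms: discovery (26 cases, 56
healthy, 30 other-cancer; stage mix Ta 12, T2 4, T3 4, T4 1, CIS 5;
grade 8 low / 18 high) and hematuria (93 cases of 273, i.e. 34.1%;
stage mix Ta 43, T1 31, T2 9, T3 1, T4 2, CIS 7; grade 29 low / 61
high / 3 missing). Stage and grade are sampled independently of
shedding by default; `stage_shedding_delta` optionally shifts shedding
upward with invasive stage to emulate a stage gradient in sensitivity.
Not emulated: DNA-yield failures, collection-protocol differences,
assay batch effects, and any real marker-specific biology — marker
labels m1..m8 are anonymous.

## Problem sizes

Tests and the acceptance script run the generators at desk scale:
6,000–8,000 CpGs and 16 lines for discovery recovery (recall and
precision of planted DMRs aggregated over 10–20 seeds), 2,000 patients
for calibration-recovery checks, and the preset cohort sizes (112 and
273) elsewhere. These sizes were chosen so the full suite completes in
well under a minute while every statistical check retains at least 3-SE
resolution.

## Known limitations

- The window filter is a deterministic rule set, not a statistical DMR
  test; no multiple-testing machinery is attached to discovery.
- Threshold calibration on small control sets is coarse: with 56
  healthy controls, the strict "> 0.95" constraint allows at most two
  control exceedances, so calibrated thresholds often sit above every
  control and calibrated specificity saturates at 1.0.
- The inconclusive band makes reported accuracy conditional on a
  conclusive result; comparisons against two-state tests must account
  for the conclusive rate, which is why every summary carries it.
- Predictive values inherit the assumed prevalence; they are not
  estimates from the cohort composition.
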