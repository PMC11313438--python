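# Methods

This note records the models, the defaults and the genuinely open design
choices made in `ffrfe`, in the spirit of a model-documentation page.

## Study design being emulated

The pipeline targets patient-nested quantitative proteomics of human
follicular fluid: each donor contributes 2–3 individually collected
fluids, each fluid is measured in replicate, and each fluid is labelled by
the morphological quality (good/fair/poor) of the blastocyst its oocyte
produced.  The default cohort dimensions — 50 donors, 110 fluids, 3
replicates (330 rows), 484 quantified proteins, class sizes 44/39/27 — are
the fixed study conditions of the design the package reimplements, not
tuning knobs.

## Embryo grading

Quality is a total three-way partition of well-formed morphology records:

* **good** — blastocyst by day 5 *and* trophectoderm (TE) grade 1;
* **fair** — blastocyst by day 6, or TE grade 2 at day 5 or 6, unless the
  embryo already qualified as good.  A day-5 blastocyst with TE grade 2 is
  therefore fair, not poor: the TE-2 clause is an explicit fair criterion;
* **poor** — everything else (arrested embryos, TE grade 3).

A TE grade without a blastocyst stage is contradictory and rejected.  The
grader implements only these three clauses; it is not a full Istanbul
consensus scorer and does no day-1/day-3 assessment.

## Synthetic-data generator

Replicate-level log2 abundance is `b_j + u_pj + e_cj + ε`:

| term | meaning | default |
|------|---------|---------|
| `b_j` | protein baseline (log2 units) | Uniform(10, 20) |
| `u_pj` | patient random effect, N(0, σ_p²), one draw per (patient, protein) | σ_p = 0.28 |
| `e_cj` | planted per-class effect (log2) | none |
| `ε` | replicate noise, N(0, sd_j²) | see below |

`sd_j = s₀ · (A_ref / A_j)^α` with `s₀ = 0.4` log2 units at the reference
abundance `A_ref = 2^15` (the midpoint of the baseline range) and
`α = 0.5`, so a protein 7× above reference is measured with roughly 2×
smaller log-scale error — the qualitative abundance/error relationship
seen in real acquisitions.  Class labels are assigned per fluid with
exact largest-remainder counts (44/39/27 at the default size) rather than
i.i.d. draws, matching the fixed class sizes of the emulated study, and
independently of patient.  Morphology records are generated backwards from
the class label (good → day-5/TE-1; fair → one of day-6/TE-1, day-5/TE-2,
day-6/TE-2; poor → arrested or day-5/TE-3) so grading round-trips exactly.

Only the log-normal family is modelled: no missing values, no
peptide-level structure, no immunodepletion artefacts, no heavy-tailed or
multimodal proteins.  Passing tests on this generator therefore show that
the *pipeline machinery* behaves correctly under the assumed statistical
structure; they do not certify performance on real spectra.

Two single-protein presets reproduce the two patient-effect regimes the
association layer is designed to distinguish.  Their constants were set
analytically from the variance decomposition of the model above
(fluid-level within-patient variance ≈ 0.449·sd_j² from the median of
three replicates, plus the planted class-effect variance) so that the
expected one-way patient-ANOVA adjusted R² is ≈ 0.95 ("IgA1-like": high
abundance, σ_p = 0.85, lower in good-quality fluids) and ≈ 0.30
("DKK3-like": σ_p = 0.28, higher in good-quality fluids).

## Normalization and aggregation

1. **Total-sum normalization**: each replicate row is rescaled so its
   protein sum equals a target (default: median of raw row sums) — the
   standard total-area-sums step for this kind of data.
2. **Replicate aggregation**: per fluid, the median over replicates of
   log2 abundance.  All downstream analysis is fluid-level (110 rows) by
   default; the replicate-level mode remains available, and LOPO folding
   prevents leakage in either mode.
3. **Second-pass normalization**: the cross-sample step in such workflows
   is typically performed in Perseus without a canonical definition; the
   closest standard operation — median-centring each fluid's log2 vector —
   is implemented and can be switched off (`median_center: false`).

Fold changes are computed from fluid-level linear medians per class,
reference = poor, reported as log2 ratios; using fluid-level values avoids
replicate pseudo-replication.

## Forest

Gini impurity, split search and MDI are implemented exactly as defined in
the package README.  Numerical choices:

* thresholds are midpoints of consecutive distinct sorted values; the
  split rule is strict `x < t`;
* ties in mean child impurity break to the lowest feature index, then the
  lowest threshold; argmax prediction ties break to the first class in
  (good, fair, poor) order — all for determinism;
* a split must decrease impurity by more than `impurity_tol = 1e-12`
  (the "no significant improvement" stopping rule made concrete);
* `min_samples_leaf` counts raw samples, not weighted mass;
* per-tree training subsets are drawn **without** replacement
  (`bootstrap_fraction = 0.8`); a classical bootstrap
  (with replacement, fraction 1.0) is available.  The subset size per
  tree has no canonical value, so it is exposed as a parameter;
* class weights are normalized so Σw = N, which makes MDI values
  comparable across class balances (MDI is invariant to global weight
  rescaling regardless);
* randomness flows from one root seed through counter-based
  `SeedSequence.spawn`, so results are independent of evaluation order.

## RFECV and protein scores

One feature is eliminated per RFE step (a step-size parameter exists for
speed but defaults to 1).  Per fold, the model is refit at every feature
count from p down to 1 and scored on the held-out patient; fold curves are
averaged, and the optimal count maximizes the mean curve with ties broken
toward fewer features (parsimony).

Balanced accuracy within a fold is averaged over the classes present in
that fold's test patient only: with 2–3 fluids per patient most folds lack
at least one class, and dropping absent classes is the only definition
that keeps the statistic finite.  This estimator is chance-calibrated at
1/3 under label permutation (verified by the acceptance suite).

**Score accumulation.**  Each cycle iterates the select-and-restrict loop:
run the RFE/CV pass, add 1 to each selected protein's score, restrict the
active set to the selection, repeat until one feature remains (if a pass
selects the entire active set, the least important feature is dropped so
the loop always contracts).  Scores are summed over independent cycles.
Under this reading persistent proteins accumulate scores far exceeding the
cycle count, which is the behaviour required for score scales in the
hundreds at ~30 cycles; a strict one-increment-per-cycle rule could not
produce such values.  This accumulation rule is a design choice of this
package; alternative readings would rescale the scores.

Label permutations for the null are uniform over fluids, independent of
patient, preserving class counts exactly.  The null table keeps the
per-permutation score matrix; the comparison plot shows the mean sorted
null curve against the observed sorted scores.  Because scores within a
run compete (informative features suppress the scores of noise features),
run-level summaries — not pooled per-protein scores — are the
exchangeable unit for null-vs-null comparisons.

## Association layer

* **Patient ANOVA**: fixed-effects one-way decomposition;
  adjusted R² = 1 − (1 − R²)(n − 1)/(n − k).  Heteroscedasticity is probed
  with Levene's test (median-centred) across patients with ≥ 2 fluids, and
  residual normality with Shapiro–Wilk on pooled residuals — both standard
  small-n choices; the tests used in the original analysis are not named,
  so these are the package's picks.  No mixed-effects modelling is
  attempted.
* **Dichotomization**: the stump minimizes the same weighted mean Gini as
  a tree's top split, with inverse-class-size weights for consistency with
  the forest.  "High" means value ≥ threshold; thresholds are midpoints,
  so ties cannot occur on training data.  When composed into the odds
  ratio each arm must hold at least 10% of the fluids
  (`min_leaf_fraction = 0.1`) — without this a strongly patient-driven
  protein occasionally isolates an arm containing no good or poor fluids,
  leaving the 2×2 table degenerate.
* **Odds ratio**: the stump is learned on all three classes, then the 2×2
  table counts good/poor fluids in the high/low arms (the fair class is
  excluded from the table but not from the threshold).  The saturated
  Poisson log-linear model's interaction term equals the closed-form
  cross-product ratio, which is what the implementation computes; an
  iteratively fitted GLM serves as a cross-check oracle in the tests, not
  as the implementation.  Per-protein results are reported uncorrected
  for multiple testing — the null-curve comparison, not FDR control, is
  the calibration instrument of this pipeline.

## Problem sizes in the test suite

Tests that need many refits run on deliberately reduced panels chosen as
desk-scale stand-ins for the full design: the planted-signal rank-recovery
check uses a 25-protein panel over 20 patients with 7–8 fluids each
(≈ 5× the per-patient sampling of the default design, 10 seeds), and the
chance-calibration check uses the full 110-fluid, 484-protein cohort with
20 label permutations.  Forest parameters scale accordingly (e.g. 25
trees, minimum leaf 10 on 150-fluid panels); the study-default parameters
are used whenever the full-size cohort is used.

## Known limitations

* The generator's independence assumptions (classes independent of
  patients, proteins independent given patient) are simplifications; real
  cohorts correlate both.
* The forest excludes entropy criteria, regression trees and majority
  voting by design; they are out of scope, not missing features.
* Scores are integers accumulated under one specific reading of the
  select-and-restrict loop; other readings would rescale them.
* The Poisson OR analysis implements the good/poor sub-table reading; a
  three-level quality factor with an interaction read off for good vs
  poor is a plausible alternative the package does not implement.
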