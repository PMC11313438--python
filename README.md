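# ffrfe — follicular-fluid proteome feature selection

`ffrfe` is a reusable, tested implementation of a machine-learning analysis
pipeline for follicular-fluid (hFF) proteomics in assisted reproduction.
The scientific question: can the protein composition of the fluid
surrounding a developing oocyte predict the morphological quality of the
blastocyst that oocyte will produce after fertilisation?  The setting is a
patient-nested cohort — each oocyte donor contributes several individually
collected fluids, each fluid is measured in replicate by quantitative mass
spectrometry (SWATH-MS style), and each fluid is labelled good/fair/poor by
the quality of its embryo.

Because such datasets are rarely deposited, the package ships a first-class
synthetic-cohort generator that reproduces the study design it targets
(50 donors, 2–3 fluids each, 110 fluids, 3 replicates, 484 quantified
proteins, class sizes 44/39/27, log-normal abundances with patient random
effects and abundance-dependent measurement error), so every stage of the
analysis is testable end to end.

## The method

**Weighted random forest (written from scratch).**  Depth-limited
classification trees on weighted samples, with sample weights inversely
proportional to class size (rescaled to sum to *N*).  Node impurity is the
weighted Gini index

H(Q) = Σᵢ pᵢ(1 − pᵢ),  i ∈ {good, fair, poor},

where pᵢ are weighted class frequencies.  A split on feature *xᵢ* at
threshold *t* (samples with xᵢ < t go left) minimises the weighted mean
child impurity G = (w_L·H(Q_L) + w_R·H(Q_R)) / w.  The ensemble predicts by
averaging leaf class distributions (not majority vote), and features are
ranked by Mean Decrease in Impurity,

MDI_T(x) = Σ_{m ∈ T, split on x} p(m)·Δi(m),  p(m) = w_m / w,

averaged over trees.  Default forest: 50 trees, depth ≤ 3, ≥ 30 samples
per leaf, √p features per split, 80% subsample per tree.

**Patient-wise RFECV.**  Cross-validation is leave-one-patient-out (LOPO):
every fold holds out *all* fluids of one patient, so correlated
within-patient samples never leak between training and test.  Recursive
feature elimination drops the least MDI-important protein one at a time,
scoring each feature count by balanced accuracy (mean per-class recall) on
the held-out patient; curves are averaged over folds and the best count
selected.  Repeating the select-and-restrict loop over many cycles
accumulates an integer **score** per protein — proteins that survive
elimination longest score highest.  A **permutation null** repeats the
whole procedure with quality labels shuffled across fluids; genuinely
informative panels show a characteristic kink of high scores above a
near-linear null curve.

**Association statistics.**  Per protein: one-way patient-effect ANOVA of
per-fluid log2 medians (adjusted R², F test, Levene and Shapiro–Wilk
diagnostics); a weighted-Gini decision stump that dichotomizes fluids into
high/low abundance at a learned threshold; and the good-vs-poor odds ratio
of high abundance, read off the interaction term of a saturated Poisson
log-linear model of the 2×2 count table (closed form (a·d)/(b·c), Wald
p-value, Haldane–Anscombe correction when a cell is empty).  Fold-change
tables report per-protein log2 ratios of class median abundances against
the poor class.

## Worked example

```python
import ffrfe

# a small cohort with one informative protein planted at index 0
cfg = ffrfe.CohortConfig(
    n_patients=10, fluids_per_patient_range=(3, 4), n_fluids=34,
    n_replicates=2, n_proteins=10, patient_effect_sd=0.2, seed=5,
    planted_proteins=[ffrfe.PlantedEffect(0, (1.2, 0.6, 0.0))],
)
cohort = ffrfe.generate_cohort(cfg)
fluids = ffrfe.aggregate_replicates(cohort.abundance)
proteins = cohort.protein_ids
x = fluids[proteins].to_numpy()
y = ffrfe.encode_labels(
    cohort.metadata.set_index("fluid_id")["quality"].reindex(fluids["fluid_id"])
)
patients = fluids["patient_id"].to_numpy()
params = ffrfe.ForestParams(n_trees=15, max_depth=3, min_samples_leaf=4)

sel = ffrfe.rfe_curve(x, y, patients, params, seed=2)
print("optimal feature count:", sel.n_optimal)
print("selected:", [proteins[j] for j in sel.selected])

table = ffrfe.accumulate_scores(x, y, patients, params, n_cycles=2, seed=6)
print("scores:", table.scores.tolist())
acc = ffrfe.cv_model_accuracy(x, y, patients, sel.selected, params, seed=1)
print("LOPO balanced accuracy:", round(acc, 3))
```

prints

```
optimal feature count: 1
selected: ['prot0000']
scores: [2, 0, 0, 0, 0, 0, 0, 0, 0, 0]
LOPO balanced accuracy: 0.908
```

— cross-validated elimination finds that a single protein, the planted
one, carries all the signal: the accuracy curve peaks at one feature, the
select-and-restrict loop collapses straight onto `prot0000` in both
cycles (score 2, everything else 0), and a forest restricted to it
predicts held-out patients' embryo quality with 91% balanced accuracy
(chance is 33%).  On weaker, many-protein signals the scores spread out
and the sorted score curve develops the kink that separates informative
proteins from the permutation-null trend.

The same flow is available from the shell:

```bash
ffrfe simulate --seed 1 --out cohort
ffrfe run --seed 1 --out results      # select -> null -> assoc -> foldchange
ffrfe assoc cohort/abundance.csv cohort/morphology.csv --out assoc.csv
```

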