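"""Patient-wise recursive feature elimination with cross-validation.

The selection engine works at the fluid level: every fluid contributes one
row (its log2-median protein profile) and is labelled by the quality of the
embryo it produced.  Because fluids from one patient are correlated,
cross-validation is leave-one-patient-out (LOPO): each fold holds out *all*
fluids of one patient, so no patient ever appears on both sides of a fold.

RFE inner loop (per fold): fit the weighted forest, record balanced
accuracy on the held-out patient, drop the least MDI-important feature,
repeat down to a single feature.  The per-fold accuracy curves are averaged
over folds; the feature count with the highest mean balanced accuracy is
selected, and the top features (by a full-data fit) form the selection.

Protein scores: the select-and-restrict loop (select the optimal subset,
increment each selected protein's score, restrict to the subset, repeat
until one feature remains) is run for a number of independent cycles and
the increments summed.  Under this rule persistent features accumulate
scores far larger than the cycle count.  A permutation null repeats the
whole procedure with quality labels randomly permuted across fluids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .forest import ForestModel, ForestParams, fit_forest

MAX_SEED = 2**31 - 1


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0]) & MAX_SEED


def lopo_folds(patient_ids: Sequence) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-patient-out folds over rows.

    Returns one ``(train_idx, test_idx)`` pair per patient, ordered by
    sorted patient id.  Test sets partition the rows.
    """
    patients = np.asarray(patient_ids)
    unique = np.unique(patients)
    if unique.size < 2:
        raise ValueError("leave-one-patient-out needs at least two patients")
    folds = []
    all_idx = np.arange(patients.size)
    for pid in unique:
        mask = patients == pid
        folds.append((all_idx[~mask], all_idx[mask]))
    return folds


def balanced_accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Unweighted mean of per-class recall over classes present in y_true."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("balanced accuracy of empty input is undefined")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(float(np.mean(y_pred[mask] == cls)))
    return float(np.mean(recalls))


@dataclass
class SelectionResult:
    """Outcome of one RFE-with-CV pass.

    ``feature_counts`` (descending) and ``mean_scores`` form the
    cross-validated balanced-accuracy curve; ``n_optimal`` maximizes the
    curve (ties -> fewest features); ``selected`` are column indices into
    the input matrix, the ``n_optimal`` most important features of a final
    full-data fit whose importances are in ``final_importances``.
    """

    feature_counts: np.ndarray
    mean_scores: np.ndarray
    n_optimal: int
    selected: np.ndarray
    final_importances: np.ndarray


def _elimination_order(importances: np.ndarray, active: np.ndarray, n_drop: int) -> np.ndarray:
    """Indices (into ``active``) of the ``n_drop`` least important features.

    Ties in importance break by dropping the highest original feature index.
    """
    order = np.lexsort((-active, importances))
    return order[:n_drop]


def rfe_curve(
    x: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence,
    params: ForestParams,
    *,
    step: int = 1,
    seed: int = 0,
) -> SelectionResult:
    """One full RFE pass with LOPO cross-validation.

    Per fold and per feature count the forest is refit from scratch;
    balanced accuracy on the held-out patient is recorded, then the
    ``step`` least-important features are dropped (default 1).  Fold curves
    are averaged per feature count, the argmax picked (ties -> fewest
    features) and the final selection read off a full-data fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    p = x.shape[1]
    if p < 1:
        raise ValueError("need at least one feature")
    folds = lopo_folds(patient_ids)
    root = np.random.SeedSequence(seed)
    fold_seeds = root.spawn(len(folds))
    final_seed = root.spawn(1)[0]

    counts: list[int] = []
    k = p
    while True:
        counts.append(k)
        if k == 1:
            break
        k = max(1, k - step)
    scores = np.zeros((len(folds), len(counts)))

    for f, (train, test) in enumerate(folds):
        iter_seeds = fold_seeds[f].spawn(len(counts))
        active = np.arange(p)
        for c, k in enumerate(counts):
            assert active.size == k
            model = _fit(
                x[np.ix_(train, active)], y[train], params, _seed_int(iter_seeds[c])
            )
            pred = model.predict(x[np.ix_(test, active)])
            scores[f, c] = balanced_accuracy(y[test], pred)
            if k > 1:
                drop = _elimination_order(
                    model.feature_importances_, active, active.size - counts[c + 1]
                )
                active = np.delete(active, drop)

    mean_scores = scores.mean(axis=0)
    # argmax; ties -> fewest features (counts are descending, so last argmax)
    best = np.flatnonzero(mean_scores == mean_scores.max())[-1]
    n_optimal = counts[best]
    final = _fit(x, y, params, _seed_int(final_seed))
    imp = final.feature_importances_
    keep = np.lexsort((np.arange(p), -imp))[:n_optimal]
    return SelectionResult(
        feature_counts=np.asarray(counts),
        mean_scores=mean_scores,
        n_optimal=n_optimal,
        selected=np.sort(keep),
        final_importances=imp,
    )


def _fit(x: np.ndarray, y: np.ndarray, params: ForestParams, seed: int) -> ForestModel:
    from dataclasses import replace

    return fit_forest(x, y, replace(params, seed=seed))


@dataclass
class ScoreTable:
    """Per-protein selection scores accumulated over RFECV cycles."""

    scores: np.ndarray
    n_cycles: int
    seed: int
    permuted: bool = False
    n_permutations: int = 0
    per_permutation: Optional[np.ndarray] = field(default=None, repr=False)

    def ranks(self) -> np.ndarray:
        """Rank per protein: 0 = highest score (ties -> lower index first)."""
        order = np.lexsort((np.arange(self.scores.size), -self.scores))
        ranks = np.empty_like(order)
        ranks[order] = np.arange(order.size)
        return ranks

    def sorted_scores(self) -> np.ndarray:
        return np.sort(self.scores)[::-1]


def accumulate_scores(
    x: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence,
    params: ForestParams,
    n_cycles: int,
    *,
    step: int = 1,
    seed: int = 0,
) -> ScoreTable:
    """Protein scores from repeated select-and-restrict RFECV cycles.

    Each cycle starts from the full feature set and iterates: run
    :func:`rfe_curve` on the active set, add 1 to the score of every
    selected protein, restrict the active set to the selection, until a
    single feature remains.  If a pass selects the entire active set the
    least important feature is dropped so the loop always contracts.
    Cycles use independent spawned seeds; scores are summed over cycles.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    p = x.shape[1]
    scores = np.zeros(p, dtype=int)
    cycle_seeds = np.random.SeedSequence(seed).spawn(n_cycles)
    for c in range(n_cycles):
        inner = cycle_seeds[c]
        active = np.arange(p)
        while active.size > 1:
            res = rfe_curve(
                x[:, active],
                y,
                patient_ids,
                params,
                step=step,
                seed=_seed_int(inner.spawn(1)[0]),
            )
            selected = active[res.selected]
            scores[selected] += 1
            if selected.size < active.size:
                active = selected
            else:
                drop = _elimination_order(res.final_importances, active, 1)
                active = np.delete(active, drop)
    return ScoreTable(scores=scores, n_cycles=n_cycles, seed=seed)


def permute_labels(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of labels across fluids (class counts kept)."""
    return rng.permutation(np.asarray(y))


def permutation_null_scores(
    x: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence,
    params: ForestParams,
    n_cycles: int,
    n_permutations: int,
    *,
    step: int = 1,
    seed: int = 0,
) -> ScoreTable:
    """Null score distribution: scores recomputed under permuted labels.

    Each permutation draws a fresh uniform label permutation at the fluid
    level and accumulates scores exactly like :func:`accumulate_scores`.
    The returned table sums scores over permutations and keeps the
    per-permutation matrix for sorted-curve comparison plots.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(y, dtype=np.intp)
    root = np.random.SeedSequence(seed)
    perm_seeds = root.spawn(n_permutations)
    rows = []
    for ps in perm_seeds:
        rng = np.random.default_rng(ps)
        y_perm = permute_labels(y, rng)
        tab = accumulate_scores(
            x, y_perm, patient_ids, params, n_cycles, step=step,
            seed=_seed_int(ps.spawn(1)[0]),
        )
        rows.append(tab.scores)
    per_perm = np.vstack(rows)
    return ScoreTable(
        scores=per_perm.sum(axis=0),
        n_cycles=n_cycles,
        seed=seed,
        permuted=True,
        n_permutations=n_permutations,
        per_permutation=per_perm,
    )


def mean_sorted_null_curve(null: ScoreTable) -> np.ndarray:
    """Mean over permutations of the descending sorted score curve."""
    if null.per_permutation is None:
        return null.sorted_scores().astype(float)
    return np.mean(np.sort(null.per_permutation, axis=1)[:, ::-1], axis=0)


def cv_model_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence,
    selected: Sequence[int],
    params: ForestParams,
    *,
    seed: int = 0,
) -> float:
    """LOPO balanced accuracy of the forest restricted to selected features.

    Per fold the forest is fit on all other patients' fluids and evaluated
    on the held-out patient; per-fold balanced accuracies (over classes
    present in that patient's fluids) are averaged.
    """
    selected = np.asarray(list(selected), dtype=np.intp)
    if selected.size == 0:
        raise ValueError("feature selection must be nonempty")
    x = np.asarray(x, dtype=float)[:, selected]
    y = np.asarray(y, dtype=np.intp)
    folds = lopo_folds(patient_ids)
    fold_seeds = np.random.SeedSequence(seed).spawn(len(folds))
    accs = []
    for f, (train, test) in enumerate(folds):
        model = _fit(x[train], y[train], params, _seed_int(fold_seeds[f]))
        accs.append(balanced_accuracy(y[test], model.predict(x[test])))
    return float(np.mean(accs))
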