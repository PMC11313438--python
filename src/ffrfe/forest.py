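"""Weighted random forest classifier with Gini impurity and MDI importances.

This is a purpose-built ensemble for three-class (good/fair/poor) embryo
quality prediction from protein abundances.  It differs from the textbook
random forest in two deliberate ways:

* every sample carries a weight (here: inverse class frequency, so that the
  minority "poor" class is not swamped), and the Gini impurity, the split
  criterion and the leaf distributions are all computed on weighted class
  frequencies;
* ensemble prediction averages the per-tree leaf probability distributions
  instead of majority voting.

Trees are depth-limited (default depth 3) with a minimum raw sample count
per leaf (default 30), which on cohorts of ~100 fluids yields deliberately
shallow, high-bias trees; the forest is used primarily as a feature-ranking
engine through its Mean Decrease in Impurity (MDI) importances.

The split search is exhaustive over midpoints of consecutive distinct
feature values, with a per-split random feature subset of size ~sqrt(p).
All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn``, so fits are reproducible and
independent of tree evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

#: fixed class order used everywhere: integer label k <-> CLASS_NAMES[k]
CLASS_NAMES = ("good", "fair", "poor")
N_CLASSES = 3


@dataclass
class ForestParams:
    """Hyperparameters of the forest.

    ``n_features_per_split`` may be a positive int or the string ``"sqrt"``
    (floor of the square root of the feature count).  ``bootstrap_fraction``
    is the fraction of the training set drawn for each tree; by default the
    draw is *without* replacement ("random subset"); set
    ``sample_with_replacement=True`` for a classical bootstrap.
    """

    n_trees: int = 50
    max_depth: int = 3
    min_samples_leaf: int = 30
    n_features_per_split: int | str = "sqrt"
    bootstrap_fraction: float = 0.8
    sample_with_replacement: bool = False
    impurity_tol: float = 1e-12
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if not (0 < self.bootstrap_fraction <= 1):
            raise ValueError("bootstrap_fraction must be in (0, 1]")

    def resolve_n_features(self, n_total: int) -> int:
        if self.n_features_per_split == "sqrt":
            return max(1, int(np.floor(np.sqrt(n_total))))
        k = int(self.n_features_per_split)
        if k < 1:
            raise ValueError("n_features_per_split must be >= 1")
        return min(k, n_total)


def _class_weight_sums(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.bincount(y, weights=w, minlength=N_CLASSES)


def gini_impurity(y: Sequence[int], w: Optional[Sequence[float]] = None) -> float:
    """Weighted Gini impurity H(Q) = sum_i p_i (1 - p_i) = 1 - sum_i p_i^2.

    ``p_i`` is the weighted relative frequency of class ``i`` in the set.
    Ranges over [0, 2/3] for three classes; 0 iff the set is pure.
    """
    y = np.asarray(y, dtype=np.intp)
    if y.size == 0:
        raise ValueError("Gini impurity of an empty sample set is undefined")
    if w is None:
        w = np.ones(y.size)
    w = np.asarray(w, dtype=float)
    if w.shape != y.shape:
        raise ValueError("labels and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("sample weights must be positive")
    wc = _class_weight_sums(y, w)
    p = wc / wc.sum()
    return float(1.0 - np.dot(p, p))


def best_split(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    candidate_features: Sequence[int],
    min_samples_leaf: int = 1,
) -> Optional[tuple[int, float, float]]:
    """Exhaustive best weighted-Gini split over the candidate features.

    Thresholds are midpoints of consecutive distinct sorted values; a sample
    goes left iff ``x[:, i] < t``.  The returned triple is
    ``(feature, threshold, G)`` where G is the weighted mean child impurity
    ``(w_left H_left + w_right H_right) / w_parent``; both children must
    contain at least ``min_samples_leaf`` raw samples.  Ties in G break to
    the lowest feature index, then the lowest threshold.  Returns ``None``
    when no admissible split exists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    w = np.asarray(w, dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("cannot split an empty sample set")
    best: Optional[tuple[int, float, float]] = None
    for i in sorted(int(f) for f in candidate_features):
        v = x[:, i]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        onehot = np.zeros((n, N_CLASSES))
        onehot[np.arange(n), y[order]] = w[order]
        cum = np.cumsum(onehot, axis=0)
        total = cum[-1]
        w_parent = total.sum()
        # admissible cut after position j: strict value change + leaf sizes
        cuts = np.nonzero(vs[:-1] < vs[1:])[0]
        if cuts.size == 0:
            continue
        n_left = cuts + 1
        ok = (n_left >= min_samples_leaf) & (n - n_left >= min_samples_leaf)
        cuts = cuts[ok]
        if cuts.size == 0:
            continue
        left = cum[cuts]
        right = total[None, :] - left
        wl = left.sum(axis=1)
        wr = right.sum(axis=1)
        h_left = 1.0 - (left**2).sum(axis=1) / wl**2
        h_right = 1.0 - (right**2).sum(axis=1) / wr**2
        g = (wl * h_left + wr * h_right) / w_parent
        j = int(np.argmin(g))  # first minimum -> lowest threshold
        if best is None or g[j] < best[2]:
            thr = 0.5 * (vs[cuts[j]] + vs[cuts[j] + 1])
            best = (i, float(thr), float(g[j]))
    return best


@dataclass
class TreeNode:
    """A node of a decision tree.

    Internal nodes carry (feature, threshold, delta = impurity decrease,
    children); leaves carry the weighted class probability vector.  Every
    node records its raw sample count, total sample weight and impurity.
    """

    n_samples: int
    weight: float
    impurity: float
    proba: Optional[np.ndarray] = None
    feature: Optional[int] = None
    threshold: Optional[float] = None
    delta: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.proba is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "n_samples": self.n_samples,
                "weight": self.weight,
                "impurity": self.impurity,
                "proba": list(map(float, self.proba)),
            }
        return {
            "n_samples": self.n_samples,
            "weight": self.weight,
            "impurity": self.impurity,
            "feature": self.feature,
            "threshold": self.threshold,
            "delta": self.delta,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "proba" in d:
            return cls(
                n_samples=d["n_samples"],
                weight=d["weight"],
                impurity=d["impurity"],
                proba=np.asarray(d["proba"], dtype=float),
            )
        return cls(
            n_samples=d["n_samples"],
            weight=d["weight"],
            impurity=d["impurity"],
            feature=d["feature"],
            threshold=d["threshold"],
            delta=d["delta"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _leaf(y: np.ndarray, w: np.ndarray, impurity: float) -> TreeNode:
    wc = _class_weight_sums(y, w)
    return TreeNode(
        n_samples=y.size, weight=float(w.sum()), impurity=impurity, proba=wc / wc.sum()
    )


def build_tree(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    params: ForestParams,
    rng: np.random.Generator,
) -> TreeNode:
    """Grow a single depth-limited tree on a weighted sample set.

    At each node a fresh random feature subset of size
    ``params.resolve_n_features(p)`` is drawn from ``rng``.  Recursion stops
    at ``max_depth`` edges from the root, when a node cannot produce two
    children of ``min_samples_leaf`` raw samples, when the node is pure, or
    when the best split decreases impurity by at most ``impurity_tol``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    w = np.asarray(w, dtype=float)
    p = x.shape[1]
    n_feat = params.resolve_n_features(p)

    def grow(xi: np.ndarray, yi: np.ndarray, wi: np.ndarray, depth: int) -> TreeNode:
        h = gini_impurity(yi, wi)
        if (
            depth >= params.max_depth
            or yi.size < 2 * params.min_samples_leaf
            or h <= params.impurity_tol
        ):
            return _leaf(yi, wi, h)
        feats = (
            np.arange(p)
            if n_feat >= p
            else rng.choice(p, size=n_feat, replace=False)
        )
        sp = best_split(xi, yi, wi, feats, params.min_samples_leaf)
        if sp is None:
            return _leaf(yi, wi, h)
        i, t, g = sp
        delta = h - g
        if delta <= params.impurity_tol:
            return _leaf(yi, wi, h)
        mask = xi[:, i] < t
        node = TreeNode(
            n_samples=yi.size,
            weight=float(wi.sum()),
            impurity=h,
            feature=i,
            threshold=t,
            delta=delta,
            left=grow(xi[mask], yi[mask], wi[mask], depth + 1),
            right=grow(xi[~mask], yi[~mask], wi[~mask], depth + 1),
        )
        return node

    return grow(x, y, w, 0)


def _tree_predict_proba(root: TreeNode, x: np.ndarray) -> np.ndarray:
    out = np.empty((x.shape[0], N_CLASSES))

    def walk(node: TreeNode, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            out[idx] = node.proba
            return
        mask = x[idx, node.feature] < node.threshold
        walk(node.left, idx[mask])
        walk(node.right, idx[~mask])

    walk(root, np.arange(x.shape[0]))
    return out


def _tree_mdi(root: TreeNode, n_features: int) -> np.ndarray:
    """MDI_T(x) = sum over internal nodes using feature x of p(m) * delta(m),
    with node weight p(m) = w_m / w_root."""
    imp = np.zeros(n_features)
    w_root = root.weight

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        imp[node.feature] += (node.weight / w_root) * node.delta
        walk(node.left)
        walk(node.right)

    walk(root)
    return imp


@dataclass
class ForestModel:
    """A fitted ensemble: trees, parameters and per-feature MDI importances."""

    trees: list[TreeNode]
    params: ForestParams
    n_features: int
    feature_importances_: np.ndarray = field(repr=False, default=None)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Unweighted average of per-tree leaf class distributions."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[1] if x.ndim == 2 else 'non-2d input'}"
            )
        acc = np.zeros((x.shape[0], N_CLASSES))
        for tree in self.trees:
            acc += _tree_predict_proba(tree, x)
        return acc / len(self.trees)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class (ties break to the first class in CLASS_NAMES order)."""
        return np.argmax(self.predict_proba(x), axis=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": {**asdict(self.params)},
                "n_features": self.n_features,
                "feature_importances": list(map(float, self.feature_importances_)),
                "trees": [t.to_dict() for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ForestModel":
        d = json.loads(payload)
        params = ForestParams(**d["params"])
        trees = [TreeNode.from_dict(t) for t in d["trees"]]
        return cls(
            trees=trees,
            params=params,
            n_features=d["n_features"],
            feature_importances_=np.asarray(d["feature_importances"], dtype=float),
        )


def class_balance_weights(y: np.ndarray) -> np.ndarray:
    """Sample weights inversely proportional to class size, rescaled to sum N."""
    y = np.asarray(y, dtype=np.intp)
    counts = np.bincount(y, minlength=N_CLASSES)
    w = 1.0 / counts[y]
    return w * (y.size / w.sum())


def fit_forest(x: np.ndarray, y: np.ndarray, params: ForestParams) -> ForestModel:
    """Fit the weighted random forest.

    Each tree is trained on an independent random subset of
    ``round(bootstrap_fraction * N)`` samples (without replacement by
    default).  Sample weights are inverse class frequencies rescaled so
    their sum equals N.  Deterministic given ``params.seed``.
    """
    params.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("x must be 2-d with one row per label")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    n = y.size
    w = class_balance_weights(y)
    m0 = max(1, int(round(params.bootstrap_fraction * n)))
    children = np.random.SeedSequence(params.seed).spawn(params.n_trees)
    trees = []
    for ss in children:
        rng = np.random.default_rng(ss)
        idx = rng.choice(n, size=m0, replace=params.sample_with_replacement)
        trees.append(build_tree(x[idx], y[idx], w[idx], params, rng))
    mdi = np.mean([_tree_mdi(t, x.shape[1]) for t in trees], axis=0)
    return ForestModel(
        trees=trees, params=params, n_features=x.shape[1], feature_importances_=mdi
    )


def mdi_importance(model: ForestModel) -> np.ndarray:
    """Per-feature MDI, averaged over trees (identical to
    ``model.feature_importances_``; exposed as a named operation)."""
    return np.mean(
        [_tree_mdi(t, model.n_features) for t in model.trees], axis=0
    )
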