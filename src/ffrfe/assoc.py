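"""Per-protein association statistics.

Three analyses complement the forest-based feature selection:

* one-way fixed-effects ANOVA of a protein's per-fluid log2 medians
  grouped by patient, with adjusted R^2 and residual diagnostics
  (Levene's test for heteroscedasticity across patients, Shapiro-Wilk for
  residual normality) — quantifies how patient-determined a protein is;
* a decision stump (depth-1 tree on a single protein, weighted Gini
  criterion with inverse-class-size weights) that dichotomizes fluids into
  high/low abundance at a learned threshold;
* a saturated Poisson log-linear model of the 2x2 (quality x high/low)
  count table, whose interaction coefficient is the log odds ratio; the
  closed form OR = (a*d)/(b*c) with a Wald standard error
  sqrt(1/a + 1/b + 1/c + 1/d).  Haldane-Anscombe +0.5 is added to every
  cell iff any cell is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forest import best_split, class_balance_weights
from .grading import GOOD, POOR, encode_labels


@dataclass
class AnovaResult:
    """One-way patient-effect ANOVA summary for a single protein."""

    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    p_value: float
    levene_p: Optional[float]
    shapiro_p: Optional[float]
    n_groups: int
    n_samples: int


def patient_anova(values: Sequence[float], patient_ids: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA of per-fluid values grouped by patient.

    adjusted R^2 = 1 - (1 - R^2) (n - 1) / (n - k).  Diagnostics: Levene
    (median-centred, groups with >= 2 fluids) and Shapiro-Wilk on pooled
    residuals; both are None when not computable.
    """
    values = np.asarray(values, dtype=float)
    patients = np.asarray(patient_ids)
    if values.shape != patients.shape:
        raise ValueError("values and patient_ids must have equal length")
    groups = [values[patients == p] for p in np.unique(patients)]
    k, n = len(groups), values.size
    if k < 2:
        raise ValueError("ANOVA needs at least two patients")
    if n == k:
        raise ValueError("all patients have a single fluid: no within-group variance")
    grand = values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ss_between + ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    multi = [g for g in groups if g.size >= 2]
    levene_p = (
        float(stats.levene(*multi, center="median").pvalue) if len(multi) >= 2 else None
    )
    residuals = np.concatenate([g - g.mean() for g in groups])
    shapiro_p = (
        float(stats.shapiro(residuals).pvalue) if residuals.size >= 3 else None
    )
    return AnovaResult(
        r_squared=float(r2),
        adjusted_r_squared=float(adj_r2),
        f_statistic=float(f),
        p_value=p,
        levene_p=levene_p,
        shapiro_p=shapiro_p,
        n_groups=k,
        n_samples=n,
    )


@dataclass
class DichotomyResult:
    """Learned high/low dichotomization of one protein's abundances."""

    threshold: float
    high: np.ndarray  # boolean per fluid: value >= threshold
    mean_child_impurity: float


def stump_threshold(
    values: Sequence[float], labels: Sequence[str], min_samples_leaf: int = 1
) -> DichotomyResult:
    """Depth-1 decision tree on a single protein.

    The threshold (a midpoint between consecutive distinct values)
    minimizes the weighted mean Gini impurity of the two children over the
    three quality classes, with inverse-class-size sample weights.  "High"
    means value >= threshold.  ``min_samples_leaf`` keeps each arm from
    degenerating to a handful of extreme fluids, as in a tree's top split.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("constant values cannot be dichotomized")
    y = encode_labels(labels)
    w = class_balance_weights(y)
    split = best_split(values[:, None], y, w, [0], min_samples_leaf=min_samples_leaf)
    if split is None:
        raise ValueError("no admissible threshold under the leaf-size constraint")
    _, threshold, g = split
    return DichotomyResult(
        threshold=threshold, high=values >= threshold, mean_child_impurity=g
    )


@dataclass
class ORResult:
    """Odds ratio of a 2x2 (quality x abundance) count table."""

    counts: np.ndarray  # rows: (good, poor); cols: (high, low)
    odds_ratio: float
    log_odds_ratio: float
    se_log_odds_ratio: float
    p_value: float
    continuity_corrected: bool


def poisson_interaction_or(counts: np.ndarray) -> ORResult:
    """Odds ratio from the saturated Poisson log-linear model of a 2x2 table.

    The interaction coefficient of the saturated model equals
    log((a*d)/(b*c)); its Wald standard error is sqrt(sum of reciprocal
    cells), giving a two-sided normal p-value.  If any cell is zero, 0.5 is
    added to every cell first; a row or column of two zeros is degenerate.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    c = counts.astype(float)
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column is all zero")
    corrected = bool(np.any(c == 0))
    if corrected:
        c = c + 0.5
    (a, b), (cc, d) = c
    log_or = float(np.log(a * d / (b * cc)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / cc + 1 / d))
    z = log_or / se
    p = float(2 * stats.norm.sf(abs(z)))
    return ORResult(
        counts=counts,
        odds_ratio=float(np.exp(log_or)),
        log_odds_ratio=log_or,
        se_log_odds_ratio=se,
        p_value=p,
        continuity_corrected=corrected,
    )


def quality_abundance_association(
    values: Sequence[float],
    labels: Sequence[str],
    min_leaf_fraction: float = 0.1,
) -> tuple[DichotomyResult, ORResult]:
    """Good-vs-poor odds ratio of high abundance for one protein.

    The stump threshold is learned on all three classes (it plays the role
    of a tree's top split) with each arm forced to hold at least
    ``min_leaf_fraction`` of the fluids; the 2x2 table then counts
    good/poor fluids in the high/low arms.  OR > 1 means high abundance
    favours good quality.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    for cls in (GOOD, POOR):
        if cls not in labels:
            raise ValueError(f"class {cls!r} absent")
    min_leaf = max(1, int(values.size * min_leaf_fraction))
    dich = stump_threshold(values, labels, min_samples_leaf=min_leaf)
    table = np.empty((2, 2), dtype=int)
    for r, cls in enumerate((GOOD, POOR)):
        mask = labels == cls
        table[r, 0] = int(np.sum(dich.high & mask))
        table[r, 1] = int(np.sum(~dich.high & mask))
    return dich, poisson_interaction_or(table)


def association_table(
    fluid_table: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Per-protein association summary (one CSV-ready row per protein).

    Combines the patient ANOVA (on per-fluid log2 medians), the learned
    dichotomy threshold, the good/poor 2x2 counts and the Poisson
    interaction odds ratio.
    """
    from .grading import KEY_COLUMNS

    proteins = [c for c in fluid_table.columns if c not in KEY_COLUMNS[:2]]
    y = labels.reindex(fluid_table["fluid_id"]).to_numpy()
    patients = fluid_table["patient_id"].to_numpy()
    rows = []
    for prot in proteins:
        v = fluid_table[prot].to_numpy(dtype=float)
        an = patient_anova(v, patients)
        row = {
            "protein": prot,
            "adjusted_r_squared": an.adjusted_r_squared,
            "anova_f": an.f_statistic,
            "anova_p": an.p_value,
            "levene_p": an.levene_p,
            "shapiro_p": an.shapiro_p,
        }
        try:
            dich, orr = quality_abundance_association(v, y)
        except ValueError:
            # degenerate good/poor table (e.g. one arm holds only fair
            # fluids): the OR is undefined for this protein
            row.update(
                threshold_log2=np.nan, n_good_high=np.nan, n_good_low=np.nan,
                n_poor_high=np.nan, n_poor_low=np.nan, odds_ratio=np.nan,
                or_p=np.nan,
            )
        else:
            (a, b), (c, d) = orr.counts
            row.update(
                threshold_log2=dich.threshold, n_good_high=a, n_good_low=b,
                n_poor_high=c, n_poor_low=d, odds_ratio=orr.odds_ratio,
                or_p=orr.p_value,
            )
        rows.append(row)
    return pd.DataFrame(rows)
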