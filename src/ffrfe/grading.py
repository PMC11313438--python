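"""Cohort preparation: recruitment filters, embryo grading, normalization,
replicate aggregation and fold-change reporting.

Embryo quality is a three-way partition derived from blastocyst morphology
(Istanbul-consensus style day-5/day-6 assessment):

* good — blastocyst by day 5 with trophectoderm (TE) grade 1;
* fair — blastocyst by day 6, or TE grade 2 observed at day 5 or 6
  (an embryo that is both a day-5 blastocyst and TE grade 1 stays good);
* poor — everything else (no blastocyst, or TE grade 3).

Abundance processing mirrors a two-step SWATH-MS workflow: replicate rows
are rescaled to equal total protein sums (total-area normalization), then
replicates of each fluid are collapsed to a per-fluid log2-median profile;
an optional second pass median-centres each fluid's log2 vector across
proteins.  Fold changes are log2 ratios of per-class median abundances with
the poor class as reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

GOOD, FAIR, POOR = "good", "fair", "poor"
CLASS_ORDER = (GOOD, FAIR, POOR)

#: leading non-protein columns of a replicate-level abundance table
KEY_COLUMNS = ("patient_id", "fluid_id", "replicate")


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """Map class names to integers 0/1/2 in CLASS_ORDER."""
    lut = {name: i for i, name in enumerate(CLASS_ORDER)}
    try:
        return np.asarray([lut[l] for l in labels], dtype=np.intp)
    except KeyError as e:
        raise ValueError(f"unknown quality class: {e.args[0]!r}") from None


def decode_labels(codes: Sequence[int]) -> list[str]:
    return [CLASS_ORDER[int(c)] for c in codes]


@dataclass(frozen=True)
class MorphologyRecord:
    """Per-embryo developmental observations.

    ``blastocyst_day`` is 5 or 6 (None if the embryo never reached the
    blastocyst stage); ``te_grade`` is the trophectoderm grade 1/2/3
    observed on that day (None if not graded).
    """

    fluid_id: str
    blastocyst_day: Optional[int] = None
    te_grade: Optional[int] = None


@dataclass(frozen=True)
class RosterRecord:
    """One recruited donor in the enrolment funnel."""

    donor_id: str
    flag_mixed_fluids: bool = False
    flag_uncertain_identification: bool = False
    n_fluids_collected: int = 0


@dataclass
class FunnelResult:
    """Survivors of the recruitment filters plus stage-by-stage counts."""

    survivors: list[RosterRecord]
    stages: list[tuple[str, int]]


def apply_recruitment_filters(roster: Iterable[RosterRecord]) -> FunnelResult:
    """Apply the enrolment filters in order.

    First donors whose follicular fluids could not be kept separate
    (mixed fluids) are removed, then donors with uncertain fluid/oocyte
    identification; counts are logged at each stage.
    """
    roster = list(roster)
    stages = [("recruited", len(roster))]
    after_mixed = [r for r in roster if not r.flag_mixed_fluids]
    stages.append(("fluids taken separately", len(after_mixed)))
    survivors = [r for r in after_mixed if not r.flag_uncertain_identification]
    stages.append(("confirmed identification", len(survivors)))
    return FunnelResult(survivors=survivors, stages=stages)


def grade_embryo(record: MorphologyRecord) -> str:
    """Grade a single embryo good/fair/poor from its morphology record."""
    day, te = record.blastocyst_day, record.te_grade
    if te is not None and day is None:
        raise ValueError(
            f"fluid {record.fluid_id}: trophectoderm grade without blastocyst"
        )
    if day is not None and day not in (5, 6):
        raise ValueError(f"fluid {record.fluid_id}: blastocyst_day must be 5 or 6")
    if te is not None and te not in (1, 2, 3):
        raise ValueError(f"fluid {record.fluid_id}: te_grade must be 1, 2 or 3")
    if day == 5 and te == 1:
        return GOOD
    if day == 6 or (te == 2 and day in (5, 6)):
        return FAIR
    return POOR


def grade_cohort(morphology: pd.DataFrame) -> pd.Series:
    """Grade every fluid of a morphology table.

    Expects columns ``fluid_id``, ``blastocyst_day``, ``te_grade`` (missing
    observations as NaN/None).  Returns a Series of class names indexed by
    fluid id.
    """
    labels = {}
    for row in morphology.itertuples(index=False):
        day = None if pd.isna(row.blastocyst_day) else int(row.blastocyst_day)
        te = None if pd.isna(row.te_grade) else int(row.te_grade)
        labels[row.fluid_id] = grade_embryo(
            MorphologyRecord(fluid_id=row.fluid_id, blastocyst_day=day, te_grade=te)
        )
    return pd.Series(labels, name="quality")


def _protein_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in KEY_COLUMNS]


def total_sum_normalize(
    table: pd.DataFrame, target: Union[float, str] = "median"
) -> pd.DataFrame:
    """Rescale each replicate row so its total protein abundance equals
    ``target`` (default: the median of the raw row sums)."""
    proteins = _protein_columns(table)
    values = table[proteins].to_numpy(dtype=float)
    sums = values.sum(axis=1)
    if np.any(sums <= 0):
        bad = table.index[sums <= 0][0]
        raise ValueError(f"row {bad!r} has nonpositive total abundance")
    if target == "median":
        target_value = float(np.median(sums))
    else:
        target_value = float(target)
        if target_value <= 0:
            raise ValueError("normalization target must be positive")
    out = table.copy()
    out[proteins] = values * (target_value / sums)[:, None]
    return out


def aggregate_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows to one log2-median profile per fluid.

    Each entry of the result is the median over the fluid's replicates of
    log2(abundance).  Returns a table keyed by (patient_id, fluid_id).
    """
    proteins = _protein_columns(table)
    values = table[proteins].to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("nonpositive abundance: log2 aggregation undefined")
    logged = pd.concat(
        [
            table[list(KEY_COLUMNS[:2])].reset_index(drop=True),
            pd.DataFrame(np.log2(values), columns=proteins),
        ],
        axis=1,
    )
    out = logged.groupby(["patient_id", "fluid_id"], sort=True).median()
    return out.reset_index()


def median_center_fluids(fluid_table: pd.DataFrame) -> pd.DataFrame:
    """Second-pass normalization: subtract each fluid's median log2 value
    across proteins (brings all fluid profiles to a common centre)."""
    proteins = [c for c in fluid_table.columns if c not in KEY_COLUMNS[:2]]
    out = fluid_table.copy()
    values = out[proteins].to_numpy(dtype=float)
    out[proteins] = values - np.median(values, axis=1, keepdims=True)
    return out


def fold_change_table(fluid_table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-protein log2 fold changes of class median abundances vs poor.

    ``fluid_table`` holds per-fluid log2 medians; medians per class are
    taken over fluids on the linear scale.  Requires all three classes.
    """
    proteins = [c for c in fluid_table.columns if c not in KEY_COLUMNS[:2]]
    y = labels.reindex(fluid_table["fluid_id"]).to_numpy()
    if pd.isna(y).any():
        raise ValueError("labels missing for some fluids")
    present = set(y)
    missing = [c for c in CLASS_ORDER if c not in present]
    if missing:
        raise ValueError(f"class(es) absent from cohort: {missing}")
    linear = 2.0 ** fluid_table[proteins].to_numpy(dtype=float)
    med = {c: np.median(linear[y == c], axis=0) for c in CLASS_ORDER}
    return pd.DataFrame(
        {
            "protein": proteins,
            "log2fc_good": np.log2(med[GOOD] / med[POOR]),
            "log2fc_fair": np.log2(med[FAIR] / med[POOR]),
        }
    )
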