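"""Synthetic follicular-fluid cohort generator.

Emulates the statistical structure of a patient-nested SWATH-MS protein
abundance study so every downstream stage (grading, normalization, forest,
RFECV, association statistics) is testable without real data.  The default
configuration mirrors the study design this package targets: 50 oocyte
donors contributing 2-3 fluids each (110 fluids total), three technical
replicates per fluid (330 replicate rows) and 484 quantified proteins,
with embryo-quality classes of exactly 44 good / 39 fair / 27 poor fluids.

Generative model (per replicate row, on the log2 scale)::

    log2 A[f,r,j] = b_j + u[patient(f), j] + e[class(f), j] + eps[f,r,j]

* ``b_j`` — protein baseline, uniform over ``baseline_log2_mean_range``;
* ``u`` — patient random effect, N(0, patient_effect_sd_j^2), drawn once
  per (patient, protein);
* ``e`` — planted per-class log2 effect (0 for unplanted proteins);
* ``eps`` — replicate noise, N(0, sd_j^2) with an abundance-dependent
  scale ``sd_j = noise_sd_at_reference * (A_ref / A_j)^exponent`` so that
  high-abundance proteins are measured with proportionally smaller error.

Abundances are emitted on the linear scale (``2**log2``), so they are
strictly positive.  Class labels are assigned per fluid with exact rounded
class counts, independent of patient.  Morphology records are generated
backwards from the class label so that the grading rules round-trip.

Two preset single-protein profiles reproduce the two patient-effect
regimes seen in real data: ``"IgA1-like"`` (a high-abundance protein whose
level is strongly patient-determined, one-way patient ANOVA adjusted R^2
around 0.95, lower in fluids of good-quality embryos) and ``"DKK3-like"``
(lower abundance, weak patient effect, adjusted R^2 around 0.3, higher in
fluids of good-quality embryos).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .grading import CLASS_ORDER, FAIR, GOOD, KEY_COLUMNS, POOR, RosterRecord

#: log2 abundance at which ``noise_sd_at_reference`` applies (midpoint of
#: the default baseline range)
REFERENCE_LOG2 = 15.0


@dataclass(frozen=True)
class PlantedEffect:
    """Per-class log2 abundance shifts planted on one protein
    (order: good, fair, poor)."""

    protein: int
    log2_effects: tuple[float, float, float]


@dataclass(frozen=True)
class ProteinProfile:
    """A preset (baseline, patient-effect strength, class effects) triple."""

    baseline_log2: float
    patient_effect_sd: float
    class_log2_effects: tuple[float, float, float]


PROFILES = {
    # strong patient effect, high abundance (hence low noise), lower in good
    "IgA1-like": ProteinProfile(
        baseline_log2=REFERENCE_LOG2 + np.log2(7) - 1.0,  # ~16.81
        patient_effect_sd=0.85,
        class_log2_effects=(-0.26, -0.34, 0.0),
    ),
    # weak patient effect, sevenfold lower abundance, higher in good
    "DKK3-like": ProteinProfile(
        baseline_log2=REFERENCE_LOG2 - 1.0,
        patient_effect_sd=0.28,
        class_log2_effects=(0.43, -0.00047, 0.0),
    ),
}


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort; defaults are the study design."""

    n_patients: int = 50
    fluids_per_patient_range: tuple[int, int] = (2, 3)
    n_fluids: int = 110
    n_replicates: int = 3
    n_proteins: int = 484
    class_proportions: tuple[float, float, float] = (44 / 110, 39 / 110, 27 / 110)
    planted_proteins: list[PlantedEffect] = field(default_factory=list)
    patient_effect_sd: Union[float, np.ndarray] = 0.28
    baseline_log2_mean_range: tuple[float, float] = (10.0, 20.0)
    baseline_log2_overrides: dict[int, float] = field(default_factory=dict)
    noise_sd_at_reference: float = 0.4
    noise_abundance_exponent: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_fluids, self.n_replicates, self.n_proteins) < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.fluids_per_patient_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid fluids_per_patient_range")
        if not (lo * self.n_patients <= self.n_fluids <= hi * self.n_patients):
            raise ValueError(
                "n_fluids incompatible with n_patients and fluids_per_patient_range"
            )
        if abs(sum(self.class_proportions) - 1.0) > 1e-12:
            raise ValueError("class_proportions must sum to 1")
        if min(self.class_proportions) < 0:
            raise ValueError("class_proportions must be nonnegative")
        if self.noise_sd_at_reference <= 0:
            raise ValueError("noise_sd_at_reference must be positive")
        for pe in self.planted_proteins:
            if not (0 <= pe.protein < self.n_proteins):
                raise ValueError(f"planted protein index {pe.protein} out of range")


@dataclass
class Cohort:
    """The three generated tables plus the configuration that produced them."""

    abundance: pd.DataFrame
    metadata: pd.DataFrame
    morphology: pd.DataFrame
    config: CohortConfig

    @property
    def protein_ids(self) -> list[str]:
        return [c for c in self.abundance.columns if c not in KEY_COLUMNS]


def plant_profile(config: CohortConfig, protein: int, profile: str) -> CohortConfig:
    """Return a config with one preset protein profile planted at ``protein``."""
    prof = PROFILES[profile]
    sd = config.patient_effect_sd
    sd_vec = np.full(config.n_proteins, float(sd)) if np.isscalar(sd) else np.array(sd)
    sd_vec[protein] = prof.patient_effect_sd
    return replace(
        config,
        patient_effect_sd=sd_vec,
        baseline_log2_overrides={
            **config.baseline_log2_overrides,
            protein: prof.baseline_log2,
        },
        planted_proteins=config.planted_proteins
        + [PlantedEffect(protein, prof.class_log2_effects)],
    )


def _class_counts(proportions: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder rounding of proportions to exact integer counts."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _fluid_counts(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.fluids_per_patient_range
    counts = np.full(config.n_patients, lo)
    extras = config.n_fluids - counts.sum()
    while extras > 0:
        eligible = np.flatnonzero(counts < hi)
        pick = rng.choice(eligible, size=min(extras, eligible.size), replace=False)
        counts[pick] += 1
        extras -= pick.size
    return counts


_FAIR_MORPHOLOGIES = [(6, 1), (5, 2), (6, 2)]
# a day-6 blastocyst always grades fair, so poor embryos are either
# arrested (no blastocyst) or day-5 blastocysts with TE grade 3
_POOR_MORPHOLOGIES = [(None, None), (5, 3)]


def _morphology_for(label: str, rng: np.random.Generator) -> tuple:
    if label == GOOD:
        return (5, 1)
    if label == FAIR:
        return _FAIR_MORPHOLOGIES[rng.integers(len(_FAIR_MORPHOLOGIES))]
    return _POOR_MORPHOLOGIES[rng.integers(len(_POOR_MORPHOLOGIES))]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a replicate-level abundance table with metadata and
    class-consistent morphology records; fully reproducible from
    ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_prot = config.n_proteins

    fluid_counts = _fluid_counts(config, rng)
    patient_of_fluid = np.repeat(np.arange(config.n_patients), fluid_counts)
    n_fluids = patient_of_fluid.size

    counts = _class_counts(config.class_proportions, n_fluids)
    label_codes = rng.permutation(np.repeat(np.arange(3), counts))

    lo, hi = config.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, size=n_prot)
    for j, b in config.baseline_log2_overrides.items():
        baseline[j] = b

    sd = config.patient_effect_sd
    sd_vec = np.full(n_prot, float(sd)) if np.isscalar(sd) else np.asarray(sd, float)
    patient_effect = rng.normal(0.0, 1.0, size=(config.n_patients, n_prot)) * sd_vec

    class_effect = np.zeros((3, n_prot))
    for pe in config.planted_proteins:
        class_effect[:, pe.protein] += np.asarray(pe.log2_effects)

    noise_sd = config.noise_sd_at_reference * 2.0 ** (
        (REFERENCE_LOG2 - baseline) * config.noise_abundance_exponent
    )
    n_rows = n_fluids * config.n_replicates
    eps = rng.normal(0.0, 1.0, size=(n_rows, n_prot)) * noise_sd

    fluid_row = np.repeat(np.arange(n_fluids), config.n_replicates)
    log2_values = (
        baseline[None, :]
        + patient_effect[patient_of_fluid[fluid_row]]
        + class_effect[label_codes[fluid_row]]
        + eps
    )

    pat_width = len(str(config.n_patients))
    patient_ids = np.array(
        [f"pat{p + 1:0{pat_width}d}" for p in range(config.n_patients)]
    )
    fluid_ids = []
    seen: dict[int, int] = {}
    for p in patient_of_fluid:
        seen[p] = seen.get(p, 0) + 1
        fluid_ids.append(f"{patient_ids[p]}_f{seen[p]}")
    fluid_ids = np.array(fluid_ids)
    proteins = [f"prot{j:04d}" for j in range(n_prot)]

    keys = pd.DataFrame(
        {
            "patient_id": patient_ids[patient_of_fluid[fluid_row]],
            "fluid_id": fluid_ids[fluid_row],
            "replicate": np.tile(np.arange(1, config.n_replicates + 1), n_fluids),
        }
    )
    abundance = pd.concat(
        [keys, pd.DataFrame(2.0**log2_values, columns=proteins)], axis=1
    )

    labels = [CLASS_ORDER[c] for c in label_codes]
    metadata = pd.DataFrame(
        {
            "patient_id": patient_ids[patient_of_fluid],
            "fluid_id": fluid_ids,
            "quality": labels,
        }
    )

    morph_rows = []
    for fid, label in zip(fluid_ids, labels):
        day, te = _morphology_for(label, rng)
        morph_rows.append((fid, day, te))
    morphology = pd.DataFrame(
        morph_rows, columns=["fluid_id", "blastocyst_day", "te_grade"]
    ).astype({"blastocyst_day": "Int64", "te_grade": "Int64"})

    return Cohort(
        abundance=abundance, metadata=metadata, morphology=morphology, config=config
    )


def generate_roster(
    n_recruited: int, n_mixed: int, n_uncertain: int
) -> list[RosterRecord]:
    """Recruitment-roster fixture: ``n_mixed`` donors flagged for mixed
    fluids, ``n_uncertain`` flagged for uncertain identification (the flags
    are mutually exclusive), the remainder clean."""
    if min(n_recruited, n_mixed, n_uncertain) < 0:
        raise ValueError("counts must be nonnegative")
    if n_mixed + n_uncertain > n_recruited:
        raise ValueError("flagged donors exceed the recruited count")
    roster = []
    width = len(str(max(n_recruited, 1)))
    for i in range(n_recruited):
        roster.append(
            RosterRecord(
                donor_id=f"donor{i + 1:0{width}d}",
                flag_mixed_fluids=i < n_mixed,
                flag_uncertain_identification=n_mixed <= i < n_mixed + n_uncertain,
                n_fluids_collected=2 + (i % 10),
            )
        )
    return roster
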