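import pytest
from hypothesis import HealthCheck, settings

import ffrfe
from ffrfe.grading import KEY_COLUMNS

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def design_matrix(cohort):
    """Aggregate a cohort to the fluid level and return (x, y, patients, proteins)."""
    fluids = ffrfe.aggregate_replicates(cohort.abundance)
    proteins = [c for c in fluids.columns if c not in KEY_COLUMNS[:2]]
    labels = cohort.metadata.set_index("fluid_id")["quality"].reindex(
        fluids["fluid_id"]
    )
    return (
        fluids[proteins].to_numpy(dtype=float),
        ffrfe.encode_labels(labels),
        fluids["patient_id"].to_numpy(),
        proteins,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort: 50 patients, 110 fluids, 484 proteins."""
    return ffrfe.generate_cohort(ffrfe.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def strong_signal_cohort():
    """Small cohort with one protein that separates the classes strongly."""
    cfg = ffrfe.CohortConfig(
        n_patients=10,
        fluids_per_patient_range=(3, 4),
        n_fluids=34,
        n_replicates=2,
        n_proteins=10,
        planted_proteins=[ffrfe.PlantedEffect(0, (3.0, 1.5, 0.0))],
        patient_effect_sd=0.2,
        seed=5,
    )
    return ffrfe.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_forest_params():
    return ffrfe.ForestParams(
        n_trees=15, max_depth=3, min_samples_leaf=4, seed=0
    )
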