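"""End-to-end pipeline driver.

Stage order: (simulate or load) -> total-sum normalize -> aggregate
replicates -> grade/join labels -> RFECV protein scores -> permutation
null -> association statistics -> fold-change table -> score-curve plot ->
manifest.  Every output is reproducible byte-for-byte from (inputs,
config, seed); input files are never mutated.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .assoc import association_table
from .grading import (
    KEY_COLUMNS,
    aggregate_replicates,
    encode_labels,
    fold_change_table,
    grade_cohort,
    median_center_fluids,
    total_sum_normalize,
)
from .io import RunConfig, read_abundance_table, read_morphology_table, write_cohort, write_table
from .rfecv import (
    accumulate_scores,
    mean_sorted_null_curve,
    permutation_null_scores,
)
from .synth import CohortConfig, generate_cohort

log = logging.getLogger("ffrfe")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage(name: str, func, timings: dict):
    t0 = time.perf_counter()
    try:
        result = func()
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name!r} failed: {e}") from e
    timings[name] = round(time.perf_counter() - t0, 3)
    return result


def plot_score_curves(
    observed: np.ndarray, null_curve: np.ndarray, path: Path
) -> None:
    """Sorted observed protein scores against the permutation-null curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ranks = np.arange(1, observed.size + 1)
    ax.plot(ranks, np.sort(observed)[::-1], label="embryo quality", lw=1.5)
    ax.plot(ranks, null_curve, label="permuted labels", lw=1.5, ls="--")
    ax.set_xlabel("protein rank")
    ax.set_ylabel("RFECV score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the output bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "ffrfe_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # --- load or simulate ------------------------------------------------
    if config.abundance_path is None:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)

        def simulate():
            cohort = generate_cohort(cohort_cfg)
            write_cohort(cohort, out / "cohort")
            return cohort

        cohort = _stage("simulate", simulate, timings)
        abundance, morphology = cohort.abundance, cohort.morphology
    else:
        abundance = _stage(
            "load", lambda: read_abundance_table(config.abundance_path), timings
        )
        morphology = _stage(
            "load_morphology",
            lambda: read_morphology_table(config.morphology_path),
            timings,
        )
    log.info("loaded %d replicate rows", len(abundance))

    # --- normalize / aggregate / grade -----------------------------------
    if config.normalize:
        abundance = _stage(
            "normalize",
            lambda: total_sum_normalize(abundance, config.normalize_target),
            timings,
        )
    fluid_table = _stage("aggregate", lambda: aggregate_replicates(abundance), timings)
    if config.median_center:
        fluid_table = _stage(
            "median_center", lambda: median_center_fluids(fluid_table), timings
        )
    labels = _stage("grade", lambda: grade_cohort(morphology), timings)
    log.info("aggregated to %d fluids", len(fluid_table))

    proteins = [c for c in fluid_table.columns if c not in KEY_COLUMNS[:2]]
    x = fluid_table[proteins].to_numpy(dtype=float)
    y = encode_labels(labels.reindex(fluid_table["fluid_id"]))
    patients = fluid_table["patient_id"].to_numpy()
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0]) & (2**31 - 1) for s in root.spawn(2)]

    # --- selection and null ----------------------------------------------
    table = _stage(
        "select",
        lambda: accumulate_scores(
            x, y, patients, config.forest, config.n_cycles,
            step=config.rfe_step, seed=seeds[0],
        ),
        timings,
    )
    score_df = pd.DataFrame({"protein": proteins, "score": table.scores})
    score_df["rank"] = table.ranks() + 1
    write_table(score_df.sort_values("rank"), out / "score_table.csv")

    null = _stage(
        "null",
        lambda: permutation_null_scores(
            x, y, patients, config.forest, config.n_cycles, config.n_permutations,
            step=config.rfe_step, seed=seeds[1],
        ),
        timings,
    )
    null_curve = mean_sorted_null_curve(null)
    null_df = pd.DataFrame(
        {
            "rank": np.arange(1, len(proteins) + 1),
            "observed_sorted": table.sorted_scores(),
            "null_sorted_mean": null_curve,
        }
    )
    write_table(null_df, out / "null_curves.csv")
    _stage(
        "plot",
        lambda: plot_score_curves(table.scores, null_curve, out / "score_curves.png"),
        timings,
    )

    # --- association / fold changes --------------------------------------
    if config.run_association:
        assoc_df = _stage(
            "assoc", lambda: association_table(fluid_table, labels), timings
        )
        write_table(assoc_df, out / "association.csv")
    fc = _stage(
        "foldchange", lambda: fold_change_table(fluid_table, labels), timings
    )
    write_table(fc, out / "fold_changes.csv")

    manifest["stages"] = timings
    manifest["n_replicate_rows"] = int(len(abundance))
    manifest["n_fluids"] = int(len(fluid_table))
    manifest["n_proteins"] = len(proteins)
    manifest["class_counts"] = {
        c: int(np.sum(labels.to_numpy() == c)) for c in ("good", "fair", "poor")
    }
    manifest["forest_params"] = {
        k: v for k, v in vars(config.forest).items()
    }
    manifest["n_cycles"] = config.n_cycles
    manifest["n_permutations"] = config.n_permutations
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
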