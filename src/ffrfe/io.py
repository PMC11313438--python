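"""Table and configuration I/O.

All tables travel as plain CSV/TSV.  A replicate-level abundance table has
three leading key columns (``patient_id``, ``fluid_id``, ``replicate``)
followed by one numeric column per protein.  Validation is strict: missing
key columns, non-numeric protein cells, duplicate (fluid, replicate) keys
and fluids spanning two patients are all rejected with named errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .forest import ForestParams
from .grading import KEY_COLUMNS
from .synth import Cohort, CohortConfig, PlantedEffect

#: significant digits for CSV output (full precision stays in JSON)
CSV_DIGITS = 9


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_abundance_table(
    path: Union[str, Path], sep: Optional[str] = None
) -> pd.DataFrame:
    """Read and validate a replicate-level abundance table.

    The delimiter is sniffed from the extension (.tsv/.tab -> tab,
    otherwise comma) unless ``sep`` overrides it.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing key column(s) {missing}")
    proteins = [c for c in table.columns if c not in KEY_COLUMNS]
    if not proteins:
        raise ValueError(f"{path.name}: no protein columns")
    bad = [c for c in proteins if not pd.api.types.is_numeric_dtype(table[c])]
    if bad:
        rows = table.index[pd.to_numeric(table[bad[0]], errors="coerce").isna()]
        raise ValueError(
            f"{path.name}: non-numeric abundance in column {bad[0]!r}"
            f" (first bad row {int(rows[0]) + 2})"
        )
    dup = table.duplicated(subset=["fluid_id", "replicate"], keep=False)
    if dup.any():
        key = table.loc[dup, ["fluid_id", "replicate"]].iloc[0].tolist()
        raise ValueError(f"{path.name}: duplicate (fluid, replicate) key {key}")
    fluids = table.groupby("fluid_id")["patient_id"].nunique()
    if (fluids > 1).any():
        raise ValueError(
            f"{path.name}: fluid {fluids.index[fluids > 1][0]!r} maps to"
            " multiple patients"
        )
    if (table[proteins].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path.name}: negative abundances")
    return table


def write_table(table: pd.DataFrame, path: Union[str, Path], sep: Optional[str] = None) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path, sep), index=False,
                 float_format=f"%.{CSV_DIGITS}g")


def read_metadata_table(path: Union[str, Path], sep: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path, sep))
    for col in ("patient_id", "fluid_id"):
        if col not in table.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    return table


def read_morphology_table(path: Union[str, Path], sep: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path, sep))
    for col in ("fluid_id", "blastocyst_day", "te_grade"):
        if col not in table.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    return table.astype({"blastocyst_day": "Int64", "te_grade": "Int64"})


def write_cohort(cohort: Cohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write a synthetic cohort (abundance/metadata/morphology CSVs plus a
    provenance sidecar JSON recording the full config and seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out / "abundance.csv",
        "metadata": out / "metadata.csv",
        "morphology": out / "morphology.csv",
        "provenance": out / "provenance.json",
    }
    write_table(cohort.abundance, paths["abundance"])
    write_table(cohort.metadata, paths["metadata"])
    write_table(cohort.morphology, paths["morphology"])
    paths["provenance"].write_text(json.dumps(_config_dict(cohort.config), indent=2))
    return paths


def _config_dict(config: CohortConfig) -> dict:
    d = {
        "n_patients": config.n_patients,
        "fluids_per_patient_range": list(config.fluids_per_patient_range),
        "n_fluids": config.n_fluids,
        "n_replicates": config.n_replicates,
        "n_proteins": config.n_proteins,
        "class_proportions": list(config.class_proportions),
        "planted_proteins": [
            {"protein": pe.protein, "log2_effects": list(pe.log2_effects)}
            for pe in config.planted_proteins
        ],
        "patient_effect_sd": (
            float(config.patient_effect_sd)
            if np.isscalar(config.patient_effect_sd)
            else list(map(float, config.patient_effect_sd))
        ),
        "baseline_log2_mean_range": list(config.baseline_log2_mean_range),
        "baseline_log2_overrides": {
            str(k): float(v) for k, v in config.baseline_log2_overrides.items()
        },
        "noise_sd_at_reference": config.noise_sd_at_reference,
        "noise_abundance_exponent": config.noise_abundance_exponent,
        "seed": config.seed,
    }
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["fluids_per_patient_range"] = tuple(d.get("fluids_per_patient_range", (2, 3)))
    d["class_proportions"] = tuple(d.get("class_proportions", (44/110, 39/110, 27/110)))
    d["baseline_log2_mean_range"] = tuple(d.get("baseline_log2_mean_range", (10.0, 20.0)))
    d["planted_proteins"] = [
        PlantedEffect(pe["protein"], tuple(pe["log2_effects"]))
        for pe in d.get("planted_proteins", [])
    ]
    d["baseline_log2_overrides"] = {
        int(k): float(v) for k, v in d.get("baseline_log2_overrides", {}).items()
    }
    sd = d.get("patient_effect_sd", 0.28)
    d["patient_effect_sd"] = float(sd) if np.isscalar(sd) else np.asarray(sd, float)
    return CohortConfig(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-serializable)."""

    abundance_path: Optional[str] = None
    metadata_path: Optional[str] = None
    morphology_path: Optional[str] = None
    cohort: Optional[CohortConfig] = None  # simulate when no paths given
    normalize: bool = True
    normalize_target: Union[float, str] = "median"
    median_center: bool = True
    forest: ForestParams = field(default_factory=ForestParams)
    n_cycles: int = 30
    n_permutations: int = 5
    rfe_step: int = 1
    run_association: bool = True
    seed: int = 0
    out_dir: str = "ffrfe_out"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        forest = ForestParams(**raw.pop("forest", {}))
        cohort = raw.pop("cohort", None)
        cfg = cls(forest=forest, **raw)
        if cohort is not None:
            cfg.cohort = cohort_config_from_dict(cohort)
        return cfg

    def to_yaml(self, path: Union[str, Path]) -> None:
        from dataclasses import asdict

        d = asdict(self)
        if self.cohort is not None:
            d["cohort"] = _config_dict(self.cohort)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
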