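"""Configuration, table I/O, run manifests and small data-prep utilities.

All tables are UTF-8 TSV with a header row; floats are serialized at 10
significant digits so written tables round-trip through :func:`read_table`.
Configs are YAML or JSON files whose keys mirror the dataclass field names
of :class:`~haplotrait.simulate.AdmixtureSimConfig` and
:class:`~haplotrait.simulate.ARSSimConfig`.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import PaintedCohort

__all__ = [
    "write_table",
    "read_table",
    "load_config",
    "write_manifest",
    "ISCED_YEARS",
    "isced_years",
    "painting_to_table",
    "painting_from_table",
    "genotypes_to_table",
    "genotypes_from_table",
    "export_painted_cohort",
    "load_painted_cohort",
]


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a TSV atomically (temp file + rename), floats at 10 sig digits."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format="%.10g")
    os.replace(tmp, path)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return cfg


def write_manifest(
    path: str | os.PathLike, config: dict, seed: int, **extra
) -> None:
    """Write a reproducibility manifest (config hash, seed, versions)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        **extra,
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# Educational attainment recoding
# ---------------------------------------------------------------------------

#: Years-of-education score per qualification category (ISCED definition).
ISCED_YEARS = {
    "None of the above": 7,
    "CSEs or equivalent": 10,
    "O levels/GCSEs or equivalent": 10,
    "A levels/AS levels or equivalent": 13,
    "Other professional qualifications eg: nursing, teaching": 15,
    "NVQ or HND or HNC or equivalent": 19,
    "College or University degree": 20,
}


def isced_years(category: str) -> int:
    """Years-of-education score for an educational-attainment category.

    Matching is exact after whitespace normalization (no fuzzy matching).
    """
    normalized = re.sub(r"\s+", " ", category).strip()
    try:
        return ISCED_YEARS[normalized]
    except KeyError:
        valid = "; ".join(ISCED_YEARS)
        raise KeyError(
            f"unknown education category {category!r}; valid labels are: {valid}"
        ) from None


# ---------------------------------------------------------------------------
# Painted-cohort tables
# ---------------------------------------------------------------------------


def painting_to_table(painting: np.ndarray, ancestry_labels: list[str]) -> pd.DataFrame:
    """Long table (haplotype_id, snp_id, ancestry, probability) of a
    (H, M, K) painting array."""
    h, m, k = painting.shape
    hap, snp, anc = np.meshgrid(
        np.arange(h), np.arange(m), np.arange(k), indexing="ij"
    )
    return pd.DataFrame({
        "haplotype_id": hap.ravel(),
        "snp_id": snp.ravel(),
        "ancestry": np.asarray(ancestry_labels)[anc.ravel()],
        "probability": painting.ravel(),
    })


def painting_from_table(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Reconstruct the (H, M, K) painting array from its long table."""
    labels = list(dict.fromkeys(df["ancestry"]))
    h = int(df["haplotype_id"].max()) + 1
    m = int(df["snp_id"].max()) + 1
    k = len(labels)
    arr = np.zeros((h, m, k))
    anc_index = df["ancestry"].map({a: i for i, a in enumerate(labels)}).to_numpy()
    arr[df["haplotype_id"].to_numpy(), df["snp_id"].to_numpy(), anc_index] = (
        df["probability"].to_numpy()
    )
    return arr, labels


def genotypes_to_table(genotypes: np.ndarray) -> pd.DataFrame:
    """Haplotype-major genotype table: one row per haplotype, one column per SNP."""
    df = pd.DataFrame(
        genotypes, columns=[f"snp{j}" for j in range(genotypes.shape[1])]
    )
    df.insert(0, "haplotype_id", np.arange(genotypes.shape[0]))
    return df


def genotypes_from_table(df: pd.DataFrame) -> np.ndarray:
    cols = [c for c in df.columns if c != "haplotype_id"]
    return df[cols].to_numpy()


def export_painted_cohort(cohort: PaintedCohort, out_dir: str | os.PathLike) -> None:
    """Write a painted cohort as a directory of TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(
        painting_to_table(cohort.painting, cohort.ancestry_labels),
        out / "painting.tsv",
    )
    write_table(genotypes_to_table(cohort.genotypes), out / "genotypes.tsv")
    write_table(
        pd.DataFrame({
            "snp_id": np.arange(cohort.effects.size), "beta": cohort.effects
        }),
        out / "effects.tsv",
    )
    write_table(
        painting_to_table(cohort.pool_painting, cohort.ancestry_labels),
        out / "pool_painting.tsv",
    )
    write_table(genotypes_to_table(cohort.pool_genotypes), out / "pool_genotypes.tsv")


def load_painted_cohort(in_dir: str | os.PathLike) -> PaintedCohort:
    """Read a painted cohort from the directory layout written by
    :func:`export_painted_cohort` (the real-data entry point)."""
    d = Path(in_dir)
    painting, labels = painting_from_table(read_table(d / "painting.tsv"))
    pool_painting, _ = painting_from_table(read_table(d / "pool_painting.tsv"))
    genotypes = genotypes_from_table(read_table(d / "genotypes.tsv"))
    pool_genotypes = genotypes_from_table(read_table(d / "pool_genotypes.tsv"))
    effects = read_table(d / "effects.tsv")["beta"].to_numpy()
    return PaintedCohort(
        n_individuals=painting.shape[0] // 2,
        ancestry_labels=labels,
        painting=painting,
        genotypes=genotypes,
        effects=effects,
        pool_painting=pool_painting,
        pool_genotypes=pool_genotypes,
    )
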