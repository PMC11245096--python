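"""TSV schemas, readers/writers, run manifests, and packaged reference data."""

from __future__ import annotations

import json
import platform
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

__all__ = [
    "HABITAT_LABELS",
    "read_detection_tsv",
    "read_census_tsv",
    "read_genome_tsv",
    "read_trait_matrix_tsv",
    "read_training_tsv",
    "write_tsv",
    "write_manifest",
    "load_class_genome_counts",
]

#: Canonical habitat vocabulary; user-defined labels are also accepted.
HABITAT_LABELS = (
    "soil",
    "engineered",
    "freshwater",
    "host-associated",
    "marine",
    "non-marine saline and alkaline",
    "terrestrial non-soil",
)


class SchemaError(ValueError):
    """Input table missing required columns or violating an invariant."""


def _require(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_detection_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str})
    _require(df, ["dataset_id", "habitat", "lineage", "relative_abundance_pct"], path)
    if (df["relative_abundance_pct"] <= 0).any():
        bad = df.index[df["relative_abundance_pct"] <= 0][0]
        raise SchemaError(f"{path}: non-positive abundance at row {bad}")
    dup = df.duplicated(subset=["dataset_id", "lineage"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (dataset_id, lineage) at row {df.index[dup][0]}")
    multi = df.groupby("dataset_id")["habitat"].nunique()
    if (multi > 1).any():
        ds = multi.index[multi > 1][0]
        raise SchemaError(f"{path}: dataset {ds!r} carries more than one habitat label")
    return df


def read_census_tsv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["habitat", "n_datasets"], path)
    return dict(zip(df["habitat"], df["n_datasets"].astype(int)))


def read_genome_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    _require(df, ["genome_id", "lineage", "habitat"], path)
    if df["genome_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate genome_id")
    return df


def read_trait_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        raise SchemaError(f"{path}: trait matrix entries must be 0/1")
    return df


def read_training_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    _require(df, ["id", "regulatory_flexibility", "resource_acquisition", "label"], path)
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_manifest(
    out_dir: str | Path,
    stage: str,
    inputs: Mapping[str, Any],
    thresholds: Mapping[str, Any],
    seed: int | None,
    exclusions: Mapping[str, int] | None = None,
) -> Path:
    """Write a reproducibility manifest next to a stage's outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "thresholds": dict(thresholds),
        "seed": seed,
        "exclusions": dict(exclusions or {}),
        "versions": {
            "habprof": __version__,
            "python": platform.python_version(),
            "pandas": pd.__version__,
        },
    }
    path = out / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_class_genome_counts() -> pd.DataFrame:
    """Packaged per-class genome-provenance census across seven habitats."""
    with resources.files("habprof.data").joinpath("class_genome_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
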