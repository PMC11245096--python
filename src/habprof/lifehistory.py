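"""Genomic-investment indices and nearest-centroid life-history calls.

Two indices summarize a genome's investment tradeoff:

* regulatory flexibility — transcription-factor count / total gene count;
* resource acquisition — (secreted CAZymes + secreted proteases +
  secreted lipases + BGC count) / membrane-transporter count.

Strategy labels (Scarcity, Ruderal, Competitor) are assigned by nearest
centroid in z-scored index space; centroids are the per-label means of a
labeled training set, with scaling parameters taken from that same set.
The shipped default training set is synthetic — a clearly labeled stand-in
for a user-supplied reference TSV.  Classification is deterministic; ties
resolve to the fixed label order Scarcity < Ruderal < Competitor with a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRATEGY_LABELS",
    "InvestmentIndices",
    "StrategyCentroids",
    "StrategyCall",
    "regulatory_flexibility_index",
    "resource_acquisition_index",
    "indices_from_counts",
    "fit_centroids",
    "classify_strategy",
    "classify_genomes",
]

#: Fixed label order; also the tie-break order.
STRATEGY_LABELS: tuple[str, ...] = ("Scarcity", "Ruderal", "Competitor")


@dataclass(frozen=True)
class InvestmentIndices:
    genome_id: str
    regulatory_flexibility: float
    resource_acquisition: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.regulatory_flexibility <= 1.0:
            raise ValueError("regulatory_flexibility must be in [0, 1]")
        if self.resource_acquisition < 0.0:
            raise ValueError("resource_acquisition must be >= 0")

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.regulatory_flexibility, self.resource_acquisition])


@dataclass(frozen=True)
class StrategyCentroids:
    centroids: Mapping[str, np.ndarray]  # label -> scaled 2-vector
    scale_mean: np.ndarray
    scale_sd: np.ndarray

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.scale_mean) / self.scale_sd


@dataclass(frozen=True)
class StrategyCall:
    genome_id: str
    label: str
    distances: Mapping[str, float]  # scaled-space distance to each centroid
    tie: bool = False


def regulatory_flexibility_index(n_tf: int, n_genes_total: int) -> float:
    """Transcription-factor count relative to total gene count."""
    if n_genes_total <= 0:
        raise ValueError("n_genes_total must be positive")
    if n_tf < 0 or n_tf > n_genes_total:
        raise ValueError("n_tf must be in [0, n_genes_total]")
    return n_tf / n_genes_total


def resource_acquisition_index(
    n_secreted_cazymes: int,
    n_secreted_proteases: int,
    n_secreted_lipases: int,
    n_bgc: int,
    n_transporters: int,
) -> float:
    """Secreted-enzyme and BGC counts per membrane transporter."""
    counts = (n_secreted_cazymes, n_secreted_proteases, n_secreted_lipases, n_bgc)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    if n_transporters <= 0:
        raise ValueError("n_transporters must be positive")
    return sum(counts) / n_transporters


def indices_from_counts(row: Mapping[str, int], genome_id: str) -> InvestmentIndices:
    """Build both indices from a genome table row of annotation counts."""
    return InvestmentIndices(
        genome_id=genome_id,
        regulatory_flexibility=regulatory_flexibility_index(
            int(row["n_tf"]), int(row["n_genes_total"])
        ),
        resource_acquisition=resource_acquisition_index(
            int(row["n_secreted_cazymes"]),
            int(row["n_secreted_proteases"]),
            int(row["n_secreted_lipases"]),
            int(row["n_bgc"]),
            int(row["n_transporters"]),
        ),
    )


def fit_centroids(
    training: Sequence[tuple[InvestmentIndices, str]]
) -> StrategyCentroids:
    """Fit per-label centroids in z-scored index space.

    Scaling (mean, sd per dimension) comes from all training points
    pooled; each centroid is the mean of its label's scaled points.
    Deterministic — no random initialization.
    """
    labels = {lab for _, lab in training}
    missing = set(STRATEGY_LABELS) - labels
    if missing:
        raise ValueError(f"training set lacks label(s): {sorted(missing)}")
    unknown = labels - set(STRATEGY_LABELS)
    if unknown:
        raise ValueError(f"unknown strategy label(s): {sorted(unknown)}")
    coords = np.array([idx.coords for idx, _ in training])
    if len(np.unique(coords, axis=0)) < 2:
        raise ValueError("training set needs at least 2 distinct coordinates")
    mean = coords.mean(axis=0)
    sd = coords.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero variance in a training dimension; cannot scale")
    scaled = (coords - mean) / sd
    labs = np.array([lab for _, lab in training])
    centroids = {
        lab: scaled[labs == lab].mean(axis=0) for lab in STRATEGY_LABELS
    }
    return StrategyCentroids(centroids=centroids, scale_mean=mean, scale_sd=sd)


def classify_strategy(idx: InvestmentIndices, c: StrategyCentroids) -> StrategyCall:
    """Assign the nearest-centroid label (Euclidean, scaled space)."""
    z = c.transform(idx.coords)
    distances = {
        lab: float(np.linalg.norm(z - c.centroids[lab])) for lab in STRATEGY_LABELS
    }
    best = min(distances.values())
    winners = [lab for lab in STRATEGY_LABELS if math.isclose(distances[lab], best, rel_tol=0, abs_tol=1e-12)]
    return StrategyCall(
        genome_id=idx.genome_id,
        label=winners[0],
        distances=distances,
        tie=len(winners) > 1,
    )


def classify_genomes(
    genomes: pd.DataFrame,
    centroids: StrategyCentroids,
    *,
    id_column: str = "genome_id",
) -> tuple[pd.DataFrame, list[str]]:
    """Classify every genome in an annotation-count table.

    Genomes whose indices cannot be computed (zero transporters, zero
    genes) are excluded and their ids returned for logging, not raised.
    """
    rows = []
    excluded: list[str] = []
    for _, row in genomes.iterrows():
        gid = str(row[id_column])
        try:
            idx = indices_from_counts(row, gid)
        except ValueError:
            excluded.append(gid)
            continue
        call = classify_strategy(idx, centroids)
        rows.append(
            {
                "genome_id": gid,
                "rf_index": idx.regulatory_flexibility,
                "ra_index": idx.resource_acquisition,
                "label": call.label,
                "d_scarcity": call.distances["Scarcity"],
                "d_ruderal": call.distances["Ruderal"],
                "d_competitor": call.distances["Competitor"],
                "tie_flag": call.tie,
            }
        )
    return pd.DataFrame(rows), excluded
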