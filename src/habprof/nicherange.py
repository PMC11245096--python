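"""Habitat-breadth records and generalist/specialist classification.

Two evidence routes exist and are never silently mixed: detection tables
(one study = one unit of evidence; strict mode asks for presence in every
declared habitat) and genome provenance (one genome = one unit; the
default generalist rule is presence in >= 2 habitats).  Taxa with too
little evidence are ``indeterminate`` rather than misclassified as
specialists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .taxonomy import parse_lineage

__all__ = [
    "BreadthRecord",
    "NicheCall",
    "habitat_breadth_from_detections",
    "habitat_breadth_from_genomes",
    "classify_niche",
    "MIN_STUDIES_DEFAULT",
    "MIN_GENOMES_DEFAULT",
]

#: Default evidence cutoffs (0 disables the exclusion).
MIN_STUDIES_DEFAULT = 250
MIN_GENOMES_DEFAULT = 5


@dataclass(frozen=True)
class BreadthRecord:
    taxon: str
    n_habitats_detected: int
    n_habitats_possible: int
    n_studies_or_genomes: int
    evidence: str  # "detections" | "genomes"

    def __post_init__(self) -> None:
        if not 0 <= self.n_habitats_detected <= self.n_habitats_possible:
            raise ValueError("breadth outside [0, possible]")


@dataclass(frozen=True)
class NicheCall:
    taxon: str
    label: str  # generalist | specialist | intermediate-breadth | indeterminate
    record: BreadthRecord


def habitat_breadth_from_detections(
    table: pd.DataFrame,
    taxon: str,
    rank: str,
    habitat_universe: Iterable[str],
) -> BreadthRecord:
    """Breadth of a taxon over the declared habitat universe, from detections."""
    universe = set(habitat_universe)
    unknown = set(table["habitat"].unique()) - universe
    if unknown:
        raise ValueError(f"habitat labels outside declared universe: {sorted(unknown)}")
    names = table["lineage"].map(lambda s: parse_lineage(s).at_rank(rank))
    rows = table[names == taxon]
    return BreadthRecord(
        taxon=taxon,
        n_habitats_detected=int(rows["habitat"].nunique()),
        n_habitats_possible=len(universe),
        n_studies_or_genomes=int(rows["dataset_id"].nunique()),
        evidence="detections",
    )


def habitat_breadth_from_genomes(
    genomes: pd.DataFrame,
    taxon: str,
    rank: str,
    habitat_universe: Optional[Iterable[str]] = None,
) -> BreadthRecord:
    """Breadth of a taxon from genome source habitats.

    ``genomes`` needs columns ``genome_id``, ``lineage``, ``habitat``.
    When no universe is given, the table's own label set defines it.
    """
    universe = (
        set(genomes["habitat"].unique())
        if habitat_universe is None
        else set(habitat_universe)
    )
    unknown = set(genomes["habitat"].unique()) - universe
    if unknown:
        raise ValueError(f"habitat labels outside declared universe: {sorted(unknown)}")
    names = genomes["lineage"].map(lambda s: parse_lineage(s).at_rank(rank))
    rows = genomes[names == taxon]
    return BreadthRecord(
        taxon=taxon,
        n_habitats_detected=int(rows["habitat"].nunique()),
        n_habitats_possible=len(universe),
        n_studies_or_genomes=int(len(rows)),
        evidence="genomes",
    )


def classify_niche(
    rec: BreadthRecord,
    mode: str = "strict-all-habitats",
    k: int = 2,
    min_evidence: int = 0,
) -> NicheCall:
    """Label a breadth record generalist / specialist / indeterminate.

    ``strict-all-habitats`` calls a generalist only at full breadth;
    ``at-least-k`` at breadth >= k (k >= 2).  Records below
    ``min_evidence`` (or with no evidence at all) are ``indeterminate``.
    Strict-mode taxa with breadth strictly between 1 and full are reported
    as ``intermediate-breadth`` rather than forced into a binary.
    """
    if mode not in ("strict-all-habitats", "at-least-k"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "at-least-k" and k < 2:
        raise ValueError("k must be >= 2 in at-least-k mode")
    if rec.n_studies_or_genomes < max(min_evidence, 1):
        label = "indeterminate"
    elif mode == "strict-all-habitats":
        if rec.n_habitats_detected == rec.n_habitats_possible:
            label = "generalist"
        elif rec.n_habitats_detected == 1:
            label = "specialist"
        else:
            label = "intermediate-breadth"
    else:
        if rec.n_habitats_detected >= k:
            label = "generalist"
        elif rec.n_habitats_detected == 1:
            label = "specialist"
        else:  # breadth 0 with nonzero evidence cannot occur
            label = "indeterminate"
    return NicheCall(taxon=rec.taxon, label=label, record=rec)
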