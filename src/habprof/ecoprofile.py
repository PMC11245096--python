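"""Ubiquity, soil-preference metrics, and SPL/NSPL/intermediate/rare calls.

A detection table row *is* a detection: relative abundance is only recorded
where a taxon was found, so the habitat-wide dataset totals (the ubiquity
denominators) are supplied separately as a census mapping.

Classification thresholds (all strict comparisons):

* ``rare``: below-threshold ubiquity (default 4%) in every habitat;
* ``SPL`` (soil-preferring): soil ubiquity > 75% and soil:non-soil
  ubiquity ratio > 4;
* ``NSPL`` (non-soil-preferring): ubiquity ratio < 4 and soil:non-soil
  mean-abundance ratio < 1;
* ``intermediate``: everything else (boundary values land here).

Host-associated datasets are excluded from the non-soil group by default
before any soil/non-soil comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .taxonomy import aggregate_to_rank

__all__ = [
    "DEFAULT_EXCLUDE",
    "Thresholds",
    "HabitatSummary",
    "PreferenceMetrics",
    "PreferenceCall",
    "CensusError",
    "compute_ubiquity",
    "soil_nonsoil_partition",
    "compute_preference_metrics",
    "classify_preference",
    "profile_all_taxa",
]

#: Habitat labels dropped from the non-soil group in soil/non-soil comparisons.
DEFAULT_EXCLUDE = frozenset({"host-associated"})


class CensusError(ValueError):
    """Census missing, inconsistent with detections, or empty."""


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs; comparisons are strict."""

    ubiquity: float = 75.0
    ratio: float = 4.0
    abundance_ratio: float = 1.0
    rare: float = 4.0

    def __post_init__(self) -> None:
        for name in ("ubiquity", "ratio", "abundance_ratio", "rare"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name!r} must be positive")


@dataclass(frozen=True)
class HabitatSummary:
    taxon: str
    habitat: str
    n_datasets: int
    n_detected: int
    ubiquity: float
    mean_abundance: float


@dataclass(frozen=True)
class PreferenceMetrics:
    taxon: str
    soil_ubiquity: float
    nonsoil_ubiquity: float
    preference_ratio: float
    soil_mean_abundance: float
    nonsoil_mean_abundance: float
    abundance_ratio: float
    absent: bool = False


@dataclass(frozen=True)
class PreferenceCall:
    taxon: str
    label: str  # SPL | NSPL | intermediate | rare
    metrics: PreferenceMetrics
    flags: tuple[str, ...] = field(default=())


def _taxon_rows(table: pd.DataFrame, taxon: str, rank: str) -> pd.DataFrame:
    """Rows of ``table`` belonging to ``taxon`` at ``rank``, one per dataset."""
    agg = aggregate_to_rank(table, rank)
    from .taxonomy import parse_lineage

    names = agg["lineage"].map(lambda s: parse_lineage(s).at_rank(rank))
    return agg[names == taxon]


def compute_ubiquity(
    table: pd.DataFrame,
    taxon: str,
    rank: str,
    habitat_group: Iterable[str],
    dataset_census: Mapping[str, int],
    *,
    include_undetected_in_mean: bool = False,
) -> HabitatSummary:
    """Ubiquity and mean relative abundance of one taxon over a habitat group.

    Parameters
    ----------
    table
        Detection table (``dataset_id``, ``habitat``, ``lineage``,
        ``relative_abundance_pct``).
    taxon, rank
        Name of the taxon at the stated rank.
    habitat_group
        Habitat labels pooled into one denominator.
    dataset_census
        Habitat label -> total number of datasets surveyed (detected or not).
    include_undetected_in_mean
        If True, mean abundance averages zeros over all census datasets;
        default averages over detected datasets only.

    Raises
    ------
    CensusError
        If the group's census total is zero, a group habitat is uncensused,
        or detections exceed the census for some habitat.
    """
    group = set(habitat_group)
    missing = group - set(dataset_census)
    if missing:
        raise CensusError(f"habitats missing from census: {sorted(missing)}")
    n_datasets = sum(int(dataset_census[h]) for h in group)
    if n_datasets == 0:
        raise CensusError(f"census total for group {sorted(group)} is zero; ubiquity undefined")

    rows = _taxon_rows(table, taxon, rank)
    rows = rows[rows["habitat"].isin(group)]
    # sanity: per-habitat detections cannot exceed the census
    per_hab = rows.groupby("habitat")["dataset_id"].nunique()
    for hab, n_det in per_hab.items():
        if n_det > int(dataset_census[hab]):
            raise CensusError(
                f"{n_det} detections in habitat {hab!r} exceed census count "
                f"{dataset_census[hab]}"
            )
    n_detected = int(rows["dataset_id"].nunique())
    ubiquity = 100.0 * n_detected / n_datasets
    if n_detected == 0:
        mean_abund = 0.0
    else:
        per_dataset = rows.groupby("dataset_id")["relative_abundance_pct"].sum()
        denom = n_datasets if include_undetected_in_mean else n_detected
        mean_abund = float(per_dataset.sum() / denom)
    label = next(iter(group)) if len(group) == 1 else "+".join(sorted(group))
    return HabitatSummary(
        taxon=taxon,
        habitat=label,
        n_datasets=n_datasets,
        n_detected=n_detected,
        ubiquity=ubiquity,
        mean_abundance=mean_abund,
    )


def soil_nonsoil_partition(
    habitats: Iterable[str], exclude: Optional[Iterable[str]] = None
) -> tuple[set[str], set[str]]:
    """Split habitat labels into the soil group and the non-soil group.

    ``exclude`` (default: host-associated) is removed from the non-soil side.
    """
    labels = set(habitats)
    if "soil" not in labels:
        raise ValueError("habitat label 'soil' not present")
    excl = DEFAULT_EXCLUDE if exclude is None else set(exclude)
    return {"soil"}, labels - {"soil"} - excl


def _ratio(num: float, den: float) -> float:
    """Quotient with the infinite marker on a zero denominator."""
    if den == 0:
        return math.inf
    return num / den


def compute_preference_metrics(
    table: pd.DataFrame,
    taxon: str,
    rank: str,
    census: Mapping[str, int],
    *,
    exclude: Optional[Iterable[str]] = None,
    include_undetected_in_mean: bool = False,
) -> PreferenceMetrics:
    """Soil vs non-soil ubiquity and mean-abundance ratios for one taxon.

    Ratios are quotients of the ubiquity *percentages* (and of the mean
    abundances), not of raw dataset counts.  Zero denominators yield
    ``math.inf`` rather than an exception; a taxon absent everywhere yields
    all-zero metrics with ``absent=True``.
    """
    soil_group, nonsoil_group = soil_nonsoil_partition(census.keys(), exclude)
    if not nonsoil_group:
        raise CensusError("non-soil group is empty after exclusions")
    soil = compute_ubiquity(
        table, taxon, rank, soil_group, census,
        include_undetected_in_mean=include_undetected_in_mean,
    )
    nonsoil = compute_ubiquity(
        table, taxon, rank, nonsoil_group, census,
        include_undetected_in_mean=include_undetected_in_mean,
    )
    absent = soil.n_detected == 0 and nonsoil.n_detected == 0
    if absent:
        return PreferenceMetrics(taxon, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, absent=True)
    return PreferenceMetrics(
        taxon=taxon,
        soil_ubiquity=soil.ubiquity,
        nonsoil_ubiquity=nonsoil.ubiquity,
        preference_ratio=_ratio(soil.ubiquity, nonsoil.ubiquity),
        soil_mean_abundance=soil.mean_abundance,
        nonsoil_mean_abundance=nonsoil.mean_abundance,
        abundance_ratio=_ratio(soil.mean_abundance, nonsoil.mean_abundance),
        absent=False,
    )


def classify_preference(
    m: PreferenceMetrics,
    max_ubiquity_any_habitat: float,
    thresholds: Thresholds = Thresholds(),
) -> PreferenceCall:
    """Assign SPL / NSPL / intermediate / rare from preference metrics.

    Infinite ratio markers compare as greater than any finite threshold.
    Boundary values (exact threshold hits) fall to ``intermediate``.
    """
    flags: list[str] = []
    if m.absent:
        flags.append("absent")
    if max_ubiquity_any_habitat < thresholds.rare:
        label = "rare"
    elif m.soil_ubiquity > thresholds.ubiquity and m.preference_ratio > thresholds.ratio:
        label = "SPL"
    elif (
        m.preference_ratio < thresholds.ratio
        and m.abundance_ratio < thresholds.abundance_ratio
    ):
        label = "NSPL"
    else:
        label = "intermediate"
    return PreferenceCall(taxon=m.taxon, label=label, metrics=m, flags=tuple(flags))


def profile_all_taxa(
    table: pd.DataFrame,
    rank: str,
    census: Mapping[str, int],
    thresholds: Thresholds = Thresholds(),
    *,
    exclude: Optional[Iterable[str]] = None,
    include_undetected_in_mean: bool = False,
) -> tuple[list[PreferenceCall], pd.DataFrame]:
    """Preference calls for every taxon at ``rank``, plus the summary grid.

    Returns calls in lexicographic taxon order and a tidy DataFrame of
    per-(taxon, habitat) summaries over every censused habitat.  Degenerate
    taxa are flagged, never fatal for the batch.
    """
    if len(table) == 0:
        return [], pd.DataFrame(
            columns=["taxon", "habitat", "n_datasets", "n_detected", "ubiquity", "mean_abundance"]
        )
    from .taxonomy import parse_lineage

    agg = aggregate_to_rank(table, rank)
    taxa = sorted(agg["lineage"].map(lambda s: parse_lineage(s).at_rank(rank)).unique())

    calls: list[PreferenceCall] = []
    grid_rows: list[HabitatSummary] = []
    for taxon in taxa:
        summaries = {
            hab: compute_ubiquity(
                table, taxon, rank, {hab}, census,
                include_undetected_in_mean=include_undetected_in_mean,
            )
            for hab in census
            if census[hab] > 0
        }
        grid_rows.extend(summaries.values())
        max_ubiq = max(s.ubiquity for s in summaries.values())
        metrics = compute_preference_metrics(
            table, taxon, rank, census,
            exclude=exclude, include_undetected_in_mean=include_undetected_in_mean,
        )
        calls.append(classify_preference(metrics, max_ubiq, thresholds))
    grid = pd.DataFrame(
        [
            {
                "taxon": s.taxon,
                "habitat": s.habitat,
                "n_datasets": s.n_datasets,
                "n_detected": s.n_detected,
                "ubiquity": s.ubiquity,
                "mean_abundance": s.mean_abundance,
            }
            for s in grid_rows
        ]
    ).sort_values(["taxon", "habitat"], ignore_index=True)
    return calls, grid
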