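"""Ranked-lineage parsing and rank-level aggregation.

Lineage strings follow the GTDB dialect: semicolon-delimited, rank-prefixed
tokens ``d__...;p__...;c__...;o__...;f__...;g__...``, filled contiguously
from domain downward.  Names are compared as exact strings after trimming
whitespace; placeholder names (e.g. alphanumeric codes like ``UBA7541``)
are ordinary names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "RANKS",
    "RANK_PREFIXES",
    "LineageError",
    "RankedLineage",
    "parse_lineage",
    "lineage_at_rank",
    "aggregate_to_rank",
]

#: Recognized ranks, shallowest first.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Rank -> GTDB prefix.
RANK_PREFIXES: dict[str, str] = {
    "domain": "d__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
}

_PREFIX_TO_RANK = {v: k for k, v in RANK_PREFIXES.items()}
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


class LineageError(ValueError):
    """Malformed lineage string or invalid rank request."""


@dataclass(frozen=True)
class RankedLineage:
    """Ordered taxon path from domain to genus.

    Ranks are filled contiguously from domain downward: a filled rank below
    a missing rank is invalid and rejected at construction.
    """

    domain: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None

    def __post_init__(self) -> None:
        names = self.names()
        seen_missing = False
        for rank, name in zip(RANKS, names):
            if name is None:
                seen_missing = True
            elif seen_missing:
                raise LineageError(
                    f"rank '{rank}' is filled below a missing rank "
                    f"(lineage must be contiguous from domain downward)"
                )

    def names(self) -> tuple[Optional[str], ...]:
        return (self.domain, self.phylum, self.class_, self.order, self.family, self.genus)

    @property
    def depth(self) -> int:
        """Number of filled ranks."""
        return sum(n is not None for n in self.names())

    def at_rank(self, rank: str) -> Optional[str]:
        """Name at ``rank`` or ``None`` if that rank is missing."""
        if rank not in _RANK_INDEX:
            raise LineageError(f"unrecognized rank {rank!r}; expected one of {RANKS}")
        return self.names()[_RANK_INDEX[rank]]

    def truncate(self, rank: str) -> "RankedLineage":
        """Lineage with every rank below ``rank`` dropped."""
        if rank not in _RANK_INDEX:
            raise LineageError(f"unrecognized rank {rank!r}; expected one of {RANKS}")
        keep = _RANK_INDEX[rank] + 1
        names = list(self.names()[:keep]) + [None] * (len(RANKS) - keep)
        return RankedLineage(*names)

    def render(self) -> str:
        """Render back to the prefixed string form; inverse of :func:`parse_lineage`."""
        parts = [
            RANK_PREFIXES[rank] + name
            for rank, name in zip(RANKS, self.names())
            if name is not None
        ]
        return ";".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_lineage(text: str) -> RankedLineage:
    """Parse a GTDB-style lineage string into a :class:`RankedLineage`.

    Parameters
    ----------
    text
        Semicolon-delimited, rank-prefixed string; prefixes must appear in
        domain→genus order with no rank skipped.

    Raises
    ------
    LineageError
        On empty input, unknown prefix, out-of-order or duplicate ranks,
        or a filled rank below a missing one.
    """
    if not isinstance(text, str) or not text.strip():
        raise LineageError("empty lineage string")
    names: dict[str, Optional[str]] = {}
    last_index = -1
    for token in text.split(";"):
        token = token.strip()
        if not token:
            raise LineageError(f"empty token in lineage {text!r}")
        prefix = token[:3]
        if prefix not in _PREFIX_TO_RANK:
            raise LineageError(f"unknown rank prefix in token {token!r}")
        rank = _PREFIX_TO_RANK[prefix]
        idx = _RANK_INDEX[rank]
        if rank in names:
            raise LineageError(f"duplicate rank in token {token!r}")
        if idx <= last_index:
            raise LineageError(f"out-of-order rank in token {token!r}")
        last_index = idx
        suffix = token[3:].strip()
        names[rank] = suffix if suffix else None
    kwargs = {
        "domain": names.get("domain"),
        "phylum": names.get("phylum"),
        "class_": names.get("class"),
        "order": names.get("order"),
        "family": names.get("family"),
        "genus": names.get("genus"),
    }
    try:
        return RankedLineage(**kwargs)
    except LineageError as exc:
        raise LineageError(f"in lineage {text!r}: {exc}") from None


def lineage_at_rank(lin: RankedLineage, rank: str) -> Optional[str]:
    """Project a lineage onto one rank; ``None`` when the rank is missing."""
    return lin.at_rank(rank)


def aggregate_to_rank(table: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Aggregate a detection table to a shallower rank.

    Parameters
    ----------
    table
        Detection table with columns ``dataset_id``, ``habitat``,
        ``lineage`` (rendered lineage strings), ``relative_abundance_pct``.
    rank
        Target rank; every row's lineage must be at least this deep.

    Returns
    -------
    pandas.DataFrame
        One row per (dataset, lineage-truncated-at-rank); relative abundance
        is the sum over child rows within the dataset.

    Raises
    ------
    LineageError
        If ``rank`` is unknown or any row's lineage is shallower than it.
    """
    if rank not in _RANK_INDEX:
        raise LineageError(f"unrecognized rank {rank!r}; expected one of {RANKS}")
    parsed = {s: parse_lineage(s) for s in table["lineage"].unique()}
    too_shallow = sorted(
        s for s, lin in parsed.items() if lin.at_rank(rank) is None
    )
    if too_shallow:
        raise LineageError(
            f"{len(too_shallow)} lineage(s) shallower than rank {rank!r}: "
            + "; ".join(too_shallow[:5])
        )
    truncated = table["lineage"].map(lambda s: parsed[s].truncate(rank).render())
    out = (
        table.assign(lineage=truncated)
        .groupby(["dataset_id", "habitat", "lineage"], as_index=False, sort=True)[
            "relative_abundance_pct"
        ]
        .sum()
    )
    return out[["dataset_id", "habitat", "lineage", "relative_abundance_pct"]]
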