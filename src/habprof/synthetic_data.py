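"""Synthetic detection and genome tables with known ground truth.

Every downstream stage (ecoprofile, nicherange, varpart, lifehistory) is
testable offline against tables generated here.  Generators are seeded and
deterministic; one global seed drives an independent substream per
(taxon, habitat) / (class, habitat) / label, so adding taxa to a config
does not perturb the draws of existing taxa.

Modeling choices (stand-ins, isolated behind the configs):

* detections are independent Bernoulli events per (taxon, dataset);
* abundances are log-normal, truncated to (0, 100] percent;
* continuous genome features are class baseline + habitat offset +
  interaction offset + Gaussian noise;
* binary traits are Bernoulli with a logit-linear class + habitat model;
* life-history annotation counts are reverse-engineered so the two
  investment indices land on the genome's archetype coordinate plus
  Gaussian jitter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lifehistory import STRATEGY_LABELS
from .taxonomy import RankedLineage, parse_lineage

__all__ = [
    "TaxonSpec",
    "EcosystemSimConfig",
    "BinaryTraitSpec",
    "ArchetypeSpec",
    "GenomeSimConfig",
    "generate_detection_table",
    "generate_genome_table",
    "generate_training_set",
    "default_archetypes",
]

# reference scales for reverse-engineering annotation counts from indices
_GENES_TOTAL = 4000
_TRANSPORTERS = 400


def _substream(seed: int, *tokens: str, salt: int = 0) -> np.random.Generator:
    """Independent generator keyed by seed + string tokens."""
    entropy = [seed & 0xFFFFFFFF, salt]
    entropy.extend(zlib.crc32(t.encode()) for t in tokens)
    return np.random.default_rng(entropy)


@dataclass(frozen=True)
class TaxonSpec:
    """One family-depth taxon with per-habitat occurrence parameters."""

    lineage: str  # rendered lineage, family depth or deeper
    detection_prob: Mapping[str, float]  # habitat -> p in [0, 1]
    log_abundance: Mapping[str, tuple[float, float]]  # habitat -> (mu, sd) of ln(%)

    def family(self) -> str:
        name = parse_lineage(self.lineage).at_rank("family")
        if name is None:
            raise ValueError(f"taxon lineage {self.lineage!r} lacks a family rank")
        return name


@dataclass(frozen=True)
class EcosystemSimConfig:
    habitats: Mapping[str, int]  # habitat -> dataset count
    taxa: Sequence[TaxonSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        for hab, n in self.habitats.items():
            if n < 0:
                raise ValueError(f"dataset count for {hab!r} must be >= 0")
        families = [t.family() for t in self.taxa]
        if len(set(families)) != len(families):
            raise ValueError("family names must be unique across taxa")
        for t in self.taxa:
            for hab, p in t.detection_prob.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"detection probability {p} outside [0,1]")
            for hab, (_, sd) in t.log_abundance.items():
                if sd < 0:
                    raise ValueError("log-abundance sd must be >= 0")


def generate_detection_table(cfg: EcosystemSimConfig) -> pd.DataFrame:
    """Draw a detection table from the configured occurrence model.

    Each (taxon, dataset) detection is an independent Bernoulli draw at the
    taxon's per-habitat probability; detected rows carry a log-normal
    relative abundance truncated to (0, 100] percent.
    """
    records: list[tuple[str, str, str, float]] = []
    for taxon in cfg.taxa:
        for hab, n in cfg.habitats.items():
            if n == 0:
                continue
            p = taxon.detection_prob.get(hab, 0.0)
            if p == 0.0:
                continue
            rng = _substream(cfg.seed, taxon.family(), hab, salt=1)
            detected = rng.random(n) < p
            mu, sd = taxon.log_abundance.get(hab, (0.0, 1.0))
            abund = np.exp(rng.normal(mu, sd, size=n))
            abund = np.minimum(abund, 100.0)
            for i in np.flatnonzero(detected):
                records.append(
                    (f"{hab}_{i:06d}", hab, taxon.lineage, float(abund[i]))
                )
    df = pd.DataFrame(
        records,
        columns=["dataset_id", "habitat", "lineage", "relative_abundance_pct"],
    )
    return df.sort_values(
        ["habitat", "dataset_id", "lineage"], ignore_index=True
    )


@dataclass(frozen=True)
class BinaryTraitSpec:
    """Logit-linear presence model: baseline + class offset + habitat offset."""

    baseline: float = 0.0
    class_offsets: Mapping[str, float] = field(default_factory=dict)
    habitat_offsets: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Mean and sd of the two investment-index coordinates for one strategy."""

    rf_mean: float
    ra_mean: float
    rf_sd: float
    ra_sd: float

    def __post_init__(self) -> None:
        if self.rf_sd < 0 or self.ra_sd < 0:
            raise ValueError("archetype sds must be >= 0")


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """Well-separated stand-in archetypes for the three strategies."""
    return {
        "Scarcity": ArchetypeSpec(rf_mean=0.012, ra_mean=0.20, rf_sd=0.002, ra_sd=0.05),
        "Ruderal": ArchetypeSpec(rf_mean=0.050, ra_mean=0.60, rf_sd=0.004, ra_sd=0.10),
        "Competitor": ArchetypeSpec(rf_mean=0.028, ra_mean=2.00, rf_sd=0.003, ra_sd=0.25),
    }


@dataclass(frozen=True)
class GenomeSimConfig:
    class_baselines: Mapping[str, Mapping[str, float]]  # class -> feature -> value
    habitat_offsets: Mapping[str, Mapping[str, float]]  # habitat -> feature -> offset
    n_per_cell: Mapping[tuple[str, str], int]  # (class, habitat) -> genome count
    residual_sd: Mapping[str, float]  # feature -> sd
    interaction_offsets: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=dict
    )
    binary_traits: Mapping[str, BinaryTraitSpec] = field(default_factory=dict)
    archetypes: Mapping[str, ArchetypeSpec] = field(default_factory=default_archetypes)
    class_strategy: Mapping[str, str] = field(default_factory=dict)  # class -> label
    phylum: str = "Simulobacterota"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.archetypes) != set(STRATEGY_LABELS):
            raise ValueError(
                f"archetypes must carry exactly the labels {STRATEGY_LABELS}"
            )
        for key, n in self.n_per_cell.items():
            if n < 0:
                raise ValueError(f"genome count for cell {key} must be >= 0")
        for feat, sd in self.residual_sd.items():
            if sd < 0:
                raise ValueError(f"residual sd for {feat!r} must be >= 0")

    @property
    def features(self) -> list[str]:
        first = next(iter(self.class_baselines.values()))
        return list(first)

    def lineage_for(self, cls: str) -> str:
        return RankedLineage(domain="Bacteria", phylum=self.phylum, class_=cls).render()


def _counts_from_indices(rf: float, ra: float) -> dict[str, int]:
    """Reverse-engineer annotation counts whose indices approximate (rf, ra)."""
    rf = float(np.clip(rf, 0.0, 1.0))
    ra = max(float(ra), 0.0)
    n_tf = int(round(rf * _GENES_TOTAL))
    total_secreted = int(round(ra * _TRANSPORTERS))
    n_bgc = total_secreted // 4
    rest = total_secreted - n_bgc
    n_caz = rest // 2
    n_prot = (rest - n_caz) // 2
    n_lip = rest - n_caz - n_prot
    return {
        "n_tf": n_tf,
        "n_genes_total": _GENES_TOTAL,
        "n_secreted_cazymes": n_caz,
        "n_secreted_proteases": n_prot,
        "n_secreted_lipases": n_lip,
        "n_bgc": n_bgc,
        "n_transporters": _TRANSPORTERS,
    }


def generate_genome_table(
    cfg: GenomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a genome table plus a ground-truth record of generating effects.

    Returns
    -------
    (genomes, truth)
        ``genomes`` has one row per genome with lineage, habitat, the
        configured continuous features, and life-history annotation counts.
        ``truth`` is tidy, keyed by (class, habitat, feature), recording the
        class baseline, habitat offset, interaction offset, and residual sd
        that generated each cell, plus per-genome strategy labels in a
        ``strategy:<genome_id>`` pseudo-feature block.
    """
    features = cfg.features
    rows: list[dict] = []
    truth_rows: list[dict] = []
    for cls, baselines in cfg.class_baselines.items():
        for hab, hab_offsets in cfg.habitat_offsets.items():
            n = int(cfg.n_per_cell.get((cls, hab), 0))
            inter = cfg.interaction_offsets.get((cls, hab), {})
            for feat in features:
                truth_rows.append(
                    {
                        "class": cls,
                        "habitat": hab,
                        "feature": feat,
                        "baseline": baselines[feat],
                        "habitat_offset": hab_offsets.get(feat, 0.0),
                        "interaction_offset": inter.get(feat, 0.0),
                        "residual_sd": cfg.residual_sd.get(feat, 0.0),
                        "n_genomes": n,
                    }
                )
            if n == 0:
                continue
            rng = _substream(cfg.seed, cls, hab, salt=2)
            for i in range(n):
                gid = f"{cls}_{hab}_{i:04d}".replace(" ", "-")
                row: dict = {
                    "genome_id": gid,
                    "lineage": cfg.lineage_for(cls),
                    "habitat": hab,
                }
                for feat in features:
                    mean = (
                        baselines[feat]
                        + hab_offsets.get(feat, 0.0)
                        + inter.get(feat, 0.0)
                    )
                    sd = cfg.residual_sd.get(feat, 0.0)
                    row[feat] = float(mean + (rng.normal(0.0, sd) if sd > 0 else 0.0))
                for trait, spec in cfg.binary_traits.items():
                    logit = (
                        spec.baseline
                        + spec.class_offsets.get(cls, 0.0)
                        + spec.habitat_offsets.get(hab, 0.0)
                    )
                    p = 1.0 / (1.0 + np.exp(-logit))
                    row[f"trait_{trait}"] = int(rng.random() < p)
                label = cfg.class_strategy.get(cls) or STRATEGY_LABELS[
                    rng.integers(len(STRATEGY_LABELS))
                ]
                arch = cfg.archetypes[label]
                rf = rng.normal(arch.rf_mean, arch.rf_sd) if arch.rf_sd > 0 else arch.rf_mean
                ra = rng.normal(arch.ra_mean, arch.ra_sd) if arch.ra_sd > 0 else arch.ra_mean
                row.update(_counts_from_indices(rf, ra))
                row["true_strategy"] = label
                rows.append(row)
    genomes = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return genomes, truth


def generate_training_set(
    cfg: GenomeSimConfig, n_per_label: int, seed: Optional[int] = None
) -> pd.DataFrame:
    """Labeled investment-index points drawn from the configured archetypes.

    Returns a frame with columns ``id``, ``regulatory_flexibility``,
    ``resource_acquisition``, ``label`` — the training-TSV schema.
    """
    if n_per_label < 1:
        raise ValueError("n_per_label must be >= 1")
    seed = cfg.seed if seed is None else seed
    rows = []
    for label in STRATEGY_LABELS:
        arch = cfg.archetypes[label]
        rng = _substream(seed, label, salt=3)
        for i in range(n_per_label):
            rf = rng.normal(arch.rf_mean, arch.rf_sd) if arch.rf_sd > 0 else arch.rf_mean
            ra = rng.normal(arch.ra_mean, arch.ra_sd) if arch.ra_sd > 0 else arch.ra_mean
            rows.append(
                {
                    "id": f"train_{label}_{i:03d}",
                    "regulatory_flexibility": float(np.clip(rf, 0.0, 1.0)),
                    "resource_acquisition": max(float(ra), 0.0),
                    "label": label,
                }
            )
    return pd.DataFrame(rows)
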