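"""Shared fixtures: tiny hand-built detection tables and simulator configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from habprof.synthetic_data import (
    ArchetypeSpec,
    EcosystemSimConfig,
    GenomeSimConfig,
    TaxonSpec,
)

HABITATS = (
    "soil",
    "engineered",
    "freshwater",
    "host-associated",
    "marine",
    "non-marine saline and alkaline",
    "terrestrial non-soil",
)


def det_row(dataset_id: str, habitat: str, lineage: str, abund: float) -> dict:
    return {
        "dataset_id": dataset_id,
        "habitat": habitat,
        "lineage": lineage,
        "relative_abundance_pct": abund,
    }


def make_detection_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["dataset_id", "habitat", "lineage", "relative_abundance_pct"]
    )


def random_detection_table(
    rng: np.random.Generator, n_datasets: int = 8, n_families: int = 3
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Small random table + census over two habitats, for brute-force checks."""
    habitats = ["soil", "marine"]
    rows = []
    census = {h: 0 for h in habitats}
    lineages = [
        f"d__B;p__P;c__C{i % 2};o__O{i};f__F{i}" for i in range(n_families)
    ]
    for d in range(n_datasets):
        hab = habitats[d % 2]
        census[hab] += 1
        for lin in lineages:
            if rng.random() < 0.5:
                rows.append(det_row(f"ds{d}", hab, lin, float(rng.uniform(0.1, 10))))
    return make_detection_table(rows), census


@pytest.fixture
def two_habitat_table() -> tuple[pd.DataFrame, dict[str, int]]:
    """Deterministic micro-table: 4 soil + 4 marine datasets, 2 families."""
    fam_a = "d__B;p__P;c__C1;o__O1;f__FA"
    fam_b = "d__B;p__P;c__C1;o__O1;f__FB"
    rows = [
        det_row("s1", "soil", fam_a, 1.2),
        det_row("s1", "soil", fam_b, 0.8),
        det_row("s2", "soil", fam_a, 2.0),
        det_row("s3", "soil", fam_a, 0.5),
        det_row("m1", "marine", fam_a, 0.3),
        det_row("m2", "marine", fam_b, 0.4),
    ]
    census = {"soil": 4, "marine": 4}
    return make_detection_table(rows), census


def make_genome_sim_config(
    seed: int = 0,
    n_per_cell: int = 20,
    class_spread: float = 1.0,
    habitat_shift: float = 0.0,
    noise_sd: float = 1.0,
) -> GenomeSimConfig:
    """Three classes x two habitats, single feature 'x' with tunable effects."""
    return GenomeSimConfig(
        class_baselines={
            "Alpha": {"x": -class_spread},
            "Beta": {"x": 0.0},
            "Gamma": {"x": class_spread},
        },
        habitat_offsets={"soil": {"x": habitat_shift}, "marine": {}},
        n_per_cell={
            (c, h): n_per_cell
            for c in ("Alpha", "Beta", "Gamma")
            for h in ("soil", "marine")
        },
        residual_sd={"x": noise_sd},
        class_strategy={"Alpha": "Scarcity", "Beta": "Ruderal", "Gamma": "Competitor"},
        seed=seed,
    )


def make_separated_archetypes(sd_frac: float = 0.0) -> dict[str, ArchetypeSpec]:
    """Archetypes on a line; sd expressed as a fraction of centroid spacing."""
    coords = {"Scarcity": (0.01, 0.2), "Ruderal": (0.04, 1.0), "Competitor": (0.07, 1.8)}
    rf_spacing, ra_spacing = 0.03, 0.8
    return {
        lab: ArchetypeSpec(
            rf_mean=rf, ra_mean=ra,
            rf_sd=sd_frac * rf_spacing, ra_sd=sd_frac * ra_spacing,
        )
        for lab, (rf, ra) in coords.items()
    }


@pytest.fixture
def ecosystem_config() -> EcosystemSimConfig:
    nonsoil = [h for h in HABITATS if h != "soil"]
    taxa = [
        TaxonSpec(
            lineage="d__B;p__P;c__Soilia;o__SoilO;f__SoilF",
            detection_prob={"soil": 0.9, **{h: 0.05 for h in nonsoil}},
            log_abundance={"soil": (1.0, 0.4), **{h: (-1.0, 0.4) for h in nonsoil}},
        ),
        TaxonSpec(
            lineage="d__B;p__P;c__Aquatica;o__AquaO;f__AquaF",
            detection_prob={"soil": 0.05, **{h: 0.5 for h in nonsoil}},
            log_abundance={"soil": (-1.5, 0.4), **{h: (0.5, 0.4) for h in nonsoil}},
        ),
        TaxonSpec(
            lineage="d__B;p__P;c__Raritas;o__RareO;f__RareF",
            detection_prob={h: 0.02 for h in HABITATS},
            log_abundance={h: (-2.0, 0.4) for h in HABITATS},
        ),
    ]
    return EcosystemSimConfig(
        habitats={h: 500 for h in HABITATS}, taxa=taxa, seed=7
    )
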