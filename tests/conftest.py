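"""Shared fixtures: small seeded synthetic datasets, built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sigreverse.datatypes import DiseaseSignature
from sigreverse.synthetic_data import (
    CompendiumSpec,
    annotations_from_panel,
    default_compound_panel,
    generate_compendium,
    generate_disease_cohort,
    generate_drug_library,
    generate_sensitivity,
    random_planted_signature,
)


@pytest.fixture(scope="session")
def small_compendium():
    """Two-tissue compendium, 600 genes, seeded."""
    spec = CompendiumSpec(
        n_genes=600,
        n_landmark=400,
        tissues=[("brain", 40), ("liver", 30)],
        n_disease_samples=10,
        source_tissue="brain",
        seed=101,
    )
    return generate_compendium(spec)


@pytest.fixture(scope="session")
def planted(small_compendium):
    return random_planted_signature(
        small_compendium.landmark_genes, n_up=40, n_down=40, n_control=100, seed=102
    )


@pytest.fixture(scope="session")
def cohort(small_compendium, planted):
    return generate_disease_cohort(small_compendium, planted, 10, seed=103)


@pytest.fixture(scope="session")
def truth_signature(planted):
    """The planted ground truth wrapped as a DiseaseSignature."""
    return DiseaseSignature(
        up=list(planted.up_genes),
        down=list(planted.down_genes),
        lfc=planted.effect_log2fc,
        provenance="bulk",
    )


@pytest.fixture(scope="session")
def compound_panel():
    return default_compound_panel(n_compounds=60, n_strong=8, seed=104)


@pytest.fixture(scope="session")
def library(planted, compound_panel, small_compendium):
    return generate_drug_library(
        planted,
        compound_panel,
        landmark_genes=small_compendium.landmark_genes,
        noise_sd=0.3,
        seed=105,
    )


@pytest.fixture(scope="session")
def sensitivity_bundle(compound_panel):
    return generate_sensitivity(compound_panel, seed=106)


@pytest.fixture(scope="session")
def annotations(compound_panel):
    return annotations_from_panel(compound_panel)


def brute_force_es(positions, n) -> float:
    """Running-sum oracle for the signed KS enrichment score.

    Walks every rank position, tracking the empirical CDF of the gene
    set against the uniform CDF; independent of the closed-form
    implementation it checks.
    """
    hit_set = set(int(p) for p in positions)
    t = len(hit_set)
    best_top = -np.inf
    best_bottom = -np.inf
    hits_before = 0
    for i in range(1, n + 1):
        if i in hit_set:
            # excess just after stepping onto a hit (top concentration)
            top = (hits_before + 1) / t - i / n
            # excess just before the hit (bottom concentration)
            bottom = i / n - hits_before / t
            best_top = max(best_top, top)
            best_bottom = max(best_bottom, bottom)
            hits_before += 1
    return best_top if best_top > best_bottom else -best_bottom
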