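"""Shared fixtures: toy hierarchies, synthetic cohorts and trained models.

Everything is generated programmatically; expensive fixtures (the trained
planted-signal model) are session-scoped so the suite trains once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pathwaynet import (
    CohortDataset,
    ConstrainedPathwayClassifier,
    MaskStack,
    PathwayHierarchy,
    SyntheticCohortConfig,
    generate_cohort,
    preprocess_cohort,
    train_and_evaluate,
)
from pathwaynet.simulate import default_masks


@pytest.fixture()
def toy_hierarchy() -> PathwayHierarchy:
    """R -> C -> {A, B}; A holds g1,g2; B holds g3."""
    return PathwayHierarchy(
        pathways={"A": "path A", "B": "path B", "C": "path C", "R": "root"},
        gene_membership={"A": {"g1", "g2"}, "B": {"g3"}, "C": set(), "R": set()},
        parent_child={("C", "A"), ("C", "B"), ("R", "C")},
    )


@pytest.fixture()
def toy_masks() -> MaskStack:
    """3 genes -> 2 level-1 -> 1 level-2 -> 1 level-3 nodes, 6 connections."""
    return MaskStack(
        gene_order=["g1", "g2", "g3"],
        level_orders=[["A", "B"], ["C"], ["R"]],
        masks=[
            np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            np.array([[1.0], [1.0]]),
            np.array([[1.0]]),
        ],
    )


def random_dag_hierarchy(rng: np.random.Generator, n_pathways: int = 50,
                         n_genes: int = 40) -> PathwayHierarchy:
    """Random layered DAG fixture for oracle comparisons."""
    names = [f"P{i:02d}" for i in range(n_pathways)]
    genes = [f"g{i:02d}" for i in range(n_genes)]
    # order pathways; edges only from earlier (parent) to later (child)
    relations = set()
    for i, child in enumerate(names[5:], start=5):
        for parent in rng.choice(i, size=rng.integers(1, 3), replace=False):
            relations.add((names[parent], child))
    membership = {p: set() for p in names}
    for g in genes:
        for p in rng.choice(n_pathways, size=rng.integers(1, 4), replace=False):
            membership[names[p]].add(g)
    h = PathwayHierarchy(
        pathways={p: p for p in names}, gene_membership=membership, parent_child=relations
    )
    h.validate()
    return h


@pytest.fixture()
def small_cohort() -> CohortDataset:
    """Fast cohort: 30/30/20 samples, 60 genes, planted effects."""
    return generate_cohort(
        SyntheticCohortConfig(n_per_class=(30, 30, 20), n_genes=60,
                              n_planted_snp=5, n_planted_expression=5, seed=11)
    )


@pytest.fixture(scope="session")
def planted_setup():
    """Default study conditions: 212/317/97, 300 genes, effect 2.0."""
    cfg = SyntheticCohortConfig(seed=1)
    dataset = generate_cohort(cfg)
    mask_snp, mask_expr = default_masks(cfg)
    return cfg, dataset, mask_snp, mask_expr


@pytest.fixture(scope="session")
def planted_run(planted_setup):
    """One full preprocess + train + evaluate run on the planted cohort."""
    _, dataset, mask_snp, mask_expr = planted_setup
    model, processed, report = train_and_evaluate(dataset, mask_snp, mask_expr, seed=1)
    return dataset, mask_snp, mask_expr, model, processed, report
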