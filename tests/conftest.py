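"""Shared fixtures.

The heavy fixtures (trained promoter/distal models on n=2000-gene synthetic
datasets, three seeds) are session-scoped and shared between the model,
perturbation and acceptance tests so each training run happens once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from epitx.experiments import (
    DataBundle,
    causal_bin_recovery,
    distal_effects,
    prepare_bundle,
    train_distal_fold,
    train_promoter_fold,
)
from epitx.models import DistalModelConfig, PromoterModelConfig
from epitx.synthetic import SyntheticConfig, simulate_dataset

SEEDS = (101, 202, 303)


def planted_config(seed: int, n_genes: int = 2000) -> SyntheticConfig:
    """Study conditions with distal enhancers planted outside the promoter."""
    return SyntheticConfig(
        seed=seed, n_genes=n_genes, n_chromosomes=8, enhancers_per_gene=(1, 2),
        noise_sd=0.3,
    )


def promoter_only_config(seed: int, n_genes: int = 2000) -> SyntheticConfig:
    """Study conditions where expression depends on the promoter alone."""
    return SyntheticConfig(
        seed=seed, n_genes=n_genes, n_chromosomes=8, enhancers_per_gene=(0, 0),
        noise_sd=0.4,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(
        SyntheticConfig(seed=7, n_genes=24, n_chromosomes=4, enhancers_per_gene=(1, 2))
    )


@dataclass
class PlantedRun:
    bundle: DataBundle
    promoter_r: float
    distal_r: float
    distal_model: object
    effects: object  # level-0 ablation effects on the test fold
    median_rank: float
    top_fraction: float


@pytest.fixture(scope="session")
def planted_runs() -> list[PlantedRun]:
    """Promoter + distal models trained on planted-enhancer data, 3 seeds."""
    runs = []
    for seed in SEEDS:
        bundle = prepare_bundle(planted_config(seed))
        prom = train_promoter_fold(bundle, seed=seed, config=PromoterModelConfig(seed=seed))
        dist = train_distal_fold(bundle, seed=seed, config=DistalModelConfig(seed=seed))
        test_mask = bundle.folds == 0
        eff = distal_effects([dist.trained.model], bundle, gene_mask=test_mask)
        med, top, _ = causal_bin_recovery(eff, bundle)
        runs.append(
            PlantedRun(bundle, prom.test_r, dist.test_r, dist.trained.model, eff, med, top)
        )
    return runs


@pytest.fixture(scope="session")
def promoter_only_runs():
    """(bundle, promoter r, distal r) on promoter-only data, 3 seeds."""
    runs = []
    for seed in SEEDS:
        bundle = prepare_bundle(promoter_only_config(seed))
        prom = train_promoter_fold(bundle, seed=seed, config=PromoterModelConfig(seed=seed))
        dist = train_distal_fold(bundle, seed=seed, config=DistalModelConfig(seed=seed))
        runs.append((bundle, prom.test_r, dist.test_r))
    return runs


@pytest.fixture(scope="session")
def fold_pair_effects(planted_runs):
    """Effects from two fold models of one seed, on the same genes."""
    run = planted_runs[0]
    second = train_distal_fold(
        run.bundle, test_fold=2, seed=SEEDS[0] + 1, config=DistalModelConfig(seed=SEEDS[0] + 1)
    )
    test_mask = run.bundle.folds == 0
    eff2 = distal_effects([second.trained.model], run.bundle, gene_mask=test_mask)
    return run.effects, eff2
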