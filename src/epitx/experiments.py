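"""High-level experiment drivers shared by the analysis scripts and tests.

These wire the generator, signal pipeline, models, perturbation assays and
enrichment statistics into the standard study designs: chromosome-grouped
train/validation/test splits, promoter-vs-distal comparisons on planted
data, causal-bin recovery, and decile enrichment of planted SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from epitx.models import (
    DistalModelConfig,
    PromoterModelConfig,
    TrainingSchedule,
    build_distal_batch,
    build_distal_model,
    build_promoter_matrix,
    build_promoter_model,
    predict_and_score,
    train_model,
)
from epitx.perturb import PerturbationSpec, run_perturbation_assay, summarize_effects
from epitx.signal import classify_expression, make_chromosome_folds
from epitx.stats import assign_deciles, bootstrap_enrichment, filter_distal_effects
from epitx.synthetic import SyntheticConfig, SyntheticDataset, simulate_dataset

PROMOTER_OVERLAP_BINS = (9, 10)  # 2000-bp window bins straddling the TSS


@dataclass
class DataBundle:
    """One simulated dataset prepared for both models."""

    dataset: SyntheticDataset
    X: np.ndarray  # promoter matrix (N, C, 60)
    gene_ids: list[str]
    y: np.ndarray  # log2(RPKM+1) targets aligned to gene_ids
    batch: object  # DistalBatch aligned to gene_ids
    folds: np.ndarray  # fold index per gene
    states: dict[str, str]  # gene -> active/inactive


def prepare_bundle(
    config: SyntheticConfig,
    distal_config: DistalModelConfig | None = None,
    k: int = 4,
    mark: str = "mark",
) -> DataBundle:
    ds = simulate_dataset(config)
    tracks = {mark: ds.track}
    X, gene_ids = build_promoter_matrix(tracks, ds.annotations)
    y = ds.expression.set_index("gene_id").loc[gene_ids, "log2rpkm"].to_numpy()
    batch = build_distal_batch(
        tracks, ds.annotations, ds.interactions, distal_config or DistalModelConfig()
    )
    fold_map = make_chromosome_folds(ds.annotations, k=k, seed=config.seed)
    folds = np.array([fold_map[g] for g in gene_ids])
    states = dict(
        classify_expression(ds.expression).set_index("gene_id")["state"]
    )
    return DataBundle(ds, X, gene_ids, y, batch, folds, states)


def split_masks(folds: np.ndarray, test_fold: int, k: int = 4):
    """Chromosome-grouped split: one fold test, next fold validation."""
    val_fold = (test_fold + 1) % k
    test = folds == test_fold
    val = folds == val_fold
    return ~test & ~val, val, test


@dataclass
class FoldResult:
    trained: object
    test_r: float | None
    test_fold: int


def train_promoter_fold(
    bundle: DataBundle,
    test_fold: int = 0,
    config: PromoterModelConfig | None = None,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    mark: str = "mark",
) -> FoldResult:
    train, val, test = split_masks(bundle.folds, test_fold)
    model = build_promoter_model(config or PromoterModelConfig(seed=seed), (mark,))
    trained = train_model(
        model,
        (bundle.X[train], bundle.y[train]),
        (bundle.X[val], bundle.y[val]),
        schedule,
        seed=seed,
        fold=test_fold,
    )
    r = predict_and_score(model, bundle.X[test], bundle.y[test]).pearson_r
    return FoldResult(trained, r, test_fold)


def train_distal_fold(
    bundle: DataBundle,
    test_fold: int = 0,
    config: DistalModelConfig | None = None,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    mark: str = "mark",
) -> FoldResult:
    train, val, test = split_masks(bundle.folds, test_fold)
    idx = np.arange(len(bundle.gene_ids))
    model = build_distal_model(config or DistalModelConfig(seed=seed), (mark,))
    trained = train_model(
        model,
        (bundle.batch.take(idx[train]), bundle.y[train]),
        (bundle.batch.take(idx[val]), bundle.y[val]),
        schedule,
        seed=seed,
        fold=test_fold,
    )
    r = predict_and_score(
        model, bundle.batch.take(idx[test]), bundle.y[test]
    ).pearson_r
    return FoldResult(trained, r, test_fold)


def distal_effects(
    models: list,
    bundle: DataBundle,
    gene_mask: np.ndarray | None = None,
    levels: tuple = (0.0, 1.0),
    direction: str = "decrease",
    gene_state: str | None = None,
) -> pd.DataFrame:
    """Run the distal bin-ablation assay and summarise level-0 effects."""
    idx = np.flatnonzero(gene_mask) if gene_mask is not None else np.arange(len(bundle.gene_ids))
    sub = bundle.batch.take(idx)
    genes = [bundle.gene_ids[i] for i in idx]
    spec = PerturbationSpec(levels=levels, target="distal_bins", gene_state=gene_state)
    records = run_perturbation_assay(
        models, sub, genes, spec, states=bundle.states if gene_state else None,
        cell=bundle.dataset.config.cell,
    )
    return summarize_effects(records, direction=direction)


def causal_bin_recovery(
    effects: pd.DataFrame, bundle: DataBundle
) -> tuple[float, float, int]:
    """How well ablation effects recover the planted enhancer bins.

    Returns (median rank of the best causal bin among all 20 bins,
    fraction of genes whose top-effect *distal* bin — excluding the two
    promoter-overlap bins, which carry the promoter's own signal — is
    causal, number of genes with enhancers).
    """
    gt = bundle.dataset.ground_truth
    ranks = []
    top = 0
    n = 0
    for gene_id, sub in effects.groupby("gene_id"):
        causal = set(gt.genes[gene_id].causal_bins())
        if not causal:
            continue
        sub = sub.sort_values(
            ["effect_directional", "bin"], ascending=[False, True]
        ).reset_index(drop=True)
        ranks.append(int(min(sub.index[sub["bin"].isin(causal)])) + 1)
        distal_only = sub[~sub["bin"].isin(PROMOTER_OVERLAP_BINS)].reset_index(drop=True)
        top += int(distal_only.loc[0, "bin"] in causal)
        n += 1
    if n == 0:
        raise ValueError("no genes with planted enhancers in the effect table")
    return float(np.median(ranks)), top / n, n


def enrichment_from_effects(
    effects: pd.DataFrame,
    snps: pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
):
    """Promoter-zone filter -> side deciles -> bootstrap SNP enrichment."""
    filtered = filter_distal_effects(effects)
    deciles = assign_deciles(filtered)
    return deciles, bootstrap_enrichment(deciles, snps, n_boot=n_boot, seed=seed)
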