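"""Generator: planted truth, determinism, and the statistical couplings."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from epitx.synthetic import (
    Enhancer,
    GeneTruth,
    GroundTruth,
    SyntheticConfig,
    generate_genome,
    noise_ceiling,
    simulate_dataset,
    synthesize_expression,
    synthesize_interactions_and_snps,
    synthesize_track,
)


def manual_truth(config, genes):
    gt = GroundTruth({g.gene_id: g for g in genes}, config)
    for g in genes:
        linear = config.promoter_effect * g.promoter_strength + sum(
            e.effect for e in g.enhancers
        )
        g.expression_noise_free = max(linear, 0.0)
    return gt


def test_one_gene_per_chromosome_when_counts_force_it():
    annot, gt = generate_genome(SyntheticConfig(seed=1, n_genes=4, n_chromosomes=4))
    assert len(annot) == 4 and len(gt) == 4
    assert annot["chrom"].nunique() == 4


def test_degenerate_enhancer_range_gives_empty_lists():
    _, gt = generate_genome(
        SyntheticConfig(seed=1, n_genes=10, n_chromosomes=2, enhancers_per_gene=(0, 0))
    )
    assert all(g.enhancers == [] for g in gt)


def test_fixed_seed_runs_are_byte_identical(tmp_path):
    cfg = SyntheticConfig(seed=42, n_genes=12, n_chromosomes=3)
    out = []
    for run in range(2):
        ds = simulate_dataset(cfg)
        d = tmp_path / str(run)
        d.mkdir()
        ds.annotations.to_csv(d / "annot.tsv", sep="\t", index=False)
        ds.track.to_bedgraph(d / "track.bedGraph")
        ds.expression.to_csv(d / "expr.tsv", sep="\t", index=False)
        ds.interactions.to_csv(d / "ints.tsv", sep="\t", index=False)
        ds.snps.to_csv(d / "snps.tsv", sep="\t", index=False)
        ds.ground_truth.to_json(d / "gt.json")
        out.append(d)
    for name in ["annot.tsv", "track.bedGraph", "expr.tsv", "ints.tsv", "snps.tsv", "gt.json"]:
        assert (out[0] / name).read_bytes() == (out[1] / name).read_bytes()


def test_zero_background_zero_strength_track_is_all_zero():
    cfg = SyntheticConfig(seed=0, n_genes=1, n_chromosomes=1, background_rate=0.0)
    gt = manual_truth(cfg, [GeneTruth("G0", "chr1", 50000, "+", 0.0)])
    track = synthesize_track(gt, cfg)
    assert np.all(track.window("chr1", 30000, 70000) == 0)


def test_single_enhancer_peak_argmax_near_planted_position():
    cfg = SyntheticConfig(seed=0, n_genes=1, n_chromosomes=1, background_rate=0.0)
    g = GeneTruth("G0", "chr1", 50000, "+", 0.0, enhancers=[Enhancer(10000, 2.0, 15)])
    gt = manual_truth(cfg, [g])
    track = synthesize_track(gt, cfg)
    win = track.window("chr1", 30000, 70000)
    argmax = 30000 + int(np.argmax(win))
    assert abs(argmax - 60000) <= cfg.peak_width_sd


def test_promoter_amplitude_tracks_expression_for_noiseless_active_mark():
    cfg = SyntheticConfig(
        seed=3, n_genes=150, n_chromosomes=4, enhancers_per_gene=(0, 0),
        noise_sd=0.0, background_rate=0.0,
    )
    annot, gt = generate_genome(cfg)
    track = synthesize_track(gt, cfg)
    expr = synthesize_expression(gt, cfg)
    amps = []
    for g in gt:
        win = track.window(g.chrom, g.tss - 3000, g.tss + 3000)
        amps.append(win.max())
    rho = spearmanr(amps, expr.set_index("gene_id").loc[[g.gene_id for g in gt], "log2rpkm"]).statistic
    assert rho > 0.995  # monotone up to integer-rounding ties


def test_repressive_mark_amplitude_decreases_with_expression():
    cfg = SyntheticConfig(
        seed=3, n_genes=150, n_chromosomes=4, enhancers_per_gene=(0, 0),
        noise_sd=0.0, background_rate=0.0, mark_polarity="repressive",
    )
    _, gt = generate_genome(cfg)
    track = synthesize_track(gt, cfg)
    amps = [track.window(g.chrom, g.tss - 3000, g.tss + 3000).max() for g in gt]
    expr = [g.expression_noise_free for g in gt]
    assert spearmanr(amps, expr).statistic < -0.95


def test_zero_noise_expression_is_exact_linear_combination():
    cfg = SyntheticConfig(seed=5, n_genes=50, n_chromosomes=2, noise_sd=0.0)
    _, gt = generate_genome(cfg)
    expr = synthesize_expression(gt, cfg).set_index("gene_id")["log2rpkm"]
    for g in gt:
        expected = max(
            cfg.promoter_effect * g.promoter_strength + sum(e.effect for e in g.enhancers),
            0.0,
        )
        assert expr[g.gene_id] == pytest.approx(expected, abs=0)


def test_all_zero_effects_give_zero_expression():
    cfg = SyntheticConfig(seed=0, n_genes=2, n_chromosomes=1, noise_sd=0.0)
    gt = manual_truth(
        cfg, [GeneTruth(f"G{i}", "chr1", 50000 + 44000 * i, "+", 0.0) for i in range(2)]
    )
    expr = synthesize_expression(gt, cfg)
    assert (expr["log2rpkm"] == 0).all()


def test_noisy_expression_correlation_matches_analytic_ceiling():
    cfg = SyntheticConfig(seed=9, n_genes=2000, n_chromosomes=8, noise_sd=0.6)
    _, gt = generate_genome(cfg)
    expr = synthesize_expression(gt, cfg).set_index("gene_id")["log2rpkm"]
    clean = np.array([g.expression_noise_free for g in gt])
    noisy = expr[[g.gene_id for g in gt]].to_numpy()
    r = np.corrcoef(clean, noisy)[0, 1]
    assert abs(r - noise_ceiling(gt, cfg)) < 0.05


def test_interaction_count_forced_by_single_enhancer_no_decoys():
    cfg = SyntheticConfig(
        seed=2, n_genes=30, n_chromosomes=3, enhancers_per_gene=(1, 1),
        decoy_interaction_rate=0.0,
    )
    _, gt = generate_genome(cfg)
    ints, _ = synthesize_interactions_and_snps(gt, cfg)
    assert len(ints) == 30


def test_causal_fraction_one_places_every_snp_in_a_causal_bin():
    cfg = SyntheticConfig(
        seed=2, n_genes=30, n_chromosomes=3, enhancers_per_gene=(1, 3),
        causal_snp_fraction=1.0,
    )
    _, gt = generate_genome(cfg)
    _, snps = synthesize_interactions_and_snps(gt, cfg)
    bins = []
    for g in gt:
        start = g.tss - cfg.distal_half_width
        bins += [
            (g.chrom, start + b * 2000, start + (b + 1) * 2000) for b in g.causal_bins()
        ]
    for _, s in snps.iterrows():
        assert any(c == s["chrom"] and lo <= s["pos"] < hi for c, lo, hi in bins)
        assert s["pip_focal"] > 0.9 and s["pip_other_max"] < 0.1


def test_causal_fraction_zero_means_no_high_pip_snp():
    cfg = SyntheticConfig(seed=2, n_genes=30, n_chromosomes=3, causal_snp_fraction=0.0)
    _, gt = generate_genome(cfg)
    _, snps = synthesize_interactions_and_snps(gt, cfg)
    assert (snps["pip_focal"] < 0.1).all()


def test_gene_without_enhancers_skips_causal_snps():
    cfg = SyntheticConfig(
        seed=2, n_genes=10, n_chromosomes=2, enhancers_per_gene=(0, 0),
        causal_snp_fraction=0.5, snps_per_gene=4,
    )
    _, gt = generate_genome(cfg)
    _, snps = synthesize_interactions_and_snps(gt, cfg)
    assert len(snps) == 10 * 4
    assert (snps["pip_focal"] < 0.1).all()


@pytest.mark.parametrize(
    "field,value",
    [
        ("background_rate", -1.0),
        ("causal_snp_fraction", 1.5),
        ("mark_polarity", "both"),
        ("n_genes", 0),
        ("promoter_half_width", -5),
    ],
)
def test_config_validation_rejects_bad_values(field, value):
    cfg = SyntheticConfig(**{field: value})
    with pytest.raises(ValueError, match=field.split("_")[0]):
        cfg.validate()


def test_infeasible_placement_names_the_chromosome():
    cfg = SyntheticConfig(seed=0, n_genes=10, n_chromosomes=1, chromosome_length=100000)
    with pytest.raises(ValueError, match="chr1"):
        generate_genome(cfg)


def test_ground_truth_json_is_complete(tmp_path):
    cfg = SyntheticConfig(seed=4, n_genes=6, n_chromosomes=2)
    _, gt = generate_genome(cfg)
    synthesize_interactions_and_snps(gt, cfg)
    path = tmp_path / "gt.json"
    gt.to_json(path)
    payload = json.loads(path.read_text())
    assert len(payload["genes"]) == 6
    g0 = next(iter(payload["genes"].values()))
    assert {"tss", "strand", "promoter_strength", "enhancers", "causal_snps"} <= set(g0)


def test_enhancer_offsets_within_distal_window():
    cfg = SyntheticConfig(seed=6, n_genes=60, n_chromosomes=4, enhancers_per_gene=(1, 3))
    _, gt = generate_genome(cfg)
    for g in gt:
        for e in g.enhancers:
            assert abs(e.offset) < cfg.distal_half_width
            assert 0 <= e.bin_index < 20
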