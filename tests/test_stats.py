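"""Aggregation, deciles, bootstrap enrichment and benchmark loci."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from epitx.stats import (
    agreement_matrix,
    aggregate_performance,
    assign_deciles,
    benchmark_loci,
    bootstrap_enrichment,
    compare_groups,
    filter_distal_effects,
    filter_tissue_specific_snps,
    write_decile_bed,
)
from epitx.tracks import DepthTrack


def test_mean_sd_matches_hand_computation():
    rec = pd.DataFrame(
        dict(marks=["A", "A", "A"], cell=["c1", "c1", "c2"], fold=[0, 1, 0],
             pearson_r=[0.5, 0.7, 0.6])
    )
    out = aggregate_performance(rec)
    assert out.loc[0, "mean_r"] == pytest.approx(0.6)
    assert out.loc[0, "sd_r"] == pytest.approx(0.1)


def test_identical_predictions_give_agreement_one():
    rng = np.random.default_rng(0)
    v = rng.normal(size=50)
    preds = {("A", "c1", 0): v, ("B", "c1", 0): v.copy()}
    mat = agreement_matrix(preds)
    assert mat.loc["A", "B"] == pytest.approx(1.0)


def test_agreement_matched_on_cell_and_fold_only():
    rng = np.random.default_rng(1)
    a0, b0 = rng.normal(size=30), rng.normal(size=30)
    preds = {("A", "c1", 0): a0, ("B", "c1", 0): b0, ("A", "c2", 1): rng.normal(size=30)}
    mat = agreement_matrix(preds)
    assert mat.loc["A", "B"] == pytest.approx(np.corrcoef(a0, b0)[0, 1])


def test_wilcoxon_null_calibration():
    """Same-distribution groups are rejected at roughly the nominal 5% rate."""
    rng = np.random.default_rng(2)
    rejections = 0
    reps = 100
    for _ in range(reps):
        rec = pd.DataFrame(
            dict(
                marks="A",
                cell_state=["ESC"] * 10 + ["primary tissue"] * 10,
                pearson_r=rng.normal(0.7, 0.05, size=20),
            )
        )
        out = compare_groups(rec, {"A": "active"})
        rejections += out.loc[0, "p_value"] < 0.05
    assert 0 <= rejections / reps <= 0.12  # ~Binomial(100, 0.05)


def test_small_groups_are_skipped_with_warning(caplog):
    rec = pd.DataFrame(
        dict(marks="A", cell_state=["ESC", "primary tissue"], pearson_r=[0.5, 0.6])
    )
    with caplog.at_level("WARNING"):
        out = compare_groups(rec, {"A": "active"})
    assert out.empty
    assert "skipped" in caplog.text


# ---------------------------------------------------------------------------
# promoter-zone filter and deciles


def effects_frame(distances, effects=None, chrom="chr1"):
    n = len(distances)
    effects = effects if effects is not None else np.ones(n)
    return pd.DataFrame(
        dict(
            gene_id=[f"g{i}" for i in range(n)],
            cell="c",
            chrom=chrom,
            bin=np.arange(n) % 20,
            bin_start=np.arange(n) * 2000,
            bin_end=np.arange(n) * 2000 + 2000,
            signed_distance=distances,
            effect=-np.asarray(effects),
            effect_directional=np.asarray(effects, dtype=float),
        )
    )


def test_promoter_zone_filter_boundaries():
    eff = effects_frame([-5000, -7000, 4500, 3000, -6000, 4000])
    out = filter_distal_effects(eff)
    kept = out.set_index("signed_distance")["side"].to_dict()
    assert kept == {-7000: "upstream", 4500: "downstream"}


def test_ten_distinct_values_one_per_decile():
    eff = effects_frame([-7000 - i for i in range(10)], effects=np.arange(10.0))
    dec = assign_deciles(filter_distal_effects(eff))
    assert sorted(dec["decile"]) == list(range(1, 11))
    assert dec.loc[dec["effect_directional"].idxmax(), "decile"] == 10


def test_decile_boundaries_match_sort_and_slice_oracle():
    rng = np.random.default_rng(3)
    vals = rng.random(100)
    eff = effects_frame([-7000] * 100, effects=vals)
    dec = assign_deciles(filter_distal_effects(eff))
    order = np.argsort(vals, kind="stable")
    oracle = np.empty(100, dtype=int)
    for i, chunk in enumerate(np.array_split(order, 10)):
        oracle[chunk] = i + 1
    got = dec.set_index("gene_id")["decile"]
    assert all(got[f"g{i}"] == oracle[i] for i in range(100))


def test_tied_effects_get_stable_deterministic_assignment():
    eff = effects_frame([-7000] * 30, effects=np.zeros(30))
    a = assign_deciles(filter_distal_effects(eff))
    b = assign_deciles(filter_distal_effects(eff.sample(frac=1, random_state=5)))
    ga = a.set_index("gene_id")["decile"]
    gb = b.set_index("gene_id")["decile"]
    assert ga.sort_index().equals(gb.sort_index())  # permutation-invariant


def test_fewer_than_ten_regions_on_a_side_is_an_error():
    eff = effects_frame([-7000] * 5)
    with pytest.raises(ValueError, match="upstream"):
        assign_deciles(filter_distal_effects(eff))


# ---------------------------------------------------------------------------
# bootstrap enrichment


def decile_universe(n_per_decile=20, chrom="chr1"):
    rows = []
    for d in range(1, 11):
        for j in range(n_per_decile):
            i = (d - 1) * n_per_decile + j
            rows.append(
                dict(gene_id=f"g{i}", cell="c", chrom=chrom, bin=0,
                     bin_start=i * 2000, bin_end=(i + 1) * 2000,
                     signed_distance=-7000, side="upstream",
                     effect=-float(d), effect_directional=float(d), decile=d)
            )
    return pd.DataFrame(rows)


def snps_at(positions, chrom="chr1", pip=0.99):
    return pd.DataFrame(
        dict(chrom=chrom, pos=positions, snp_id=[f"s{i}" for i in range(len(positions))],
             pip_focal=pip, pip_other_max=0.01)
    )


def test_pip_filter_keeps_only_tissue_specific_high_confidence():
    snps = pd.DataFrame(
        dict(chrom="chr1", pos=[1, 2, 3], snp_id=list("abc"),
             pip_focal=[0.95, 0.95, 0.5], pip_other_max=[0.05, 0.5, 0.05])
    )
    assert filter_tissue_specific_snps(snps)["snp_id"].tolist() == ["a"]


def test_all_snps_in_top_decile_gives_minimal_p():
    dec = decile_universe()
    top = dec[dec.decile == 10]
    rep = bootstrap_enrichment(dec, snps_at(top["bin_start"] + 100), n_boot=1000, seed=0)
    row = rep.table[rep.table.decile == 10].iloc[0]
    assert row["p_value"] == pytest.approx(1 / 1001)
    assert row["observed_prop"] == 1.0


def test_empty_snp_table_gives_p_one_everywhere():
    rep = bootstrap_enrichment(decile_universe(), snps_at([]), n_boot=500, seed=0)
    assert (rep.table["p_value"] == 1.0).all()


def test_bootstrap_p_converges_to_exhaustive_enumeration():
    """20-region toy: the resampling p matches the exact without-replacement law."""
    dec = decile_universe(n_per_decile=2)  # 20 regions, deciles of 2
    hits = [38000, 36000, 30000]  # 3 regions contain a SNP (two in decile 10)
    rep = bootstrap_enrichment(dec, snps_at([h + 50 for h in hits]), n_boot=200000, seed=1)
    row = rep.table[rep.table.decile == 10].iloc[0]
    # exact enumeration: 2 draws from 20 regions of which 3 hit; P(X >= 2)
    exact = hypergeom(20, 3, 2).sf(1)
    se = np.sqrt(exact * (1 - exact) / 200000)
    assert abs(row["p_value"] - exact) < 4 * se + 2 / 200000


def test_null_p_values_are_super_uniform():
    """Under random SNP placement, P(p <= t) never exceeds t (plus noise)."""
    dec = decile_universe(n_per_decile=60)
    rng = np.random.default_rng(7)
    starts = dec["bin_start"].to_numpy()
    ps = []
    for rep in range(500):
        hit = starts[rng.random(len(starts)) < 0.3]
        report = bootstrap_enrichment(dec, snps_at(hit + 10), n_boot=500, seed=rep)
        ps.append(report.table.loc[report.table.decile == 10, "p_value"].iloc[0])
    ps = np.array(ps)
    for t in (0.01, 0.05, 0.1, 0.25, 0.5):
        se = np.sqrt(t * (1 - t) / len(ps))
        assert (ps <= t).mean() <= t + 3 * se


def test_bh_adjustment_matches_reference_oracle():
    rng = np.random.default_rng(8)
    from statsmodels.stats.multitest import multipletests

    p = rng.random(10)
    # hand-rolled BH: monotone-adjusted p*n/rank
    order = np.argsort(p)
    adj = np.empty(10)
    running = 1.0
    for rank in range(9, -1, -1):
        running = min(running, p[order[rank]] * 10 / (rank + 1))
        adj[order[rank]] = running
    assert np.allclose(multipletests(p, method="fdr_bh")[1], adj)


def test_low_n_boot_warns(caplog):
    with caplog.at_level("WARNING"):
        bootstrap_enrichment(decile_universe(2), snps_at([]), n_boot=50, seed=0)
    assert "n_boot" in caplog.text


# ---------------------------------------------------------------------------
# benchmark loci


def test_max_activity_finds_the_planted_peak():
    gene = dict(chrom="chr1", start=50000, end=50001, strand="+", gene_id="g")
    t = DepthTrack()
    depth = np.zeros(60000, dtype=int)
    depth[40500:41500] = 40  # genomic 60 500–61 500: peak at ~+10 000 from the TSS
    t.add_block("chr1", 20000, depth)
    loci = benchmark_loci("max_activity", gene, track=t)
    assert loci == [("chr1", 60000, 62000)]


def test_proximal_flank_is_three_2000bp_bins():
    gene = dict(chrom="chr1", start=50000, end=50001, strand="+", gene_id="g")
    up = benchmark_loci("proximal", gene, side="upstream")
    assert up == [("chr1", 44000, 46000), ("chr1", 46000, 48000), ("chr1", 48000, 50000)]
    down = benchmark_loci("proximal", gene, side="downstream")
    assert len(down) == 3 and down[0] == ("chr1", 50000, 52000)


def test_hic_mode_keeps_only_upstream_fragments():
    gene = dict(chrom="chr1", start=50000, end=50001, strand="+", gene_id="g")
    ints = pd.DataFrame(
        dict(chrom=["chr1", "chr1"], frag1_start=50000, frag1_end=52000,
             frag2_start=[40000, 60000], frag2_end=[42000, 62000],
             score=[5.0, 5.0], gene_id="g")
    )
    assert benchmark_loci("hic", gene, interactions=ints) == [("chr1", 40000, 42000)]
    minus = dict(gene, strand="-")
    assert benchmark_loci("hic", minus, interactions=ints) == [("chr1", 60000, 62000)]


def test_decile_bed_writer_round_trips(tmp_path):
    dec = decile_universe(2)
    path = tmp_path / "dec.bed"
    write_decile_bed(dec, path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 20
    assert lines[0].split("\t")[3].startswith("upstream_d")
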