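"""Perturbation math, assays, ensembling and attribution."""

import numpy as np
import pandas as pd
import pytest

from epitx.models.distal import DistalBatch, DistalGeneMeta
from epitx.perturb import (
    PerturbationSpec,
    attribution_to_bins,
    ensemble_predict,
    gradient_attribution,
    perturb_distal_bin,
    perturb_promoter_matrix,
    perturb_values,
    run_perturbation_assay,
    summarize_effects,
)


class LinearPromoterSurrogate:
    """f(x) = sum(w * x): analytic predictions and gradients."""

    mark_names = ("m",)

    def __init__(self, w):
        self.w = w

    def predict(self, x):
        return (x * self.w).sum(axis=(1, 2))

    def input_gradient(self, x):
        return np.broadcast_to(self.w, x.shape).copy()


class ConstantModel:
    mark_names = ("m",)

    def __init__(self, c):
        self.c = c

    def predict(self, x):
        return np.full(len(x), self.c, dtype=float)

    def input_gradient(self, x):
        return np.zeros_like(x, dtype=float)


class LinearDistalSurrogate:
    """f(batch) = sum(w * 100-bp window signal)."""

    mark_names = ("m",)

    def __init__(self, w):
        self.w = w  # (C, 400)

    def predict(self, batch):
        return (batch.prom[100] * self.w).sum(axis=(1, 2))


def plus_strand_batch(rng, n=3):
    prom = {r: rng.random((n, 1, 40000 // r)) * 3 for r in (100, 500, 2000)}
    frag = {r: np.zeros((n, 2, 1, 2000 // r)) for r in (100, 500, 2000)}
    meta = [DistalGeneMeta(f"g{i}", "chr1", 50000, "+", 30000, []) for i in range(n)]
    return DistalBatch(
        prom=prom, frag=frag, weights=np.zeros((n, 2)), mask=np.zeros((n, 2), bool), meta=meta
    )


def test_level_one_is_bit_exact_identity():
    rng = np.random.default_rng(0)
    v = rng.random((4, 1, 60)) * 5
    assert np.array_equal(perturb_promoter_matrix(v, 1.0), v)


def test_closed_form_values():
    assert perturb_values(np.array([2.0]), 0.0)[0] == 0.0
    assert perturb_values(np.array([2.0]), 0.5)[0] == pytest.approx(np.log2(2.5), abs=1e-12)
    assert perturb_values(np.array([2.0]), 0.5, log_space=True)[0] == 1.0


def test_level_outside_unit_interval_rejected():
    with pytest.raises(ValueError, match="level"):
        perturb_values(np.ones(3), 1.2)
    with pytest.raises(ValueError, match="1.0"):
        PerturbationSpec(levels=(0.0, 0.5)).validate()
    with pytest.raises(ValueError, match="receptive field"):
        perturb_distal_bin(plus_strand_batch(np.random.default_rng(0)), 25, 0.0)


def test_default_levels_are_eleven_tenth_steps():
    spec = PerturbationSpec()
    assert list(spec.levels) == [round(0.1 * i, 1) for i in range(11)]


def test_assay_with_only_level_one_gives_zero_deltas():
    rng = np.random.default_rng(1)
    batch = plus_strand_batch(rng)
    model = LinearDistalSurrogate(rng.random((1, 400)))
    rec = run_perturbation_assay(
        [model], batch, [m.gene_id for m in batch.meta],
        PerturbationSpec(levels=(1.0,), gene_state=None),
    )
    assert (rec["delta"] == 0).all()
    assert rec["bin"].nunique() == 20  # 40 000 bp / 2000 bp bins


def test_linear_surrogate_deltas_match_closed_form():
    rng = np.random.default_rng(2)
    batch = plus_strand_batch(rng)
    w = rng.random((1, 400))
    model = LinearDistalSurrogate(w)
    rec = run_perturbation_assay(
        [model], batch, [m.gene_id for m in batch.meta],
        PerturbationSpec(levels=(0.0, 0.3, 1.0), gene_state=None),
    )
    for row in rec.itertuples():
        if row.level == 1.0:
            assert row.delta == 0.0
            continue
        g = int(row.gene_id[1:])
        sl = slice(row.bin * 20, (row.bin + 1) * 20)
        x = batch.prom[100][g, 0, sl]
        xp = np.log2(row.level * (2.0**x - 1.0) + 1.0)
        assert row.delta == pytest.approx(float((w[0, sl] * (xp - x)).sum()), abs=1e-9)


def test_promoter_window_assay_perturbs_everything():
    rng = np.random.default_rng(3)
    x = rng.random((4, 1, 60)) * 4
    w = rng.random((1, 60))
    model = LinearPromoterSurrogate(w)
    rec = run_perturbation_assay(
        [model], x, [f"g{i}" for i in range(4)],
        PerturbationSpec(levels=(0.0, 1.0), target="promoter_window", gene_state=None),
    )
    zero = rec[rec.level == 0.0]
    for i, row in enumerate(zero.itertuples()):
        assert row.delta == pytest.approx(-float((w * x[i]).sum()), abs=1e-9)
    assert (rec["bin"] == "promoter").all()


def test_gene_state_filter_applies_and_empty_is_an_error():
    rng = np.random.default_rng(4)
    x = rng.random((4, 1, 60))
    model = LinearPromoterSurrogate(np.ones((1, 60)))
    states = {"g0": "active", "g1": "inactive", "g2": "active", "g3": "inactive"}
    spec = PerturbationSpec(levels=(0.0, 1.0), target="promoter_window", gene_state="active")
    rec = run_perturbation_assay([model], x, list(states), spec, states=states)
    assert set(rec["gene_id"]) == {"g0", "g2"}
    with pytest.raises(ValueError, match="state"):
        run_perturbation_assay(
            [model], x, list(states),
            PerturbationSpec(levels=(0.0, 1.0), target="promoter_window", gene_state="weird"),
            states=states,
        )


def test_fragment_overlapping_perturbed_bin_is_perturbed_too():
    rng = np.random.default_rng(5)
    batch = plus_strand_batch(rng)
    batch.frag = {r: rng.random((3, 2, 1, 2000 // r)) for r in (100, 500, 2000)}
    batch.mask[:] = True
    batch.meta[0].fragment_intervals = [(30000, 32000), (60000, 62000)]
    out = perturb_distal_bin(batch, 0, 0.0)  # genomic bin 0 = [30000, 32000)
    assert np.all(out.frag[100][0, 0] == 0)
    assert np.array_equal(out.frag[100][0, 1], batch.frag[100][0, 1])


def test_ensemble_mean_and_mark_homogeneity():
    x = np.zeros((3, 1, 60))
    assert np.allclose(ensemble_predict([ConstantModel(1.0), ConstantModel(3.0)], x), 2.0)
    m = LinearPromoterSurrogate(np.ones((1, 60)))
    assert np.array_equal(ensemble_predict([m, m], x), m.predict(x))
    rng = np.random.default_rng(6)
    models = [LinearPromoterSurrogate(rng.random((1, 60))) for _ in range(4)]
    xr = rng.random((5, 1, 60))
    oracle = sum(mm.predict(xr) for mm in models) / 4  # loop-and-average
    assert np.allclose(ensemble_predict(models, xr), oracle, atol=1e-12)
    bad = ConstantModel(0.0)
    bad.mark_names = ("other",)
    with pytest.raises(ValueError, match="heterogeneous"):
        ensemble_predict([m, bad], x)


def test_attribution_of_linear_surrogate_is_its_weights():
    rng = np.random.default_rng(7)
    w = rng.random((1, 60))
    x = rng.random((2, 1, 60))
    g = gradient_attribution([LinearPromoterSurrogate(w)], x)
    assert np.array_equal(g, np.broadcast_to(w, x.shape))
    g2 = gradient_attribution([ConstantModel(5.0)], x)
    assert np.all(g2 == 0)
    assert np.array_equal(
        gradient_attribution([LinearPromoterSurrogate(w)], x),
        gradient_attribution([LinearPromoterSurrogate(w)], x),
    )


def test_attribution_requires_gradient_support():
    class NoGrad:
        mark_names = ("m",)

        def predict(self, x):
            return np.zeros(len(x))

    with pytest.raises(TypeError, match="gradient"):
        gradient_attribution([NoGrad()], np.zeros((2, 1, 60)))


def test_attribution_bin_aggregation_sums_within_2000bp():
    g = np.arange(2 * 1 * 400, dtype=float).reshape(2, 1, 400)
    bins = attribution_to_bins(g)
    assert bins.shape == (2, 20)
    assert bins[0, 0] == g[0, 0, :20].sum()


def test_summarize_effects_matches_manual_pivot():
    records = pd.DataFrame(
        [
            dict(gene_id="g1", cell="c", chrom="chr1", bin=0, bin_start=0, bin_end=2000,
                 signed_distance=-19000, level=0.0, baseline=2.0, perturbed=1.2, delta=-0.8),
            dict(gene_id="g1", cell="c", chrom="chr1", bin=1, bin_start=2000, bin_end=4000,
                 signed_distance=-17000, level=0.0, baseline=2.0, perturbed=2.5, delta=0.5),
            dict(gene_id="g1", cell="c", chrom="chr1", bin=0, bin_start=0, bin_end=2000,
                 signed_distance=-19000, level=1.0, baseline=2.0, perturbed=2.0, delta=0.0),
        ]
    )
    eff = summarize_effects(records, direction="decrease")
    assert len(eff) == 2
    assert eff.set_index("bin")["effect"].to_dict() == {0: -0.8, 1: 0.5}
    assert eff.set_index("bin")["effect_directional"].to_dict() == {0: 0.8, 1: 0.0}
    inc = summarize_effects(records, direction="increase")
    assert inc.set_index("bin")["effect_directional"].to_dict() == {0: 0.0, 1: 0.5}
    with pytest.raises(ValueError, match="level 0"):
        summarize_effects(records[records.level == 1.0])


def test_fold_models_agree_on_effect_profiles(fold_pair_effects):
    """Distal models trained on different folds rank bins consistently."""
    eff_a, eff_b = fold_pair_effects
    merged = eff_a.merge(eff_b, on=["gene_id", "bin"], suffixes=("_a", "_b"))
    r = np.corrcoef(merged["effect_a"], merged["effect_b"])[0, 1]
    assert r > 0.9
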