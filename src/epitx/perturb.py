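"""In-silico histone-mark perturbation assays and gradient attribution.

A perturbation at level λ ∈ [0, 1] scales the signal in *linear depth*
space: each binned log value v becomes log2(λ·(2^v − 1) + 1), so λ = 1 is
the exact identity, λ = 0 empties the region, and intermediate levels read
as a fractional activity knob.  (Scaling the log-space value directly is
available behind ``log_space=True`` for sensitivity analysis.)

Assays run over a fold-model ensemble (arithmetic mean of predictions):
either the whole ±3000-bp promoter window, or each of the twenty
non-overlapping 2000-bp bins tiled across the 40 000-bp distal receptive
field.  Effects are summarised as the level-0 delta; attribution maps are
ensemble-averaged input gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epitx.models.distal import (
    FRAGMENT_WIDTH,
    N_PROM_TOKENS,
    RESOLUTIONS,
    DistalBatch,
)


@dataclass
class PerturbationSpec:
    levels: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
    target: str = "distal_bins"  # or "promoter_window"
    bin_size: int = 2000
    gene_state: str | None = "active"  # filter applied when states are given
    log_space: bool = False

    def validate(self) -> None:
        if self.target not in ("distal_bins", "promoter_window"):
            raise ValueError(f"unknown target {self.target!r}")
        if any(not 0.0 <= l <= 1.0 for l in self.levels):
            raise ValueError("levels must lie in [0, 1]")
        if 1.0 not in self.levels:
            raise ValueError("level 1.0 (identity baseline) must be included")


def ensemble_predict(models: list, inputs) -> np.ndarray:
    """Arithmetic mean of per-model predictions (the k-fold ensemble)."""
    if not models:
        raise ValueError("need at least one model")
    mark_sets = {tuple(getattr(m, "mark_names", ())) for m in models}
    if len(mark_sets) > 1:
        raise ValueError(f"heterogeneous mark sets across ensemble: {mark_sets}")
    preds = [m.predict(inputs) for m in models]
    return np.mean(preds, axis=0)


def perturb_values(values: np.ndarray, level: float, log_space: bool = False) -> np.ndarray:
    """Scale binned log2 signal to a fractional activity level."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level {level} outside [0, 1]")
    values = np.asarray(values, dtype=float)
    if level == 1.0:
        return values.copy()
    if log_space:
        return values * level
    return np.log2(level * (2.0**values - 1.0) + 1.0)


def perturb_promoter_matrix(x: np.ndarray, level: float, log_space: bool = False) -> np.ndarray:
    """Perturb the full promoter window (all bins, all marks)."""
    return perturb_values(x, level, log_space)


def perturb_distal_bin(
    batch: DistalBatch, genomic_bin: int, level: float, log_space: bool = False
) -> DistalBatch:
    """Perturb one 2000-bp bin of the distal window for every gene.

    ``genomic_bin`` indexes the twenty bins tiled from the upstream genomic
    edge of each gene's window.  The bin's span is perturbed in all three
    window resolutions and in any interacting-fragment slot overlapping the
    same genomic interval (fragments are perturbed whole; in the data this
    package generates, fragments are aligned to the window grid so the
    overlap is exact).
    """
    if not 0 <= genomic_bin < N_PROM_TOKENS:
        raise ValueError(
            f"bin {genomic_bin} outside the distal receptive field (0..{N_PROM_TOKENS - 1})"
        )
    out = batch.copy()
    for gi, meta in enumerate(batch.meta):
        t = meta.oriented_token(genomic_bin)
        for r in RESOLUTIONS:
            seg = FRAGMENT_WIDTH // r
            sl = slice(t * seg, (t + 1) * seg)
            out.prom[r][gi, :, sl] = perturb_values(out.prom[r][gi, :, sl], level, log_space)
        bin_start = meta.window_start + genomic_bin * FRAGMENT_WIDTH
        bin_end = bin_start + FRAGMENT_WIDTH
        for slot, (fs, fe) in enumerate(meta.fragment_intervals):
            if fs < bin_end and fe > bin_start:
                for r in RESOLUTIONS:
                    out.frag[r][gi, slot] = perturb_values(
                        out.frag[r][gi, slot], level, log_space
                    )
    return out


def _signed_distance(meta, genomic_bin: int) -> int:
    """Transcription-oriented distance of the bin midpoint from the TSS."""
    mid = meta.window_start + genomic_bin * FRAGMENT_WIDTH + FRAGMENT_WIDTH // 2
    sign = 1 if meta.strand == "+" else -1
    return sign * (mid - meta.tss)


def run_perturbation_assay(
    models: list,
    inputs,
    gene_ids: list[str],
    spec: PerturbationSpec,
    states: dict[str, str] | None = None,
    cell: str = "C1",
) -> pd.DataFrame:
    """One record per gene × (bin ×) level with baseline/perturbed/delta.

    ``inputs`` is a promoter matrix (N, C, 60) for ``promoter_window`` or a
    :class:`DistalBatch` for ``distal_bins``.  When ``states`` is given,
    genes are first filtered to ``spec.gene_state`` (active genes for an
    active mark, inactive for a repressive one).
    """
    spec.validate()
    keep = np.arange(len(gene_ids))
    if states is not None and spec.gene_state is not None:
        keep = np.array(
            [i for i, g in enumerate(gene_ids) if states.get(g) == spec.gene_state],
            dtype=int,
        )
    if len(keep) == 0:
        raise ValueError(f"no genes left after state filter {spec.gene_state!r}")
    gene_ids = [gene_ids[i] for i in keep]

    records = []
    if spec.target == "promoter_window":
        x = inputs[keep]
        baseline = ensemble_predict(models, x)
        for level in spec.levels:
            pred = (
                baseline
                if level == 1.0
                else ensemble_predict(models, perturb_promoter_matrix(x, level, spec.log_space))
            )
            for g, b, p in zip(gene_ids, baseline, pred):
                records.append(
                    dict(
                        gene_id=g,
                        cell=cell,
                        chrom="",
                        bin="promoter",
                        bin_start=-1,
                        bin_end=-1,
                        signed_distance=0,
                        level=level,
                        baseline=b,
                        perturbed=p,
                        delta=p - b,
                    )
                )
    else:
        batch = inputs.take(keep)
        baseline = ensemble_predict(models, batch)
        for genomic_bin in range(N_PROM_TOKENS):
            for level in spec.levels:
                pred = (
                    baseline
                    if level == 1.0
                    else ensemble_predict(
                        models,
                        perturb_distal_bin(batch, genomic_bin, level, spec.log_space),
                    )
                )
                for gi, (g, b, p) in enumerate(zip(gene_ids, baseline, pred)):
                    meta = batch.meta[gi]
                    records.append(
                        dict(
                            gene_id=g,
                            cell=cell,
                            chrom=meta.chrom,
                            bin=genomic_bin,
                            bin_start=meta.window_start + genomic_bin * FRAGMENT_WIDTH,
                            bin_end=meta.window_start + (genomic_bin + 1) * FRAGMENT_WIDTH,
                            signed_distance=_signed_distance(meta, genomic_bin),
                            level=level,
                            baseline=b,
                            perturbed=p,
                            delta=p - b,
                        )
                    )
    return pd.DataFrame(records)


def gradient_attribution(models: list, inputs):
    """Ensemble-averaged gradient of the prediction w.r.t. the input signal."""
    if not models:
        raise ValueError("need at least one model")
    grads = []
    for m in models:
        if not hasattr(m, "input_gradient"):
            raise TypeError(f"model {type(m).__name__} does not support input gradients")
        grads.append(m.input_gradient(inputs))
    if isinstance(grads[0], np.ndarray):
        return np.mean(grads, axis=0)
    # distal: (dprom, dfrag) dict pairs
    dprom = {
        r: np.mean([g[0][r] for g in grads], axis=0) for r in grads[0][0]
    }
    dfrag = {
        r: np.mean([g[1][r] for g in grads], axis=0) for r in grads[0][1]
    }
    return dprom, dfrag


def attribution_to_bins(grad, bin_size: int = 2000, resolution: int = 100) -> np.ndarray:
    """Sum a (N, C, L) gradient into 2000-bp display bins -> (N, L//per)."""
    per = bin_size // resolution
    N, C, L = grad.shape
    return grad.reshape(N, C, L // per, per).sum(axis=(1, 3))


def summarize_effects(records: pd.DataFrame, direction: str = "decrease") -> pd.DataFrame:
    """Per-gene, per-bin effect table from level-0 perturbation records.

    effect = prediction at level 0 − baseline (signed); the directional
    magnitude keeps only the expected-direction change (a decrease for an
    active mark, an increase for a repressive one).
    """
    zero = records[records["level"] == 0.0]
    if zero.empty:
        raise ValueError("records must include level 0.0")
    out = zero[
        ["gene_id", "cell", "chrom", "bin", "bin_start", "bin_end", "signed_distance", "delta"]
    ].copy()
    out = out.rename(columns={"delta": "effect"})
    if direction == "decrease":
        out["effect_directional"] = np.maximum(-out["effect"], 0.0)
    elif direction == "increase":
        out["effect_directional"] = np.maximum(out["effect"], 0.0)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out.reset_index(drop=True)


def write_effects_tsv(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, sep="\t", index=False)
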