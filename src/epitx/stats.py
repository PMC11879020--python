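"""Performance aggregation, decile prioritisation and bootstrap eQTL enrichment.

The enrichment pipeline mirrors the perturbation-to-eQTL analysis: distal
perturbation effects are filtered away from the promoter zone (>6000 bp
upstream or >4000 bp downstream of the TSS), ranked into deciles of
expected-direction effect magnitude separately for upstream and downstream
regions, and each decile's proportion of regions containing a high-PIP,
tissue-specific fine-mapped SNP is compared against regions resampled from
all deciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

N_DECILES = 10


# ---------------------------------------------------------------------------
# performance aggregation and agreement


def aggregate_performance(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of Pearson r per mark set, aggregating cells and folds."""
    return (
        records.groupby("marks")["pearson_r"]
        .agg(mean_r="mean", sd_r="std", n="count")
        .reset_index()
    )


def agreement_matrix(predictions: dict[tuple, np.ndarray]) -> pd.DataFrame:
    """Mark-by-mark correlation of predictions matched on (cell, fold).

    ``predictions`` maps (marks, cell, fold) -> prediction vector.  Each
    pair of mark sets is correlated within every shared (cell, fold) and
    the correlations averaged.  Rows are ordered by hierarchical clustering
    (average linkage on 1 − r).
    """
    marks = sorted({k[0] for k in predictions})
    combos = sorted({k[1:] for k in predictions})
    mat = pd.DataFrame(np.nan, index=marks, columns=marks, dtype=float)
    for i, a in enumerate(marks):
        for b in marks[i:]:
            rs = []
            for cf in combos:
                ka, kb = (a, *cf), (b, *cf)
                if ka in predictions and kb in predictions:
                    pa, pb = predictions[ka], predictions[kb]
                    if np.std(pa) > 0 and np.std(pb) > 0:
                        rs.append(np.corrcoef(pa, pb)[0, 1])
            if rs:
                mat.loc[a, b] = mat.loc[b, a] = float(np.mean(rs))
    if len(marks) > 2 and not mat.isna().any().any():
        order = leaves_list(linkage(1.0 - mat.to_numpy()[np.triu_indices(len(marks), 1)], method="average"))
        ordered = [marks[i] for i in order]
        mat = mat.loc[ordered, ordered]
    return mat


def compare_groups(
    records: pd.DataFrame, mark_classes: dict[str, str]
) -> pd.DataFrame:
    """Wilcoxon rank-sum ESC-vs-primary contrasts per mark class, BH-adjusted.

    ``records`` needs columns marks, cell_state, pearson_r; ``mark_classes``
    maps a mark set to "active" or "repressive".
    """
    rows = []
    rec = records.copy()
    rec["mark_class"] = rec["marks"].map(mark_classes)
    for mark_class, sub in rec.groupby("mark_class"):
        esc = sub.loc[sub["cell_state"] == "ESC", "pearson_r"].to_numpy()
        prim = sub.loc[sub["cell_state"] == "primary tissue", "pearson_r"].to_numpy()
        if len(esc) < 2 or len(prim) < 2:
            logger.warning("mark class %s: group with <2 records, test skipped", mark_class)
            continue
        stat, p = ranksums(esc, prim)
        rows.append(
            dict(
                mark_class=mark_class,
                n_esc=len(esc),
                n_primary=len(prim),
                statistic=float(stat),
                p_value=float(p),
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def aggregate_and_compare(
    records: pd.DataFrame,
    predictions: dict[tuple, np.ndarray] | None = None,
    mark_classes: dict[str, str] | None = None,
) -> dict:
    """Summary stats, prediction-agreement matrix and group tests."""
    out = {"summary": aggregate_performance(records)}
    if predictions:
        out["agreement"] = agreement_matrix(predictions)
    if mark_classes:
        out["tests"] = compare_groups(records, mark_classes)
    return out


# ---------------------------------------------------------------------------
# decile enrichment


def filter_distal_effects(
    effects: pd.DataFrame,
    upstream_min: int = 6000,
    downstream_min: int = 4000,
) -> pd.DataFrame:
    """Keep bins clear of the promoter zone and label their side.

    Retains bins whose transcription-oriented midpoint lies more than
    ``upstream_min`` bp upstream (signed distance < −6000) or more than
    ``downstream_min`` bp downstream (> +4000) of the TSS.
    """
    d = effects["signed_distance"]
    out = effects[(d < -upstream_min) | (d > downstream_min)].copy()
    out["side"] = np.where(out["signed_distance"] < 0, "upstream", "downstream")
    return out.reset_index(drop=True)


def assign_deciles(filtered: pd.DataFrame) -> pd.DataFrame:
    """Rank regions by effect magnitude into deciles, per side.

    Decile 1 holds the smallest expected-direction effects and decile 10
    the largest; ties break deterministically on (gene_id, bin_start).
    Decile sizes within a side differ by at most one.
    """
    out = []
    for side, sub in filtered.groupby("side"):
        if len(sub) < N_DECILES:
            raise ValueError(f"side {side!r} has {len(sub)} regions; need >= {N_DECILES}")
        sub = sub.sort_values(
            ["effect_directional", "gene_id", "bin_start"],
            ascending=[True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        deciles = np.empty(len(sub), dtype=int)
        for i, chunk in enumerate(np.array_split(np.arange(len(sub)), N_DECILES)):
            deciles[chunk] = i + 1
        sub["decile"] = deciles
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def filter_tissue_specific_snps(
    snps: pd.DataFrame, pip_min: float = 0.9, pip_other_max: float = 0.1
) -> pd.DataFrame:
    """High-confidence, tissue-specific fine-mapped SNPs (PIP filter)."""
    return snps[
        (snps["pip_focal"] > pip_min) & (snps["pip_other_max"] < pip_other_max)
    ].reset_index(drop=True)


def _regions_with_snp(regions: pd.DataFrame, snps: pd.DataFrame) -> np.ndarray:
    """Boolean per region: contains >= 1 SNP (point-in-interval, 0-based)."""
    hit = np.zeros(len(regions), dtype=bool)
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in snps.groupby("chrom")}
    chroms = regions["chrom"].to_numpy()
    starts = regions["bin_start"].to_numpy()
    ends = regions["bin_end"].to_numpy()
    for i, (c, s, e) in enumerate(zip(chroms, starts, ends)):
        pos = by_chrom.get(c)
        if pos is not None:
            hit[i] = np.searchsorted(pos, e, "left") > np.searchsorted(pos, s, "left")
    return hit


@dataclass
class EnrichmentReport:
    table: pd.DataFrame
    n_boot: int
    seed: int


def bootstrap_enrichment(
    deciles: pd.DataFrame,
    snps: pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
    pip_min: float = 0.9,
    pip_other_max: float = 0.1,
) -> EnrichmentReport:
    """Per-decile SNP-overlap proportions against resampled null deciles.

    SNPs are first filtered to focal-tissue PIP > 0.9 and other-tissue
    PIP < 0.1.  For a decile of m regions, the null draws m regions without
    replacement from all of that side's regions ``n_boot`` times; the
    empirical p is (1 + #{null >= observed}) / (n_boot + 1), BH-adjusted
    across the ten deciles within each side.  The proportion is
    region-level: the fraction of decile regions containing >= 1 SNP.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is very low; p-values will be coarse", n_boot)
    qual = filter_tissue_specific_snps(snps, pip_min, pip_other_max)
    rng = np.random.default_rng(seed)
    rows = []
    for side, sub in deciles.groupby("side"):
        sub = sub.reset_index(drop=True)
        hit = _regions_with_snp(sub, qual)
        N, K = len(hit), int(hit.sum())
        for dec in range(1, N_DECILES + 1):
            members = sub["decile"].to_numpy() == dec
            m = int(members.sum())
            obs_count = int(hit[members].sum())
            # draws ~ count of SNP-bearing regions among m sampled w/o replacement
            draws = rng.hypergeometric(K, N - K, m, size=n_boot)
            p = (1 + int((draws >= obs_count).sum())) / (n_boot + 1)
            rows.append(
                dict(
                    side=side,
                    decile=dec,
                    n_regions=m,
                    observed_prop=obs_count / m,
                    null_mean=float(draws.mean() / m),
                    p_value=p,
                )
            )
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    for side in table["side"].unique():
        sel = table["side"] == side
        table.loc[sel, "q_value"] = multipletests(
            table.loc[sel, "p_value"], method="fdr_bh"
        )[1]
    return EnrichmentReport(table=table, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# benchmark locus sets


def benchmark_loci(
    mode: str,
    gene: pd.Series | dict,
    track=None,
    interactions: pd.DataFrame | None = None,
    side: str = "upstream",
    half_width: int = 20000,
    bin_size: int = 2000,
) -> list[tuple[str, int, int]]:
    """Alternative locus-prioritisation baselines for one gene.

    max_activity: the single 2000-bp bin of highest mean signal within
    ±20000 bp of the TSS.  hic: the gene's interaction fragments upstream of
    the TSS (transcription-oriented).  proximal: the 6000-bp flank just
    up- or downstream of the TSS as 2000-bp bins.
    """
    tss = int(gene["start"])
    chrom = gene["chrom"]
    strand = gene["strand"]
    sign = 1 if strand == "+" else -1
    if mode == "max_activity":
        if track is None:
            raise ValueError("max_activity mode needs a track")
        depth = track.window(chrom, tss - half_width, tss + half_width)
        v = np.log2(depth + 1.0)
        means = v.reshape(-1, bin_size).mean(axis=1)
        b = int(np.argmax(means))
        start = tss - half_width + b * bin_size
        return [(chrom, start, start + bin_size)]
    if mode == "hic":
        if interactions is None:
            raise ValueError("hic mode needs interactions")
        sel = interactions[
            (interactions["gene_id"] == gene["gene_id"])
            & (interactions["chrom"] == chrom)
        ]
        out = []
        for _, row in sel.iterrows():
            mid = (row["frag2_start"] + row["frag2_end"]) / 2
            if sign * (mid - tss) < 0:  # transcription-oriented upstream
                out.append((chrom, int(row["frag2_start"]), int(row["frag2_end"])))
        if not out:
            logger.warning("gene %s: no upstream interactions", gene["gene_id"])
        return out
    if mode == "proximal":
        if side == "upstream":
            lo = tss - 6000 if strand == "+" else tss
        elif side == "downstream":
            lo = tss if strand == "+" else tss - 6000
        else:
            raise ValueError(f"unknown side {side!r}")
        return [
            (chrom, lo + i * bin_size, lo + (i + 1) * bin_size) for i in range(6000 // bin_size)
        ]
    raise ValueError(f"unknown mode {mode!r}")


def write_decile_bed(deciles: pd.DataFrame, path) -> None:
    """Decile regions as BED (name = side_decile), consumable as annotations."""
    bed = deciles[["chrom", "bin_start", "bin_end"]].copy()
    bed["name"] = deciles["side"] + "_d" + deciles["decile"].astype(str)
    bed.sort_values(["chrom", "bin_start"]).to_csv(
        path, sep="\t", header=False, index=False
    )
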