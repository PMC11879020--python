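"""From depth tracks to model-ready windows, targets and folds.

Binning follows log-then-average order: per-base v = log2(depth + 1), then
the per-bin mean of v at 100/500/2000 bp.  Doing the log at base resolution
makes the three resolutions mutually consistent (every coarser bin is an
exact mean of the finer values) and maps depth 0 to signal 0.  Minus-strand
windows are reversed so index 0 is always the 5'-most bin in transcription
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from epitx.tracks import DepthTrack

RESOLUTIONS = (100, 500, 2000)


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int  # 0-based, may be negative (zero-filled on read)
    end: int  # half-open
    strand: str
    anchor: int  # TSS

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"window start {self.start} >= end {self.end}")
        if not self.start <= self.anchor < self.end:
            raise ValueError("anchor must lie inside the window")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class BinnedSignal:
    values: np.ndarray  # log2 scale, 5'->3' of the gene
    resolution: int

    def __len__(self):
        return len(self.values)


def make_gene_windows(
    annotation: pd.Series | dict,
    purpose: str,
    promoter_half_width: int = 3000,
    distal_half_width: int = 20000,
) -> GenomicWindow:
    """Symmetric TSS-centred window: +-3000 bp (promoter) or +-20000 bp (distal)."""
    half = {"promoter": promoter_half_width, "distal": distal_half_width}.get(purpose)
    if half is None:
        raise ValueError(f"unknown purpose {purpose!r}")
    tss = int(annotation["start"])
    return GenomicWindow(
        chrom=annotation["chrom"],
        start=tss - half,
        end=tss + half,
        strand=annotation["strand"],
        anchor=tss,
    )


def bin_signal(track: DepthTrack, window: GenomicWindow, resolution: int) -> BinnedSignal:
    """Mean of per-base log2(depth+1) in fixed-width bins, 5'->3' oriented.

    Bases outside covered intervals (including beyond chromosome ends)
    contribute v = 0.
    """
    if window.width % resolution != 0:
        raise ValueError(
            f"window {window.chrom}:{window.start}-{window.end} width "
            f"{window.width} not divisible by resolution {resolution}"
        )
    depth = track.window(window.chrom, window.start, window.end)
    v = np.log2(depth + 1.0)
    values = v.reshape(-1, resolution).mean(axis=1)
    if window.strand == "-":
        values = values[::-1].copy()
    return BinnedSignal(values=values, resolution=resolution)


def transform_and_classify_expression(rpkm: pd.DataFrame) -> pd.DataFrame:
    """log2(RPKM+1) plus the per-cell median active/inactive split.

    Input columns: gene_id, cell, rpkm (>= 0).  A gene is active iff its
    log2rpkm exceeds the median over all genes of that cell; ties are
    inactive.
    """
    if (rpkm["rpkm"] < 0).any():
        bad = rpkm.loc[rpkm["rpkm"] < 0].iloc[0]
        raise ValueError(f"negative RPKM for gene {bad['gene_id']}")
    out = rpkm.copy()
    out["log2rpkm"] = np.log2(out["rpkm"] + 1.0)
    return classify_expression(out.drop(columns=["rpkm"]))


def classify_expression(log2_expr: pd.DataFrame) -> pd.DataFrame:
    """Median split on an already log2(RPKM+1)-scale table."""
    out = log2_expr.copy()
    med = out.groupby("cell")["log2rpkm"].transform("median")
    out["state"] = np.where(out["log2rpkm"] > med, "active", "inactive")
    return out


def make_chromosome_folds(
    annotations: pd.DataFrame, k: int = 4, seed: int = 0
) -> dict[str, int]:
    """Chromosome-coherent fold assignment by greedy gene-count balancing.

    Chromosomes are taken largest-first (seeded random order within ties)
    and each is placed in the currently smallest fold, so all genes of one
    chromosome share a fold while fold sizes stay near-balanced.
    """
    counts = annotations.groupby("chrom")["gene_id"].count()
    if len(counts) < k:
        raise ValueError(f"need at least k={k} chromosomes, have {len(counts)}")
    rng = np.random.default_rng(seed)
    order = sorted(
        counts.index, key=lambda c: (-counts[c], rng.random())
    )
    fold_sizes = [0] * k
    chrom_fold: dict[str, int] = {}
    for chrom in order:
        f = int(np.argmin(fold_sizes))
        chrom_fold[chrom] = f
        fold_sizes[f] += int(counts[chrom])
    return {
        row.gene_id: chrom_fold[row.chrom] for row in annotations.itertuples()
    }


def mark_level_summary(
    binned: dict[str, np.ndarray], states: dict[str, str]
) -> dict[str, float]:
    """Mean 100-bp-binned log2 signal per expression state over a gene set."""
    out: dict[str, float] = {}
    for state in ("active", "inactive"):
        genes = [g for g, s in states.items() if s == state and g in binned]
        if not genes:
            raise ValueError(f"no genes with state {state!r} in the subset")
        out[state] = float(np.mean(np.concatenate([np.ravel(binned[g]) for g in genes])))
    return out


def write_binned_dataset(path, binned: dict) -> None:
    """HDF5 container keyed (gene, cell, mark, resolution) -> vector."""
    import h5py

    with h5py.File(path, "w") as fh:
        for (gene, cell, mark, res), values in binned.items():
            fh.create_dataset(f"{cell}/{mark}/{res}/{gene}", data=np.asarray(values))


def read_binned_dataset(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for cell in fh:
            for mark in fh[cell]:
                for res in fh[cell][mark]:
                    for gene in fh[cell][mark][res]:
                        out[(gene, cell, mark, int(res))] = fh[cell][mark][res][gene][()]
    return out


def write_fold_assignment(folds: dict[str, int], path) -> None:
    pd.DataFrame(
        {"gene_id": list(folds), "fold": list(folds.values())}
    ).to_csv(path, sep="\t", index=False)
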