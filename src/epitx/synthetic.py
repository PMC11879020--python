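"""Seeded synthetic data with planted regulatory ground truth.

The generator emulates the statistical structure the downstream analyses
assume: log2(RPKM+1)-scale expression driven by a promoter strength plus
distal enhancer effects, histone-mark depth tracks whose peak amplitudes
track those effects (positively for an active mark, inversely with
expression for a repressive one), chromatin interactions linking each
promoter to its causal enhancer fragments (plus scored decoys), and
fine-mapped SNPs whose high-PIP, tissue-specific subset concentrates inside
causal enhancer bins.

Everything is deterministic given the config seed: per-stage RNGs are
spawned from ``numpy`` seed sequences so identical configs yield
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from epitx.tracks import DepthTrack

logger = logging.getLogger(__name__)

FRAGMENT_WIDTH = 2000  # bp, resolution of interaction fragments and distal bins


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset (one mark, one cell).

    Widths are in bp; effects and noise are on the log2(RPKM+1) scale.
    """

    seed: int = 0
    n_chromosomes: int = 4
    n_genes: int = 100
    promoter_half_width: int = 3000
    distal_half_width: int = 20000
    mark_polarity: str = "active"  # or "repressive"
    peak_width_sd: float = 300.0
    background_rate: float = 0.5  # mean reads/bp of Poisson background
    enhancers_per_gene: tuple[int, int] = (1, 3)
    enhancer_effect_sd: float = 1.0
    promoter_effect: float = 1.5
    noise_sd: float = 0.4
    causal_snp_fraction: float = 0.7
    decoy_interaction_rate: float = 0.3
    snps_per_gene: int = 3
    cell: str = "C1"
    # plumbing knobs
    amplitude_scale: float = 40.0  # peak depth per unit strength/effect
    min_enhancer_offset: int = 8000  # keeps enhancers clear of the promoter zone
    gene_spacing_margin: int = 4000
    allow_window_overlap: bool = False
    chromosome_length: int | None = None  # cap; None = sized to fit

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        for name in ("promoter_half_width", "distal_half_width", "peak_width_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for name in ("causal_snp_fraction", "decoy_interaction_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mark_polarity not in ("active", "repressive"):
            raise ValueError(f"unknown mark_polarity {self.mark_polarity!r}")
        lo, hi = self.enhancers_per_gene
        if lo < 0 or hi < lo:
            raise ValueError("enhancers_per_gene must be a non-negative range")
        if not self.min_enhancer_offset < self.distal_half_width:
            raise ValueError("min_enhancer_offset must be < distal_half_width")

    def gene_spacing(self) -> int:
        return 2 * self.distal_half_width + self.gene_spacing_margin

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed generator so stages are independent and reproducible."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class Enhancer:
    offset: int  # signed bp from TSS, transcription-oriented (+ = downstream)
    effect: float  # signed contribution to log2 expression
    bin_index: int  # 2000-bp bin within the distal window, genomic order


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    promoter_strength: float
    enhancers: list[Enhancer] = field(default_factory=list)
    causal_snps: list[int] = field(default_factory=list)
    expression_noise_free: float = 0.0

    def enhancer_position(self, enh: Enhancer) -> int:
        """Genomic coordinate of the enhancer centre."""
        sign = 1 if self.strand == "+" else -1
        return self.tss + sign * enh.offset

    def window_start(self, half_width: int) -> int:
        return self.tss - half_width

    def causal_bins(self) -> list[int]:
        return [e.bin_index for e in self.enhancers]


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth]
    config: SyntheticConfig

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self):
        return len(self.genes)

    def expression_cap(self) -> float:
        return max((g.expression_noise_free for g in self), default=0.0)

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "genes": {gid: asdict(g) for gid, g in self.genes.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_counts_per_chrom(n_genes: int, n_chrom: int) -> list[int]:
    base, extra = divmod(n_genes, n_chrom)
    return [base + (1 if i < extra else 0) for i in range(n_chrom)]


def generate_genome(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Lay out genes on chromosomes and draw the planted regulatory truth.

    Genes are spaced >= 2 * distal_half_width apart so distal windows never
    overlap (unless ``allow_window_overlap``).  Returns a BED6-style
    annotation frame and the fully-populated :class:`GroundTruth` (causal
    SNP positions are filled in by
    :func:`synthesize_interactions_and_snps`).
    """
    config.validate()
    rng = config.rng(0)
    spacing = config.gene_spacing()
    offset0 = config.distal_half_width + config.gene_spacing_margin

    counts = _gene_counts_per_chrom(config.n_genes, config.n_chromosomes)
    if config.chromosome_length is not None:
        for ci, cnt in enumerate(counts):
            needed = offset0 + max(cnt - 1, 0) * spacing + config.distal_half_width
            if cnt > 0 and needed > config.chromosome_length:
                if not config.allow_window_overlap:
                    raise ValueError(
                        f"cannot place {cnt} non-overlapping gene windows on "
                        f"chr{ci + 1} of length {config.chromosome_length}"
                    )
                logger.warning(
                    "chr%d: %d genes exceed length %d; windows may be truncated",
                    ci + 1,
                    cnt,
                    config.chromosome_length,
                )

    lo_e, hi_e = config.enhancers_per_gene
    genes: dict[str, GeneTruth] = {}
    rows = []
    gidx = 0
    for ci, cnt in enumerate(counts):
        chrom = f"chr{ci + 1}"
        for j in range(cnt):
            gene_id = f"G{gidx:05d}"
            tss = offset0 + j * spacing + int(
                rng.integers(0, config.gene_spacing_margin // 2)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            strength = float(rng.gamma(shape=2.0, scale=0.5))
            n_enh = int(rng.integers(lo_e, hi_e + 1))
            g = GeneTruth(gene_id, chrom, tss, strand, strength)
            for _ in range(n_enh):
                mag = int(
                    rng.integers(config.min_enhancer_offset, config.distal_half_width - FRAGMENT_WIDTH)
                )
                off = mag if rng.random() < 0.5 else -mag
                eff = abs(float(rng.normal(0.0, config.enhancer_effect_sd)))
                if config.mark_polarity == "repressive":
                    eff = -eff
                pos = g.enhancer_position(Enhancer(off, 0.0, 0))
                bin_index = (pos - (tss - config.distal_half_width)) // FRAGMENT_WIDTH
                g.enhancers.append(Enhancer(off, eff, int(bin_index)))
            linear = config.promoter_effect * strength + sum(
                e.effect for e in g.enhancers
            )
            g.expression_noise_free = max(linear, 0.0)
            genes[gene_id] = g
            rows.append(
                dict(chrom=chrom, start=tss, end=tss + 1, gene_id=gene_id, score=0, strand=strand)
            )
            gidx += 1

    annot = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])
    return annot, GroundTruth(genes, config)


def _add_peak(depth: np.ndarray, block_start: int, center: int, amp: float, sd: float) -> None:
    if amp <= 0:
        return
    half = int(np.ceil(4 * sd))
    lo = max(center - half - block_start, 0)
    hi = min(center + half + 1 - block_start, len(depth))
    if hi <= lo:
        return
    x = np.arange(lo, hi) + block_start
    depth[lo:hi] += np.rint(amp * np.exp(-0.5 * ((x - center) / sd) ** 2)).astype(depth.dtype)


def synthesize_track(
    ground_truth: GroundTruth,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> DepthTrack:
    """Per-base depth: Poisson background plus Gaussian peaks.

    For an active mark, promoter peak amplitude is proportional to promoter
    strength and enhancer peaks to the planted effect size; for a repressive
    mark, the promoter amplitude decreases with (noise-free) expression.
    Depth is generated inside each gene's distal window (plus a margin);
    windows never overlap under the default spacing, so the rest of the
    genome — never read by the pipeline — stays at zero depth.
    """
    config = config or ground_truth.config
    config.validate()
    rng = (
        np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        if seed is None
        else np.random.default_rng(seed)
    )
    # TSS jitter is < margin/2, so adjacent windows stay >= margin/2 apart;
    # a pad of margin/4 per side keeps blocks disjoint.
    pad = config.gene_spacing_margin // 4
    cap = ground_truth.expression_cap()
    track = DepthTrack()
    for g in ground_truth:
        start = g.tss - config.distal_half_width - pad
        width = 2 * config.distal_half_width + 2 * pad
        depth = rng.poisson(config.background_rate, width).astype(np.int32)
        if config.mark_polarity == "active":
            prom_amp = config.amplitude_scale * g.promoter_strength
        else:
            rel = (cap - g.expression_noise_free) / cap if cap > 0 else 0.0
            prom_amp = config.amplitude_scale * rel
        _add_peak(depth, start, g.tss, prom_amp, config.peak_width_sd)
        for e in g.enhancers:
            _add_peak(
                depth,
                start,
                g.enhancer_position(e),
                config.amplitude_scale * abs(e.effect),
                config.peak_width_sd,
            )
        track.add_block(g.chrom, start, depth)
    return track


def synthesize_expression(
    ground_truth: GroundTruth,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy expression on the log2(RPKM+1) scale, floored at zero."""
    config = config or ground_truth.config
    config.validate()
    rng = (
        np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        if seed is None
        else np.random.default_rng(seed)
    )
    rows = []
    for g in ground_truth:
        noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        rows.append(
            dict(
                gene_id=g.gene_id,
                cell=config.cell,
                log2rpkm=max(g.expression_noise_free + noise, 0.0),
            )
        )
    return pd.DataFrame(rows)


def noise_ceiling(ground_truth: GroundTruth, config: SyntheticConfig | None = None) -> float:
    """Analytic upper bound on Pearson r against noisy expression.

    r* = sd_signal / sqrt(sd_signal^2 + noise_sd^2), with sd_signal the
    spread of the noise-free expression.  The zero floor makes this an
    approximation when noise pushes genes below zero.
    """
    config = config or ground_truth.config
    sig = np.std([g.expression_noise_free for g in ground_truth])
    return float(sig / np.sqrt(sig**2 + config.noise_sd**2))


def synthesize_interactions_and_snps(
    ground_truth: GroundTruth,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chromatin interactions to causal fragments (plus decoys) and SNPs.

    One high-scoring interaction per true enhancer links the TSS fragment to
    the enhancer's 2000-bp fragment; each non-causal fragment of the distal
    window receives a lower-scoring decoy with probability
    ``decoy_interaction_rate``.  A ``causal_snp_fraction`` share of each
    gene's SNPs is placed uniformly inside causal bins with focal-tissue
    PIP > 0.9 and other-tissue PIP < 0.1; the rest fall uniformly in the
    window with all PIPs < 0.1.  Causal SNP positions are recorded back into
    the ground truth.
    """
    config = config or ground_truth.config
    config.validate()
    rng = (
        np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        if seed is None
        else np.random.default_rng(seed)
    )
    n_bins = (2 * config.distal_half_width) // FRAGMENT_WIDTH
    inter_rows = []
    snp_rows = []
    snp_idx = 0
    for g in ground_truth:
        win_start = g.tss - config.distal_half_width
        tss_bin = (g.tss - win_start) // FRAGMENT_WIDTH
        causal = sorted(set(g.causal_bins()))
        for e in g.enhancers:
            f2 = win_start + e.bin_index * FRAGMENT_WIDTH
            inter_rows.append(
                dict(
                    chrom=g.chrom,
                    frag1_start=win_start + tss_bin * FRAGMENT_WIDTH,
                    frag1_end=win_start + (tss_bin + 1) * FRAGMENT_WIDTH,
                    frag2_start=f2,
                    frag2_end=f2 + FRAGMENT_WIDTH,
                    score=float(rng.uniform(5.0, 10.0)),
                    gene_id=g.gene_id,
                )
            )
        if config.decoy_interaction_rate > 0:
            candidates = [
                b for b in range(n_bins) if b not in causal and b != tss_bin
            ]
            hit = rng.random(len(candidates)) < config.decoy_interaction_rate
            for b, h in zip(candidates, hit):
                if not h:
                    continue
                f2 = win_start + b * FRAGMENT_WIDTH
                inter_rows.append(
                    dict(
                        chrom=g.chrom,
                        frag1_start=win_start + tss_bin * FRAGMENT_WIDTH,
                        frag1_end=win_start + (tss_bin + 1) * FRAGMENT_WIDTH,
                        frag2_start=f2,
                        frag2_end=f2 + FRAGMENT_WIDTH,
                        score=float(rng.uniform(0.5, 3.0)),
                        gene_id=g.gene_id,
                    )
                )
        n_causal = int(round(config.causal_snp_fraction * config.snps_per_gene))
        if n_causal > 0 and not causal:
            logger.info("gene %s has no enhancers; causal SNPs skipped", g.gene_id)
            n_causal = 0
        for _ in range(n_causal):
            b = int(rng.choice(causal))
            pos = win_start + b * FRAGMENT_WIDTH + int(rng.integers(0, FRAGMENT_WIDTH))
            g.causal_snps.append(pos)
            snp_rows.append(
                dict(
                    chrom=g.chrom,
                    pos=pos,
                    snp_id=f"rs{snp_idx:07d}",
                    pip_focal=float(rng.uniform(0.9, 1.0)) + 1e-9,
                    pip_other_max=float(rng.uniform(0.0, 0.1)),
                )
            )
            snp_idx += 1
        for _ in range(config.snps_per_gene - n_causal):
            pos = win_start + int(rng.integers(0, 2 * config.distal_half_width))
            snp_rows.append(
                dict(
                    chrom=g.chrom,
                    pos=pos,
                    snp_id=f"rs{snp_idx:07d}",
                    pip_focal=float(rng.uniform(0.0, 0.1)),
                    pip_other_max=float(rng.uniform(0.0, 0.1)),
                )
            )
            snp_idx += 1

    interactions = pd.DataFrame(
        inter_rows,
        columns=[
            "chrom",
            "frag1_start",
            "frag1_end",
            "frag2_start",
            "frag2_end",
            "score",
            "gene_id",
        ],
    )
    snps = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "snp_id", "pip_focal", "pip_other_max"]
    )
    return interactions, snps


@dataclass
class SyntheticDataset:
    """One simulated mark/cell with its annotations and planted truth."""

    config: SyntheticConfig
    annotations: pd.DataFrame
    ground_truth: GroundTruth
    track: DepthTrack
    expression: pd.DataFrame
    interactions: pd.DataFrame
    snps: pd.DataFrame


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run all generator stages for one config."""
    annotations, gt = generate_genome(config)
    track = synthesize_track(gt, config)
    interactions, snps = synthesize_interactions_and_snps(gt, config)
    expression = synthesize_expression(gt, config)
    return SyntheticDataset(config, annotations, gt, track, expression, interactions, snps)


# ---------------------------------------------------------------------------
# plain-text writers


def write_bed6(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", header=False, index=False)


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index=False)


def write_interactions_tsv(interactions: pd.DataFrame, path) -> None:
    interactions.to_csv(path, sep="\t", index=False)


def write_snps_tsv(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write every artefact of a dataset as plain text under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed6(ds.annotations, outdir / "genes.bed")
    ds.track.to_bedgraph(outdir / "track.bedGraph")
    write_expression_tsv(ds.expression, outdir / "expression.tsv")
    write_interactions_tsv(ds.interactions, outdir / "interactions.tsv")
    write_snps_tsv(ds.snps, outdir / "snps.tsv")
    ds.ground_truth.to_json(outdir / "ground_truth.json")
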