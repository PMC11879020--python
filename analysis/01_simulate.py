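"""Simulate the demo dataset and write its plain-text artefacts.

Writes gene annotations (BED6), expression (TSV), interactions (TSV),
fine-mapped SNPs (TSV) and the planted ground truth (JSON) under
results/data/, plus a bedGraph excerpt of the depth track for the first
five genes (the full per-base track is regenerated from the seed on
demand rather than stored).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
from common import DATA_DIR, MARK, demo_config

from epitx.synthetic import (
    simulate_dataset,
    write_bed6,
    write_expression_tsv,
    write_interactions_tsv,
    write_snps_tsv,
)
from epitx.tracks import DepthTrack


def main():
    cfg = demo_config()
    ds = simulate_dataset(cfg)
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    write_bed6(ds.annotations, DATA_DIR / "genes.bed")
    write_expression_tsv(ds.expression, DATA_DIR / "expression.tsv")
    write_interactions_tsv(ds.interactions, DATA_DIR / "interactions.tsv")
    write_snps_tsv(ds.snps, DATA_DIR / "snps.tsv")
    ds.ground_truth.to_json(DATA_DIR / "ground_truth.json")

    excerpt = DepthTrack()
    for _, g in ds.annotations.head(5).iterrows():
        start = g["start"] - cfg.distal_half_width
        end = g["start"] + cfg.distal_half_width
        excerpt.add_block(g["chrom"], start, ds.track.window(g["chrom"], start, end))
    excerpt.to_bedgraph(DATA_DIR / f"{MARK}.excerpt.bedGraph")

    n_enh = sum(len(g.enhancers) for g in ds.ground_truth)
    n_causal = (ds.snps["pip_focal"] > 0.9).sum()
    print(f"simulated {len(ds.annotations)} genes on {cfg.n_chromosomes} chromosomes")
    print(f"planted {n_enh} enhancers; {len(ds.interactions)} interactions "
          f"({n_enh} causal + decoys)")
    print(f"{len(ds.snps)} SNPs of which {n_causal} are high-PIP tissue-specific")
    print(f"expression: mean log2(RPKM+1) = {ds.expression['log2rpkm'].mean():.2f}, "
          f"sd = {ds.expression['log2rpkm'].std():.2f}")
    print(f"artefacts under {DATA_DIR}")


if __name__ == "__main__":
    main()
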