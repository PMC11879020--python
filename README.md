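# epitx

Predicting gene expression from histone-mark ChIP-seq signal, at two
regulatory distances, and using the trained models to prioritise
cis-regulatory loci by in-silico perturbation.

## The problem

Histone marks (H3K4me3, H3K27ac, H3K27me3, ...) correlate with
transcription, but the strength of that relationship depends on the mark's
function (activating vs repressive), on genomic distance (promoter vs
distal enhancer), and on cell state. `epitx` implements the full modelling
stack needed to study this:

- **Promoter model** — a convolutional network regressing log2(RPKM+1)
  expression on the mark signal in a symmetric 6000-bp window centred on
  the TSS, binned at 100 bp (60 bins): three blocks of
  conv → batch-norm → ReLU → max-pool → dropout, two fully connected
  blocks, linear output.
- **Distal model** — an attention model over the 40 000-bp window around
  the TSS, with three independent resolution modules (100 / 500 / 2000 bp).
  Each module tokenises the window into twenty 2000-bp segments plus up to
  M promoter-capture Hi-C interacting fragments (score-ranked, min-max
  weighted), passes the tokens through a transformer block that respects
  the fragment padding mask, and pools them; the three pooled vectors feed
  a fully connected head with a linear output.
- **Training** — MSE loss, ADAM, batch 64, ≤100 epochs, early stopping
  (patience 12 on validation loss), learning rate 0.001 decayed ×0.2 after
  3 non-improving epochs; 4-fold cross-validation with all genes of a
  chromosome kept in the same fold to prevent leakage. Performance is the
  Pearson r on the blind test fold.
- **In-silico perturbation** — signal in a region is scaled in linear
  depth space, `v → log2(λ·(2^v − 1) + 1)` for λ ∈ {0, 0.1, …, 1}, either
  over the whole promoter window or bin-by-bin over the twenty 2000-bp bins
  of the distal field, with predictions averaged over the fold-model
  ensemble; plus input-gradient attribution maps.
- **eQTL enrichment** — ablation effects are filtered away from the
  promoter zone (>6000 bp upstream, >4000 bp downstream), split into effect
  deciles separately for upstream and downstream regions, and each decile
  is tested for enrichment of high-confidence tissue-specific fine-mapped
  SNPs (PIP > 0.9 focal, < 0.1 elsewhere) against 10 000 resampled region
  sets, with BH-FDR correction — alongside maximum-activity, Hi-C and
  proximal-flank benchmark locus sets.

Because the real corpus (Roadmap ChIP-seq, RefSeq, pcHi-C, UK-Biobank
fine-mapped eQTLs) is not reproducible at desk scale, the package ships a
seeded **synthetic generator** that plants the ground truth the analyses
are supposed to recover: promoter strengths and distal enhancer effects on
the log2(RPKM+1) scale, depth tracks whose peaks track those effects
(positively for an active mark, inversely for a repressive one), Hi-C
links pointing at the causal enhancer fragments, and causal SNPs
concentrated inside causal bins. Every claim the tests make is checked
against this planted truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a 400-gene
simulated dataset (one active mark, 1–2 planted enhancers per gene):

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_train_promoter.py
python analysis/04_train_distal.py
python analysis/05_perturb.py
python analysis/06_enrichment.py
```

which prints, among other things:

```
promoter model test r = 0.704
noise ceiling r* = 0.978
distal model, test fold 0: r = 0.885
distal gain on fold 0: +0.181
median rank of the causal bin among the 20 bins: 1
causal bin is the top distal effect for 99% of genes
upstream: decile 10 SNP-bearing fraction 0.76 vs null 0.08, q = 0.001
deciles 1-5 minimum q = 1 (no spurious enrichment)
```

Read: the promoter CNN explains what the 6-kb window can see (r = 0.70)
but sits well below the simulation's noise ceiling (r* = 0.98) because the
planted enhancer effects are out of its receptive field; the distal
attention model recovers most of that gap (+0.18). Ablating 2000-bp bins
one at a time points at the planted enhancer bin first for 99% of test
genes, and the top effect decile is strongly enriched for the planted
tissue-specific SNPs while the low deciles are clean.

## Layout

```
src/epitx/          library: synthetic, tracks, signal, nn, models,
                    perturb, stats, experiments
analysis/           numbered drivers over the library (the study)
tests/              pytest suite incl. end-to-end acceptance properties
scripts/acceptance.py   headline-number reproduction
docs/methods.md     models, parameters, numerical choices, limitations
```
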