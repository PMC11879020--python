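# Methods

## Signal representation

All models consume binned, strand-oriented, log-scale signal. Per base,
v = log2(depth + 1); bins are means of v over 100, 500 or 2000 bp. The log
is taken at base resolution *before* averaging, which makes the three
resolutions mutually consistent (every 2000-bp bin equals the mean of its
twenty 100-bp bins exactly) and maps zero depth to zero signal; the +1
pseudocount is forced by requiring depth 0 → 0. The alternative order
(average depth, then log) is a defensible choice too; it is deliberately
not exposed as an option because mixing orders breaks cross-resolution
consistency.

Coordinates are 0-based half-open throughout; the TSS is a single base;
windows are [TSS − w, TSS + w) with w = 3000 (promoter) or 20 000
(distal). Windows overrunning chromosome ends are zero-filled rather than
dropped. Minus-strand windows are reversed after binning so index 0 is
always 5′-most in transcription orientation. One TSS per gene id is
required in the annotation input; upstream transcript selection is the
caller's concern.

Expression targets are log2(RPKM + 1). A gene is "active" in a cell type
iff its value strictly exceeds that cell type's median across genes; ties
count as inactive (deterministic and conservative; the median gene itself
is not "above" the median).

Cross-validation folds (k = 4) are chromosome-coherent: chromosomes are
assigned greedily, largest gene count first, each to the currently
smallest fold, with seeded random order among tied counts. Greedy LPT
balancing is optimal for the small chromosome counts used here and
near-optimal in general; unequal fold sizes are acceptable by design.

## Synthetic data generator

The generator plants a known regulatory architecture and emits every input
format the pipeline reads, so all downstream stages can be validated
against ground truth.

Per gene g: a promoter strength s_g ~ Gamma(2, 0.5) (mean 1), and
E_g ∈ {enhancers_per_gene} enhancers with transcription-oriented offsets
drawn uniformly in ±[8000, 18000] bp — outside both the 6-kb promoter
window and the enrichment module's exclusion zone, so distal effects are
genuinely distal — and effect sizes |N(0, enhancer_effect_sd)| (negated
for a repressive mark). Noise-free expression is
clip₀(promoter_effect·s_g + Σ_e effect_e); observed expression adds
N(0, noise_sd) and clips at zero, mirroring the non-negativity of
log2(RPKM+1). The analytic ceiling on achievable Pearson r is
r* = sd(signal)/√(sd(signal)² + noise_sd²) (approximate when the zero
floor binds).

Tracks are integer per-base depth: Poisson background (mean
background_rate = 0.5 reads/bp) plus discretised Gaussian peaks
(sd = 300 bp) at the promoter and each enhancer. For an active mark the
promoter peak amplitude is amplitude_scale·s_g (amplitude_scale = 40
reads at the apex per unit strength — log2(41) ≈ 5.4, a realistic dynamic
range after log transform); enhancer peaks scale with |effect|. For a
repressive mark the promoter amplitude decreases linearly with noise-free
expression — an inverted coupling, not a mechanistic model of silencing.
Genes are spaced ≥ 2·distal_half_width apart so 40-kb windows never
overlap; depth is therefore generated only inside each gene's window (the
rest of the genome is never read and stays at zero depth).

Interactions link the TSS fragment to each enhancer's 2000-bp fragment
with score U(5, 10); every other non-causal window fragment becomes a
decoy with probability decoy_interaction_rate (score U(0.5, 3)). SNPs:
a causal_snp_fraction share per gene lands uniformly inside causal bins
with focal PIP in (0.9, 1] and other-tissue PIP in [0, 0.1); the rest are
uniform over the window with all PIPs below 0.1. The `snps_per_gene`
count (default 3) sets the totals.

What the generator does **not** emulate: nucleosome-level peak shapes,
sequence content, mappability artefacts, LD among SNPs, diploid genotypes,
inter-gene window overlap, or experiment-to-experiment depth variation.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under its own statistical assumptions — not performance on real
Roadmap data.

## Models

**Promoter CNN.** Input (n_marks × 60). Defaults: three conv blocks
(filters 50, kernels 10/5/5, max-pool 2, dropout 0.1), each
conv → batch-norm → ReLU → pool → dropout; fully connected 128 → 32 with
dropout before the first dense layer; linear scalar output. Marks stack as
channels. Exact sizes are configuration, chosen DeepChrome-like, not
doctrine.

**Distal attention model.** Three independent resolution modules
(100/500/2000 bp). Each module sees 20 + M tokens: the twenty 2000-bp
window segments plus up to M = 8 interacting fragments (score-ranked;
ties by fragment start; fragments on other chromosomes skipped with a
warning). Token features are the per-mark signal of the 2000-bp span at
the module's resolution (20/4/1 values per mark). Tokens are linearly
embedded (dim 32); fragment embeddings are multiplied by the gene's
min-max-normalised interaction score (a single fragment gets weight 1);
one transformer block (4 heads, feed-forward 64, pre-pool LayerNorms)
attends with padded slots excluded as keys; valid tokens are mean-pooled.
The three pooled vectors concatenate into a dropout + dense(64) + ReLU
head with linear output. Padded-slot contents provably never reach the
output (their embeddings are zeroed, they are masked as keys, and pooling
excludes them); a test perturbs them to confirm. This architecture
realises the stated three-resolution, interaction-weighted attention
contract compactly; it is not a weight-level reproduction of any external
model, and how the original combines interaction frequency with fragment
embeddings is replaced by the documented score-weighting above.

The networks are implemented in numpy with explicit backprop. This keeps
the dependency surface minimal at the problem sizes used here and makes
input gradients (needed for attribution) a first-class operation; every
layer is verified against central finite differences in the tests.

**Training.** Shared engine for both models: MSE, ADAM (β₁ = 0.9,
β₂ = 0.999, ε = 1e-8), batch 64, max 100 epochs. "Improvement" is a
validation-loss decrease > 1e-6. After 3 consecutive non-improving epochs
the learning rate (initial 0.001) is multiplied by 0.2 and the decay
counter resets; after 12 non-improving epochs training stops; weights are
restored to the best-validation epoch. Seeds fix initialisation, batch
order and dropout, making runs bit-reproducible on one device. At very
small n (tens of genes) an epoch is few optimiser steps and the plateau
decay can freeze learning early; the overfit sanity test therefore uses
batch 8 and a hotter initial rate, which the schedule exposes as ordinary
configuration.

## Perturbation

Level λ scales the signal in linear depth space,
v → log2(λ·(2^v − 1) + 1): λ = 1 is the bit-exact identity and λ = 0
empties the region, so λ reads as a fractional activity knob. Scaling v
itself (log-space) is available behind a flag for sensitivity analysis;
linear-space is the default because its endpoints behave exactly.

Assays run on the fold-model ensemble (arithmetic mean of predictions),
on active genes for an active mark and inactive genes for a repressive
one. Promoter assays perturb the whole ±3000-bp window. Distal assays
perturb each of the twenty non-overlapping 2000-bp bins tiled from the
upstream window edge — including the two bins straddling the TSS, which
downstream enrichment filters out — in all three resolution channels and
in any interacting fragment overlapping the bin. The per-bin *effect* is
the signed level-0 delta (prediction with the bin emptied minus baseline);
ranking uses the magnitude of the expected-direction change (decrease for
an active mark, increase for a repressive one).

Causal-bin recovery reports two numbers: the median rank of the planted
bin among all twenty bins, and the fraction of genes whose top-effect bin
*excluding the two promoter-overlap bins* is causal. The exclusion is
deliberate: emptying the promoter legitimately produces the largest
predicted drop for many genes — that is known biology, not a recovery
failure — and the enrichment analysis applies the same exclusion.

Attribution is the ensemble-averaged gradient of the prediction with
respect to the input signal, summed into 2000-bp bins for display.

## Enrichment statistics

Effects are filtered to bins whose transcription-oriented midpoint is
> 6000 bp upstream or > 4000 bp downstream of the TSS, then ranked into
deciles of directional effect magnitude separately per side (decile 10 =
largest; ties broken on (gene, bin start); sizes within one). SNPs are
pre-filtered to focal PIP > 0.9 and other-tissue PIP < 0.1. The statistic
is region-level — the fraction of a decile's regions containing ≥ 1
qualifying SNP (well-defined when per-region SNP counts vary; a SNP-level
proportion is the alternative reading). The null resamples m regions
without replacement from the side's full region set; since only the
overlap count enters the statistic, draws are taken from the equivalent
hypergeometric law, which is exact and fast. Empirical
p = (1 + #{null ≥ observed})/(n_boot + 1), so p is never 0 and never
below 1/(n_boot+1); BH-FDR is applied across the ten deciles within each
side. The resampling p is validated against exhaustive enumeration
(hypergeometric tail) on a 20-region toy, and its null distribution is
checked for super-uniformity — the one-sided direction is the correct
property for a conservative discrete test.

Benchmark locus sets per gene: the single 2000-bp bin of maximum mean
signal within ±20 kb; the gene's transcription-upstream interaction
fragments; and the 6000-bp proximal flank as three 2000-bp bins.

## Problem sizes and numerical choices

Study-scale runs use n = 2000 genes on 8 chromosomes (≈ 500 test genes
per fold), chosen as the size at which the noise-ceiling and
model-comparison claims stabilise while the whole suite trains dozens of
models comfortably on one CPU. The analysis scripts use n = 400 for a
fast worked example. Bootstrap calibration uses 200 replicates at
n_boot = 500 over a 600-region universe (decile size 60 keeps the
discrete p fine-grained); confirmatory enrichment uses n_boot = 10 000.
Dropout RNGs, batch shuffles, and all generator stages derive from
explicit seed sequences; attention logits are max-subtracted before
softmax; masked scores use −1e30 rather than −inf to avoid NaNs in fully
masked rows (which cannot occur here, as promoter tokens are always
valid).

## Known limitations

- The generator's additive, single-peak-per-element architecture is far
  simpler than real chromatin; transfer of the reported numbers to real
  data is explicitly out of scope.
- The distal model is a compact realisation of the three-resolution
  attention contract, not a replication of any published architecture's
  internals; absolute r values should be compared only within this
  package.
- The repressive-mark coupling inverts amplitude against expression
  rather than modelling silencing; it reproduces the active/repressive
  asymmetry qualitatively only.
- Perturbing one mark cannot model knock-on changes to other marks'
  occupancy; assays therefore use single-mark models only, and joint
  multi-mark perturbation is intentionally unsupported.
- The fragment perturbation rule assumes fragments aligned to the window
  grid (true for generated data); partially overlapping external
  fragments are perturbed whole.
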