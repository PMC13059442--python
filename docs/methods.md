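# Methods

## Ψ quantification from exon chains

A read chain is the ordered list of exon intervals one cDNA molecule
covers. For a cassette exon `[s, e)` on a gene, chains are classified:

* `X_in` — the chain contains an interval exactly equal to `[s, e)` (both
  splice sites used). Chains are assumed splice-site-corrected upstream, so
  boundary matching is exact, with no fuzz window.
* `X_out` — the chain overlaps the gene, has no interval overlapping the
  exon, and aligns ≥50 bases strictly on each genomic side of it. The
  50-base requirement keeps spurious terminal fragments from counting as
  skipping evidence.
* `X_accIn` / `X_donIn` — the chain's terminal interval (in transcription
  direction) starts exactly at the acceptor (resp. ends at the donor) but
  stops inside the exon, with a spliced junction behind it: truncated
  molecules that witness one splice site only.
* `X_tot` — the chain's genomic span (first start to last end) overlaps the
  exon interval. Span overlap, rather than base-level overlap, is used so
  that skipping molecules — which by construction cover no exonic base —
  still count toward the locus's support. This makes `X_tot` a superset of
  the other four classes and is the count the ≥10-molecule reporting rule
  is applied to.

Counts are computed per (exon, individual, cell type), divided by the
individual's total read count, and summed to pseudo-bulk per cell type; the
Ψ ratios are scale-free, so normalization only reweights individuals.
The minimum-support rule uses the *raw* (un-normalized) molecule count.
The three Ψ forms are the ratios given in the README; zero denominators and
under-supported exons yield missing values.

The 0.02–0.98 retention band is evaluated on the joint pseudo-bulk over
both cell types (an assumption; applying it per cell type would couple the
filter to cell-type depth imbalances). Intron-retention-like candidates —
non-annotated intervals sharing one or two annotated splice sites with ≥70
non-exonic bases — are excluded before Ψ is computed.

Variability: ΔΨ is oriented glia − neuron throughout. `variable` means
|ΔΨ| > 0.25 (strict), `var0.1` means |ΔΨ| > 0.1; an exon with missing Ψ in
either cell type is `unmeasured`. Training-set downsampling removes a
seeded random subset of the {Ψ_neur > 0.9, Ψ_glia > 0.9, |ΔΨ| < 0.03}
class down to 5,000 exons (an alternative predicate, Ψ = 1 in both,
is selectable for data where inclusion saturates); the subsampling RNG is
independent of the read-simulation RNG.

Exon-pair coordination is tested on molecules whose span covers both exon
loci: each is called included (exact interval) or skipped (no overlap),
partial overlaps are discarded, and the 2×2 table goes to a two-sided
Fisher exact test.

## Positional features and binding profiles

Peaks are union-merged per RBP across replicates/cell lines (bookended
intervals merge). The six positional categories are defined by containment
and boundary-crossing, which makes them mutually exclusive without a
precedence rule: *spanning* contains the exon; *acc/don overlap* cross one
boundary without containing it; *exonic* lies inside; *upstream/downstream*
are fully intronic with the near edge within 400 bp of the splice site
(transcription-oriented, so "upstream" is 5′ of the acceptor on either
strand). A peak extending beyond the 400 bp flank still counts if it enters
the window without touching the exon. Flipping an exon's strand exactly
swaps upstream↔downstream and acceptor↔donor counts.

Binding profiles are presence/absence fractions over 400 single-base
upstream flank positions + 50 equal exon-body bins + 400 downstream
positions (850 total, transcript orientation; position −1 is the last
intronic base before the acceptor). Only exons ≥50 bp with at least one
binding site of any RBP contribute. Divergence between variable and
non-variable exons is the MSE between their profiles, computed per RBP
separately for high-Ψ (≥0.5) and low-Ψ strata — four comparisons per RBP,
two per cell type — and the neuron-vs-glia MSE distributions are compared
with a two-sided paired Wilcoxon signed-rank test over (RBP, stratum)
pairs.

## The logistic splicing-code model

One affine map plus sigmoid over the positional count matrix; the loss is
binary cross-entropy with *continuous* targets (Ψ itself) plus an
elastic-net penalty (α = 0.001, L1 ratio = 0.7) on the weights only, scaled
per sample. Optimization is minibatch SGD (learning rate 0.005, batch 256)
with a proximal soft-threshold step for the L1 term, so coefficients reach
exact zeros and the sparsity path is monotone in α. Stopping: up to 200
epochs with early stopping on a 10% validation split (patience 10, best
weights restored). One independent model per cell type. Exons with no
binding site for any RBP are excluded from training and from all test sets.

Interpretation averages coefficients over 10 folds × 5 runs (50 models);
cross-model comparisons keep features supported by ≥50 exons with
|coefficient| ≥ 0.05 in at least one model and rank by absolute
coefficient difference (top 10 reported).

## The sequence model

Input: a window (default 6,144 bp; the desk preset used by the test suite
is 512 bp) with the exon of interest centered — window position
`window//2` sits at `floor((start+end)/2)` — read in transcription
orientation, zero-padded past chromosome ends. Channels: 4 one-hot
nucleotide channels; optionally a splice-site channel with exactly two set
positions (exon start index and end index); optionally one presence channel
per RBP marking merged-peak coverage. Channel ablations ({seq},
{seq, splice}, {seq, splice, rbp}, {rbp}) are a config flag.

Trunk: `n_conv_blocks` blocks of same-padded 1-D convolution → ReLU → 2×
max pool, then a GRU scanning the downsampled positions. The dense head
(per dataset, enabling multi-head training with a shared trunk) reads the
concatenation of (a) the position-wise maximum of the final conv-block
activations and (b) the positional mean of the GRU hidden states, and ends
in a sigmoid. The max path gives sharp credit assignment for local motifs
anywhere in the window — with a final-hidden-only recurrent readout the
desk-scale model memorized training windows without discovering planted
motifs — while the GRU path carries longer-range, order-sensitive
structure.

Training: Adam (learning rate 3e-3 in the desk preset) on continuous-target
BCE, weight decay 1e-4–3e-4 on weight matrices only, early stopping on a
10% validation split with a generous patience (15 in the desk preset —
generalization on motif tasks emerges after an initial memorization
plateau, and stopping early inside that plateau freezes an uninformative
model). Per fold, several independently seeded replicate runs are trained
and their predictions averaged (the evaluation contract is 5; the test
suite uses 2 to stay within minutes). All tensors are float32; predictions
are deterministic given weights and independent of batch partitioning.

Desk preset (used by all tests and the reproduction script): window 512,
2 conv blocks of width 9 with 40 filters, GRU hidden 24, batch 64, 30
epochs. The full-scale default (6,144 bp, 6 blocks, 64 filters, hidden 64)
is configurable but not exercised by the suite.

## ISM and variant effects

ISM substitutes each of the four nucleotides at every window position,
predicts (averaging replicates first), and subtracts the per-position mean
of the four predictions, so scores sum to zero per position exactly; only
the nucleotide channels are mutated, splice-site and RBP channels stay
fixed. Mutant batches are evaluated in position chunks; results are
independent of the chunking. Aggregate profiles rescale each exon's body
(default 300 bins) and flanks per exon before averaging |ISM|. Neighboring
exons are scored by the maximum |ISM| inside the exon ±150 bp, ranked to
select candidates for the coordination test. Score export writes one-hots
and ISM arrays as an `.npz` bundle plus per-exon TSVs, with the ≥25-sequence
strand-consistency threshold recorded as metadata for downstream motif
discovery.

Variant effects: per intron, only the lowest-p variants are scored; the
intron must span a measured exon and the variant must lie inside the exon's
window. ΔISM(alt−ref) is the difference of run-averaged predictions with
the alternative vs the reference allele substituted (averaging before
differencing; identical in expectation to the reverse order). Alleles are
plus-strand and complemented for minus-strand windows; a reference
mismatch is an error, not a warning. |ΔISM| > 0.005 defines an effect;
expected sign is opposite the intron-excision slope; for exons with several
effect-carrying variants the largest |ΔISM| is the prioritized call.
Multi-allelic rows are split to biallelic before scoring.

## Cross-validation and metrics

Folds partition gene groups — connected components of gene identity plus
an optional homolog map — greedily, largest group first onto the currently
smallest fold, deterministically under a seed (the balancing scheme is an
implementation choice). Exons of one gene, and homologous genes, never
straddle train and test. The headline metric is the per-fold Spearman
correlation and its median across folds; constant vectors or folds with <3
pairs report missing. Subgroup MSE uses exon-length groups (≤27, 28–100,
101–200, >200 bp), frame consistency (length divisible by 3), intron-length
groups (<101, 101–1000, >1000 bp) and the number of exons in the window;
empty groups report missing, not zero.

## The synthetic-data generator

The generator emulates the *input* side of a long-read splicing study with
a planted ground truth, not a sequencing simulator. One gene per
chromosome; each gene has one cassette exon between constitutive flanks
(≥80 bp), canonical GT/AG intron dinucleotides on the coding strand, 50%
of genes on the minus strand to force strand-aware code paths. Cassette
lengths mix microexons (≤27 bp, ~12%) with a 28–240 bp body so the
length/frame subgroup analyses are exercisable; intron lengths span the
three subgroup bands.

The grammar assigns each RBP one active positional category and a signed
logit weight; a chosen number of RBPs get opposite signs in the two cell
types (emulating QKI-like cell-specific regulators). Peaks are placed per
exon × RBP with a configurable rate at the active category's geometry;
the RBP's hexamer motif is written into the genome at each peak center (in
transcript orientation), so peak-based and sequence-based models see the
same planted signal. True inclusion is
`psi = sigmoid(baseline + Σ placed-peak effects)`, optionally plus
per-exon logit noise per cell type — setting a cell type's effects to zero
while giving it noise models splicing decoupled from the measured binding
sites. Reads are Binomial(depth, psi) inclusion draws; 5% of inclusion
molecules (a free parameter; truncation rates are not identified by
anything the generator targets) are truncated to acceptor-only or
donor-only support. Variants are placed inside planted motif instances
(slope sign consistent with the planted effect: disrupting an enhancer ⇒
ΔISM < 0 ⇒ positive slope) or in intronic sequence ≥60 bp from any peak
with random-sign slopes.

What the generator does *not* model: sequencing error, barcodes/UMIs,
alignment artifacts, correlated peak placement between RBPs, expression
differences between genes, and any real splicing biology beyond the
planted grammar. Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct and sensitive at realistic
problem sizes — not that real brain data would yield the same accuracy.

## Benchmark problem sizes

The predefined studies (`splicecode.studies`) fix the problem sizes used
by the test suite and the reproduction script: the logistic benchmark uses
5,000 exons × 122 RBPs (placement rate 0.25, cell-specific effects in 4
RBPs); the sequence benchmark uses 4,800 exons (4,000 train) with one
strong motif (+3 logit, baseline −1.5) 20 bp downstream of the donor and
two replicate fits; Ψ recovery uses 10⁴ molecules per cell type; the
divergence benchmark uses 900 exons × 40 RBPs with neuronal logit noise
σ = 2. These sizes were chosen so each study completes in minutes on a
single CPU while leaving clear statistical margins.

## Known limitations

* The sequence model's full-scale configuration mirrors published hybrid
  conv/recurrent trunks in spirit but its exact layer sizes are this
  package's own defaults, not a claimed replication of any published
  architecture.
* ISM cost scales as 4 × window × replicates forward passes per exon;
  at the 6,144 bp window this is expensive, and the exon list should be
  restricted accordingly.
* The logistic model's per-sample penalty scaling means α is not directly
  comparable to implementations that scale the penalty by dataset size.
* Ψ confidence is not modelled (no binomial CI on Ψ); the ≥10-molecule
  rule is the only support filter, as in the quantification contract.
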