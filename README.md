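# splicecode

Cell-type-specific exon inclusion from long reads: quantify percent
spliced-in (Ψ), learn the positional RBP splicing code, interpret it, and
prioritize variant effects.

## The problem

Long-read single-cell/single-nucleus RNA sequencing reports, molecule by
molecule, whether a cassette exon was included or skipped — separately for
neurons, glia, or any other cell type. That makes it possible to ask *why*
an exon is included in one cell type and skipped in another: which
RNA-binding proteins (RBPs), bound at which positions around the exon,
drive the difference, and what a regulatory variant will do to inclusion.

`splicecode` implements that analysis as a tested pipeline:

1. **Ψ quantification** (`psi_quant`). From each molecule's exon chain the
   five read classes per exon are counted — inclusion with both splice
   sites (`X_in`), same-gene skipping with ≥50 aligned bases on each side
   (`X_out`), acceptor-only and donor-only truncated support (`X_accIn`,
   `X_donIn`), and locus coverage (`X_tot`) — and combined as

   Ψ_overall = (X_in + X_accIn + X_donIn) / (X_in + X_accIn + X_donIn + X_out)

   with analogous acceptor/donor forms, on depth-normalized pseudo-bulk
   counts, reported only where ≥10 molecules cover the locus. Exons are
   filtered to 0.02 ≤ Ψ ≤ 0.98, labelled *variable* when
   |ΔΨ<sub>glia−neur</sub>| > 0.25, and the heavily skewed
   {Ψ > 0.9 in both cell types, |ΔΨ| < 0.03} class is downsampled to
   5,000 for model training.
2. **Positional binding features** (`rbp_features`). eCLIP-style peaks are
   merged per RBP and counted in six strand-aware categories per exon —
   upstream flank (≤400 bp), 3′-splice-site overlap, exonic, exon-spanning,
   5′-splice-site overlap, downstream flank — giving 6 features per RBP
   (732 for 122 RBPs). Metagene binding profiles (400 flank positions + 50
   exon-body bins + 400) and their variable-vs-non-variable divergence
   (MSE, paired Wilcoxon across RBPs) quantify how far a cell type's
   splicing deviates from the shared code.
3. **Models** (`lr_model`, `seq_model`). An elastic-net logistic model
   (α = 0.001, L1 ratio = 0.7, continuous-target binary cross-entropy)
   predicts Ψ from the positional feature counts, one model per cell type;
   a convolutional + recurrent network predicts Ψ from a 6,144 bp sequence
   window centered on the exon (4 one-hot channels, optional splice-site
   and per-RBP channels, optional per-dataset output heads).
4. **Interpretation** (`interpretation`, `sqtl_effects`). Coefficients are
   averaged over 10 folds × 5 runs and compared across cell types; in-silico
   saturation mutagenesis (ISM) scores every substitution as
   ISM<sub>e,p,n</sub> = Ψ̂<sub>p→n</sub> − ¼ Σ<sub>i</sub> Ψ̂<sub>p→i</sub>;
   splicing-QTL variants are scored by ΔISM(alt−ref), called effect-carrying
   at |ΔISM| > 0.005, and checked for sign concordance with the
   intron-excision slope (negative slope ⇔ ΔISM > 0).
5. **Evaluation** (`cv_eval`). Gene-grouped (and optionally
   homolog-grouped) 10-fold cross-validation, per-fold Spearman correlation
   with the cross-fold median as the headline metric, and subgroup MSE by
   exon length (≤27 / 28–100 / 101–200 / >200 bp), frame consistency,
   intron length and exon density.

Because the real datasets are external, the package ships a first-class
synthetic-data generator (`synthetic_data`): genomes, peak tracks, read
chains and variants whose statistics follow a *planted* position-dependent
grammar — every downstream stage is validated against known ground truth,
including grammar-sign recovery, ISM motif localization and variant-effect
sign concordance.

## Worked example

```bash
splicecode simulate --genes 40 --rbps 10 --depth 150 --individuals 2 --seed 5 --out demo
splicecode psi      --reads demo/reads.tsv --annotation demo/annotation.tsv --out demo/psi.tsv
splicecode features --beds demo/peaks --annotation demo/annotation.tsv --out demo/fm.tsv
splicecode train-lr --features demo/fm.tsv --psi demo/psi.tsv --cell-type glia \
                    --train-set all --seed 0 --out demo/coefs.tsv
```

prints

```
wrote synthetic dataset (40 genes, 10 RBPs) to demo
wrote PSI table for 40 exons to demo/psi.tsv
wrote 40 x 60 feature matrix to demo/fm.tsv
median held-out Spearman: 0.800 over 40 exons
wrote averaged coefficients to demo/coefs.tsv
```

`demo/psi.tsv` holds per-exon Ψ for both cell types with the variability
call — e.g. exon `g0000_e1` has Ψ_glia = 0.433, Ψ_neur = 0.123, ΔΨ = 0.31,
hence `variable`. The held-out Spearman of 0.80 says the logistic model
ranks unseen exons' inclusion well from binding positions alone. The
largest averaged coefficients recover the planted grammar's signs: the
generator gave `RBP000` an exonic enhancer effect (+0.63 on the inclusion
logit) and `RBP007` an upstream enhancer (+1.08), and the model's top
coefficients are `RBP000:exonic` = +0.053 and `RBP007:upstream` = +0.052 —
shrunk by the elastic-net penalty but sign-correct.

The Python API exposes the full pipeline (sequence models, ISM, sQTL
scoring); see `splicecode.studies` for ready-made benchmark designs and
`docs/methods.md` for the model details.

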