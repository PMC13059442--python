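"""Predefined desk-scale simulation studies.

Each function wires the synthetic-data generator into one reproducible
study design used by the evaluation suite and the reproduction script:

* ``single_motif_study`` — inclusion driven by one strong hexamer planted
  20 bp downstream of the donor; the benchmark for sequence-model grammar
  recovery, ISM localization and variant-effect prediction.
* ``lr_grammar_study`` — a full 122-RBP, 6-category positional grammar
  read out through peak features; the benchmark for the logistic model.
* ``decoupled_neuron_study`` — glial inclusion follows the planted peaks
  while neuronal inclusion is random on the logit scale; the benchmark for
  the binding-profile divergence direction.

Problem sizes are chosen so each study runs in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import psi_quant, rbp_features, seq_model
from . import synthetic_data as sd


@dataclasses.dataclass
class SingleMotifStudy:
    dataset: sd.SimulatedDataset
    config: seq_model.SeqModelConfig
    windows: list  # InputWindow per exon, same order as dataset.exons
    X: np.ndarray
    y: np.ndarray  # true glial PSI
    n_train: int

    @property
    def train(self):
        return self.X[: self.n_train], self.y[: self.n_train]

    @property
    def test(self):
        return self.X[self.n_train :], self.y[self.n_train :]


def single_motif_study(
    seed: int = 0,
    n_genes: int = 4800,
    train_fraction: float = 5 / 6,
    effect: float = 3.0,
    baseline: float = -1.5,
    n_planted_variants: int = 25,
    n_neutral_variants: int = 25,
) -> SingleMotifStudy:
    """Exon inclusion depends on one strong motif 20 bp past the donor.

    The planted effect (+3 on the logit, baseline -1.5) separates carrier
    exons (PSI 0.82) from non-carriers (PSI 0.18); half the exons carry the
    motif.  Targets are the true inclusion rates, so recovery failures are
    attributable to the model rather than read sampling.
    """
    grammar = sd.plant_grammar(["MOTIF1"], 0, seed=5)
    grammar.rbp_effects = {
        ("MOTIF1", "downstream", ct): effect for ct in sd.CELL_TYPES
    }
    grammar.baseline_logit = {ct: baseline for ct in sd.CELL_TYPES}
    ds = sd.simulate(
        n_genes=n_genes,
        grammar=grammar,
        rbp_names=["MOTIF1"],
        placement_rate=0.5,
        depth=0,
        n_individuals=0,
        seed=seed,
        flank_offset=20,
        n_planted_variants=n_planted_variants,
        n_neutral_variants=n_neutral_variants,
    )
    config = seq_model.desk_config()
    windows = [seq_model.build_input(ds.genome, e, config) for e in ds.exons]
    X = seq_model.stack_windows(windows)
    y = np.array([e.true_psi["glia"] for e in ds.exons])
    return SingleMotifStudy(
        dataset=ds,
        config=config,
        windows=windows,
        X=X,
        y=y,
        n_train=int(len(ds.exons) * train_fraction),
    )


def motif_occurrences(study: SingleMotifStudy, window) -> list:
    """Window positions (transcript orientation) of the planted hexamer."""
    from . import _seqs

    motif = study.dataset.grammar.motif_map["MOTIF1"]
    s = _seqs.decode(window.codes)
    k = len(motif)
    return [i for i in range(len(s) - k + 1) if s[i : i + k] == motif]


def lr_grammar_study(
    seed: int = 0, n_genes: int = 5000, n_rbps: int = 122, n_cell_specific: int = 4
):
    """Positional-grammar benchmark for the elastic-net logistic model.

    Returns (dataset, feature matrix, glial targets restricted to exons
    with >=1 binding site).
    """
    rbps = [f"RBP{i:03d}" for i in range(n_rbps)]
    ds = sd.simulate(
        n_genes=n_genes,
        rbp_names=rbps,
        n_cell_specific=n_cell_specific,
        placement_rate=0.25,
        depth=0,
        n_individuals=0,
        seed=seed,
    )
    peaksets = rbp_features.peaksets_from_intervals(ds.peaksets)
    fm = rbp_features.build_feature_matrix(ds.exons, peaksets)
    y = pd.Series({e.exon_id: e.true_psi["glia"] for e in ds.exons})
    nonzero = ~rbp_features.zero_feature_mask(fm)
    y = y.loc[fm.index[nonzero]]
    return ds, fm, y


def decoupled_neuron_study(seed: int = 0, n_genes: int = 900, n_rbps: int = 40):
    """Glia follow the planted peak grammar; neuron logits are pure noise.

    Returns (dataset, merged peaksets, measured wide PSI table).  Used to
    check that binding profiles of variable exons diverge more from the
    non-variable profiles in the decoupled cell type.
    """
    rbps = [f"RBP{i:03d}" for i in range(n_rbps)]
    grammar = sd.plant_grammar(rbps, 0, seed=seed + 1, min_effect=0.8, max_effect=2.0)
    grammar.rbp_effects = {
        k: (0.0 if k[2] == "neuron" else w) for k, w in grammar.rbp_effects.items()
    }
    ds = sd.simulate(
        n_genes=n_genes,
        rbp_names=rbps,
        grammar=grammar,
        placement_rate=0.35,
        depth=100,
        n_individuals=2,
        seed=seed,
        logit_noise_sd={"neuron": 2.0},
    )
    wide = psi_quant.quantify(ds.reads, ds.exons, ds.annotation)
    peaksets = rbp_features.peaksets_from_intervals(ds.peaksets)
    return ds, peaksets, wide
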