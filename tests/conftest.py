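import pytest

from splicecode import psi_quant, rbp_features, seq_model, studies
from splicecode import synthetic_data as sd


@pytest.fixture(scope="session")
def small_ds():
    """Small end-to-end dataset: 30 genes, 8 RBPs, reads and variants."""
    return sd.simulate(
        n_genes=30,
        n_rbps=8,
        n_cell_specific=2,
        placement_rate=0.4,
        depth=150,
        n_individuals=2,
        seed=3,
        n_planted_variants=6,
        n_neutral_variants=6,
    )


@pytest.fixture(scope="session")
def small_wide(small_ds):
    return psi_quant.quantify(small_ds.reads, small_ds.exons, small_ds.annotation)


@pytest.fixture(scope="session")
def small_peaksets(small_ds):
    return rbp_features.peaksets_from_intervals(small_ds.peaksets)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Few-parameter model over the full 512 bp desk window (fast forward)."""
    return seq_model.SeqModelConfig(
        window=512, n_conv_blocks=2, n_filters=8, hidden=6, channels=("seq", "splice")
    )


@pytest.fixture(scope="session")
def seq_study():
    """Single-strong-motif grammar study (sequence-model benchmark)."""
    return studies.single_motif_study(seed=7)


@pytest.fixture(scope="session")
def seq_replicates(seq_study):
    """Two independently seeded desk-model fits on the study's training split."""
    Xtr, ytr = seq_study.train
    return seq_model.train_replicates(Xtr, ytr, seq_study.config, seed=1, n_runs=2)
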