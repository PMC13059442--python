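"""Generator contracts: determinism, geometry, planted-grammar bookkeeping."""

import io

import numpy as np
import pandas as pd
import pytest

from splicecode import _seqs, rbp_features
from splicecode import synthetic_data as sd


def _fasta_text(genome):
    buf = io.StringIO()

    class _W:
        write = buf.write

    for chrom in sorted(genome):
        buf.write(f">{chrom}\n" + _seqs.decode(genome[chrom]) + "\n")
    return buf.getvalue()


class TestGenGenome:
    def test_minimal_gene_has_one_cassette(self):
        genome, ann = sd.gen_genome(1, 3, seed=0)
        assert (ann["role"] == "cassette").sum() == 1
        assert len(sd.cassette_exons(genome, ann)) == 1

    def test_same_seed_is_byte_identical(self):
        g1, a1 = sd.gen_genome(5, 3, seed=42)
        g2, a2 = sd.gen_genome(5, 3, seed=42)
        assert _fasta_text(g1) == _fasta_text(g2)
        pd.testing.assert_frame_equal(a1, a2)

    def test_fifty_genes_distinct_and_inside_bounds(self):
        genome, ann = sd.gen_genome(50, 3, seed=1)
        assert ann["gene_id"].nunique() == 50
        for chrom, sub in ann.groupby("chrom"):
            assert sub["start"].min() >= 0
            assert sub["end"].max() <= len(genome[chrom])
            cass = sub[sub["role"] == "cassette"]
            assert sub["start"].min() < cass["start"].iloc[0]
            assert cass["end"].iloc[0] < sub["end"].max()

    def test_canonical_splice_dinucleotides_on_coding_strand(self):
        genome, ann = sd.gen_genome(20, 3, seed=2)
        for chrom, sub in ann.groupby("chrom"):
            seq = genome[chrom]
            strand = sub["strand"].iloc[0]
            if strand == "-":
                seq = _seqs.revcomp(seq)
                L = len(seq)
                sub = sub.assign(start=L - sub["end"], end=L - sub["start"])
            sub = sub.sort_values("start")
            ends = sub["end"].to_list()[:-1]
            starts = sub["start"].to_list()[1:]
            for don, acc in zip(ends, starts):
                assert _seqs.decode(seq[don : don + 2]) == "GT"
                assert _seqs.decode(seq[acc - 2 : acc]) == "AG"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            sd.gen_genome(0, 3)
        with pytest.raises(ValueError, match="exons_per_gene"):
            sd.gen_genome(1, 2)


class TestPlantGrammar:
    def test_no_cell_specific_gives_identical_tables(self):
        g = sd.plant_grammar([f"R{i}" for i in range(10)], 0, seed=0)
        tab = sd.effect_table(g, [f"R{i}" for i in range(10)])
        glia = tab[tab.cell_type == "glia"].set_index(["rbp", "category"])["effect"]
        neur = tab[tab.cell_type == "neuron"].set_index(["rbp", "category"])["effect"]
        assert (glia == neur).all()

    def test_122_rbps_cover_full_effect_table(self):
        names = [f"R{i}" for i in range(122)]
        tab = sd.effect_table(sd.plant_grammar(names, 3, seed=1), names)
        assert len(tab) == 122 * 6 * 2

    def test_cell_specific_rbps_flip_sign(self):
        names = [f"R{i}" for i in range(12)]
        g = sd.plant_grammar(names, 4, seed=2)
        assert len(g.cell_specific) == 4
        for rbp in g.cell_specific:
            cats = g.active_categories(rbp)
            assert any(
                g.effect(rbp, c, "glia") == -g.effect(rbp, c, "neuron") != 0 for c in cats
            )

    def test_opposite_sign_weights_storable(self):
        # a QKI-like configuration: repressive at the acceptor in glia,
        # activating in neurons
        g = sd.plant_grammar(["QKI"], 1, seed=0)
        g.rbp_effects[("QKI", "acc_overlap", "glia")] = -0.15
        g.rbp_effects[("QKI", "acc_overlap", "neuron")] = 0.12
        assert g.effect("QKI", "acc_overlap", "glia") == -0.15
        assert g.effect("QKI", "acc_overlap", "neuron") == 0.12

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sd.plant_grammar(["A", "A"], 0)


class TestGenPeaks:
    def test_rate_one_single_category_every_exon_has_one_peak(self):
        genome, ann = sd.gen_genome(20, 3, seed=3)
        exons = sd.cassette_exons(genome, ann)
        g = sd.plant_grammar(["R0"], 0, seed=0)
        g.rbp_effects = {("R0", "downstream", ct): 1.0 for ct in sd.CELL_TYPES}
        placements, _ = sd.gen_peaks(exons, g, placement_rate=1.0, seed=0)
        counts = placements.groupby("exon_id").size()
        assert (counts == 1).all() and len(counts) == len(exons)
        assert set(placements["category"]) == {"downstream"}

    def test_placement_count_within_binomial_band(self):
        genome, ann = sd.gen_genome(1000, 3, seed=4)
        exons = sd.cassette_exons(genome, ann)
        g = sd.plant_grammar(["R0"], 0, seed=0)
        placements, _ = sd.gen_peaks(exons, g, placement_rate=0.5, seed=1)
        # 99% central interval of Binomial(1000, 0.5)
        assert 459 <= len(placements) <= 541

    def test_round_trip_categories(self, small_ds):
        for _, p in small_ds.placements.iterrows():
            exon = small_ds.exon_by_id(p["exon_id"])
            assert rbp_features.assign_category((p["start"], p["end"]), exon) == p["category"]

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="placement_rate"):
            sd.gen_peaks([], sd.plant_grammar(["R0"], 0), placement_rate=0.0)


class TestGenReads:
    def _one_exon(self, psi, seed=0):
        genome, ann = sd.gen_genome(1, 3, seed=seed)
        exons = sd.cassette_exons(genome, ann)
        exons[0].true_psi = {ct: psi for ct in sd.CELL_TYPES}
        return exons

    def test_psi_one_every_chain_includes_exon(self):
        exons = self._one_exon(1.0)
        reads = sd.gen_reads(
            exons, {("i0", "glia"): 200}, seed=0, truncated_fraction=0.0
        )
        exon_str = f"{exons[0].start}-{exons[0].end}"
        assert len(reads) == 200
        assert reads["exons"].str.contains(exon_str).all()

    def test_zero_depth_emits_no_rows(self):
        exons = self._one_exon(0.5)
        reads = sd.gen_reads(
            exons, {("i0", "glia"): 100, ("i1", "glia"): 0}, seed=0
        )
        assert "i1" not in set(reads["individual"])

    def test_inclusion_fraction_concentrates(self):
        exons = self._one_exon(0.5)
        reads = sd.gen_reads(exons, {("i0", "glia"): 10000}, seed=1, truncated_fraction=0.0)
        exon_str = f"{exons[0].start}-{exons[0].end}"
        frac = reads["exons"].str.contains(exon_str).mean()
        assert abs(frac - 0.5) < 0.02

    def test_same_seed_identical(self):
        exons = self._one_exon(0.5)
        r1 = sd.gen_reads(exons, {("i0", "glia"): 50}, seed=9)
        r2 = sd.gen_reads(exons, {("i0", "glia"): 50}, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_negative_depth_rejected(self):
        exons = self._one_exon(0.5)
        with pytest.raises(ValueError, match="depths"):
            sd.gen_reads(exons, {("i0", "glia"): -1})


class TestGenVariants:
    def test_labels_and_allele_sanity(self, small_ds):
        v = small_ds.variants
        assert (v["ref"] != v["alt"]).all()
        assert set(v["label"]) == {"planted", "neutral"}
        assert (v[v.label == "planted"]["expected_dism_sign"] != 0).all()
        assert (v[v.label == "neutral"]["expected_dism_sign"] == 0).all()

    def test_sign_logic_disrupting_positive_effect(self, small_ds):
        # slope sign must oppose the expected dISM sign: disrupting an
        # inclusion-enhancing motif lowers PSI (dISM < 0) and excises the
        # intron more (slope > 0)
        v = small_ds.variants
        planted = v[v.label == "planted"]
        assert (np.sign(planted["slope"]) == -planted["expected_dism_sign"]).all()

    def test_ref_base_matches_genome(self, small_ds):
        for _, row in small_ds.variants.iterrows():
            base = _seqs.BASES[small_ds.genome[row["chrom"]][row["pos"] - 1]]
            assert base == row["ref"]


def test_true_psi_matches_planted_logit(small_ds):
    g = small_ds.grammar
    by_exon = small_ds.placements.groupby("exon_id")
    for exon in small_ds.exons:
        for ct in sd.CELL_TYPES:
            logit = g.baseline_logit[ct]
            if exon.exon_id in by_exon.groups:
                for _, p in by_exon.get_group(exon.exon_id).iterrows():
                    logit += g.effect(p["rbp"], p["category"], ct)
            assert exon.true_psi[ct] == pytest.approx(1 / (1 + np.exp(-logit)))


def test_annotation_round_trip(tmp_path, small_ds):
    path = tmp_path / "ann.tsv"
    sd.write_annotation(small_ds.annotation, path)
    back = sd.read_annotation(path)
    pd.testing.assert_frame_equal(back, small_ds.annotation)
    # written form is 1-based closed
    raw = pd.read_csv(path, sep="\t")
    assert (raw["start"] == small_ds.annotation["start"] + 1).all()


def test_fasta_round_trip(tmp_path, small_ds):
    path = tmp_path / "genome.fa"
    sd.write_fasta(small_ds.genome, path)
    back = sd.read_fasta(path)
    assert set(back) == set(small_ds.genome)
    for chrom in back:
        assert np.array_equal(back[chrom], small_ds.genome[chrom])
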