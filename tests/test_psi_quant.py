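"""Read-chain classification, the three PSI formulas, filters and the
coordination test."""

import numpy as np
import pandas as pd
import pytest

from splicecode import psi_quant as pq
from splicecode import synthetic_data as sd


def _reads(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "individual", "cell_type", "chrom", "strand", "exons"]
    )


@pytest.fixture()
def plus_gene():
    """One plus-strand gene: exons [100,200) [500,600) [900,1000)."""
    ann = pd.DataFrame(
        {
            "exon_id": ["g_e0", "g_e1", "g_e2"],
            "gene_id": ["g"] * 3,
            "chrom": ["chr1"] * 3,
            "strand": ["+"] * 3,
            "start": [100, 500, 900],
            "end": [200, 600, 1000],
            "exon_idx": [0, 1, 2],
            "role": ["constitutive", "cassette", "constitutive"],
        }
    )
    exon = sd.SyntheticExon("g_e1", "g", "chr1", "+", 500, 600, (100, 200), (900, 1000))
    return ann, exon


class TestCountExonReads:
    def test_full_inclusion_chain(self, plus_gene):
        ann, exon = plus_gene
        reads = _reads([["r0", "i0", "glia", "chr1", "+", "100-200;500-600;900-1000"]])
        c = pq.count_exon_reads(reads, exon, ann).iloc[0]
        assert (c["x_in"], c["x_out"], c["x_tot"]) == (1, 0, 1)

    def test_skip_needs_50_bases_each_side(self, plus_gene):
        ann, exon = plus_gene
        reads = _reads(
            [
                # 100 bases left, only 40 right: not a countable skip
                ["r0", "i0", "glia", "chr1", "+", "100-200;900-940"],
                # 100 bases each side: countable skip
                ["r1", "i0", "glia", "chr1", "+", "100-200;900-1000"],
                # exactly 50 on each side: countable (inclusive)
                ["r2", "i0", "glia", "chr1", "+", "150-200;900-950"],
            ]
        )
        c = pq.count_exon_reads(reads, exon, ann).iloc[0]
        assert c["x_out"] == 2
        assert c["x_tot"] == 3  # all spans cover the locus

    def test_acceptor_support_ends_on_exon(self, plus_gene):
        ann, exon = plus_gene
        reads = _reads(
            [
                ["r0", "i0", "glia", "chr1", "+", "100-200;500-550"],  # acc support
                ["r1", "i0", "glia", "chr1", "+", "560-600;900-1000"],  # don support
            ]
        )
        c = pq.count_exon_reads(reads, exon, ann).iloc[0]
        assert (c["x_acc_in"], c["x_don_in"], c["x_in"]) == (1, 1, 0)

    def test_minus_strand_acceptor_is_at_genomic_end(self):
        ann = pd.DataFrame(
            {
                "exon_id": ["g_e0", "g_e1", "g_e2"],
                "gene_id": ["g"] * 3,
                "chrom": ["chr1"] * 3,
                "strand": ["-"] * 3,
                "start": [900, 500, 100],
                "end": [1000, 600, 200],
                "exon_idx": [0, 1, 2],
                "role": ["constitutive", "cassette", "constitutive"],
            }
        )
        exon = sd.SyntheticExon("g_e1", "g", "chr1", "-", 500, 600, (900, 1000), (100, 200))
        # molecule enters at the acceptor (genomic end 600) and stops mid-exon
        reads = _reads([["r0", "i0", "glia", "chr1", "-", "550-600;900-1000"]])
        c = pq.count_exon_reads(reads, exon, ann).iloc[0]
        assert (c["x_acc_in"], c["x_don_in"]) == (1, 0)

    def test_unknown_exon_errors(self, plus_gene):
        ann, _ = plus_gene
        ghost = sd.SyntheticExon("nope", "g", "chr1", "+", 1, 5, (0, 1), (6, 7))
        with pytest.raises(KeyError):
            pq.count_exon_reads(_reads([]), ghost, ann)

    def test_count_invariants_on_simulated_data(self, small_ds):
        counts = pq.count_all_exons(small_ds.reads, small_ds.exons, small_ds.annotation)
        for col in ["x_in", "x_out", "x_acc_in", "x_don_in"]:
            assert (counts["x_tot"] >= counts[col]).all()
        assert (counts[pq.COUNT_COLS] >= 0).all().all()


class TestExcludeRetentionLike:
    ann = pd.DataFrame(
        {
            "exon_id": ["e0"],
            "gene_id": ["g"],
            "chrom": ["chr1"],
            "strand": ["+"],
            "start": [100],
            "end": [200],
            "exon_idx": [0],
            "role": ["constitutive"],
        }
    )

    def _cand(self, start, end):
        return pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]})

    def test_annotated_exon_kept(self):
        kept = pq.exclude_retention_like(self._cand(100, 200), self.ann)
        assert len(kept) == 1

    def test_novel_one_annotated_site_80_intronic_removed(self):
        # shares the acceptor at 100, extends 80 bases past the donor
        kept = pq.exclude_retention_like(self._cand(100, 280), self.ann)
        assert len(kept) == 0

    def test_novel_with_60_nonexonic_bases_kept(self):
        kept = pq.exclude_retention_like(self._cand(100, 260), self.ann)
        assert len(kept) == 1

    def test_novel_without_annotated_sites_kept(self):
        kept = pq.exclude_retention_like(self._cand(120, 280), self.ann)
        assert len(kept) == 1


class TestNormalizeAndPsi:
    def _counts(self, rows):
        return pd.DataFrame(
            rows,
            columns=["exon_id", "individual", "cell_type", *pq.COUNT_COLS],
        )

    def test_single_individual_normalization_cancels(self):
        counts = self._counts([["e", "i0", "glia", 8, 10, 1, 1, 20]])
        pb = pq.normalize_by_depth(counts, {"i0": 1000})
        psi = pq.compute_psi(pb)
        assert psi["psi_overall"].iloc[0] == pytest.approx(0.5)

    def test_equal_depth_identical_counts_match_either_individual(self):
        counts = self._counts(
            [
                ["e", "i0", "glia", 6, 2, 0, 0, 8],
                ["e", "i1", "glia", 6, 2, 0, 0, 8],
            ]
        )
        pb = pq.normalize_by_depth(counts, {"i0": 500, "i1": 500})
        psi = pq.compute_psi(pb)
        assert psi["psi_overall"].iloc[0] == pytest.approx(0.75)

    def test_discordant_individuals_match_hand_computed_oracle(self):
        # individual A: depth 1e6, 90/10 in/out; individual B: depth 1e4, 1/9
        counts = self._counts(
            [
                ["e", "A", "glia", 90, 10, 0, 0, 100],
                ["e", "B", "glia", 1, 9, 0, 0, 10],
            ]
        )
        pb = pq.normalize_by_depth(counts, {"A": 10**6, "B": 10**4})
        psi = pq.compute_psi(pb)
        # hand-computed: (90/1e6 + 1/1e4) / (100/1e6 + 10/1e4)
        expected = (90 / 1e6 + 1 / 1e4) / (100 / 1e6 + 10 / 1e4)
        assert psi["psi_overall"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_total_individual_dropped(self):
        counts = self._counts(
            [
                ["e", "i0", "glia", 6, 2, 0, 0, 12],
                ["e", "bad", "glia", 1, 1, 0, 0, 2],
            ]
        )
        pb = pq.normalize_by_depth(counts, {"i0": 100, "bad": 0})
        assert pb["raw_tot"].iloc[0] == 12

    def test_three_formulas_direct_substitution(self):
        counts = self._counts([["e", "i0", "glia", 8, 10, 1, 2, 25]])
        psi = pq.compute_psi(pq.normalize_by_depth(counts, {"i0": 100}))
        assert psi["psi_overall"].iloc[0] == pytest.approx((8 + 1 + 2) / (8 + 1 + 2 + 10))
        assert psi["psi_acceptor"].iloc[0] == pytest.approx((8 + 1) / (8 + 1 + 10))
        assert psi["psi_donor"].iloc[0] == pytest.approx((8 + 2) / (8 + 2 + 10))

    def test_no_skipping_reads_gives_psi_one(self):
        counts = self._counts([["e", "i0", "glia", 12, 0, 0, 0, 12]])
        psi = pq.compute_psi(pq.normalize_by_depth(counts, {"i0": 100}))
        assert psi["psi_overall"].iloc[0] == pytest.approx(1.0)

    def test_below_ten_raw_molecules_is_missing(self):
        counts = self._counts([["e", "i0", "glia", 5, 3, 0, 1, 9]])
        psi = pq.compute_psi(pq.normalize_by_depth(counts, {"i0": 100}))
        assert psi[["psi_overall", "psi_acceptor", "psi_donor"]].isna().all().all()


class TestFilterPsiRange:
    def _pb(self, x_in, x_out):
        return pd.DataFrame(
            {
                "exon_id": ["e"] * 2,
                "cell_type": ["glia", "neuron"],
                "x_in_norm": [x_in / 2] * 2,
                "x_out_norm": [x_out / 2] * 2,
                "x_acc_in_norm": [0.0] * 2,
                "x_don_in_norm": [0.0] * 2,
                "raw_tot": [50] * 2,
            }
        )

    def test_mid_range_kept(self):
        assert list(pq.filter_psi_range(self._pb(50, 50))) == ["e"]

    def test_above_098_dropped(self):
        assert list(pq.filter_psi_range(self._pb(99, 1))) == []

    def test_exactly_002_kept_inclusive(self):
        assert list(pq.filter_psi_range(self._pb(2, 98))) == ["e"]


class TestVariability:
    def test_labels(self):
        labels = pq.classify_variability(
            [0.8, 0.60, 0.5, np.nan], [0.4, 0.45, 0.5, 0.5]
        )
        assert list(labels) == ["variable", "var0.1", "non_variable", "unmeasured"]

    def test_quarter_delta_is_not_variable_strict(self):
        # |delta| of exactly 0.25 misses the strict > 0.25 rule (but does
        # exceed the 0.1 threshold)
        assert pq.classify_variability([0.75], [0.5])[0] != "variable"


class TestDownsample:
    def _records(self, n_class, n_other, seed=0):
        rng = np.random.default_rng(seed)
        cls = pd.DataFrame(
            {
                "exon_id": [f"c{i}" for i in range(n_class)],
                "psi_glia": rng.uniform(0.95, 1.0, n_class),
                "psi_neuron": rng.uniform(0.95, 1.0, n_class),
            }
        )
        cls["psi_neuron"] = cls["psi_glia"] + rng.uniform(-0.02, 0.02, n_class)
        other = pd.DataFrame(
            {
                "exon_id": [f"o{i}" for i in range(n_other)],
                "psi_glia": rng.uniform(0.2, 0.7, n_other),
                "psi_neuron": rng.uniform(0.2, 0.7, n_other),
            }
        )
        df = pd.concat([cls, other], ignore_index=True)
        df["delta_psi"] = df["psi_glia"] - df["psi_neuron"]
        return df

    def test_oversized_class_cut_to_target(self):
        df = self._records(6000, 500)
        out = pq.downsample_skewed(df, target=5000, seed=1)
        kept_class = out["exon_id"].str.startswith("c").sum()
        assert kept_class == 5000
        assert out["exon_id"].str.startswith("o").sum() == 500

    def test_small_class_untouched(self):
        df = self._records(4000, 100)
        out = pq.downsample_skewed(df, target=5000, seed=1)
        assert len(out) == len(df)

    def test_same_seed_same_selection(self):
        df = self._records(6000, 0)
        a = pq.downsample_skewed(df, seed=7)
        b = pq.downsample_skewed(df, seed=7)
        assert list(a["exon_id"]) == list(b["exon_id"])

    def test_psi1_mode(self):
        df = pd.DataFrame(
            {
                "exon_id": [f"e{i}" for i in range(20)],
                "psi_glia": [1.0] * 15 + [0.5] * 5,
                "psi_neuron": [1.0] * 15 + [0.5] * 5,
            }
        )
        df["delta_psi"] = 0.0
        out = pq.downsample_skewed(df, target=10, seed=0, mode="psi1")
        assert (out["psi_glia"] == 1.0).sum() == 10


class TestCoordination:
    def _two_exon_reads(self, pattern_counts):
        ex_a, ex_b = (100, 150), (300, 350)
        chains = {
            (1, 1): "0-50;100-150;300-350;500-550",
            (1, 0): "0-50;100-150;500-550",
            (0, 1): "0-50;300-350;500-550",
            (0, 0): "0-50;500-550",
        }
        rows = []
        i = 0
        for key, n in pattern_counts.items():
            for _ in range(n):
                rows.append([f"r{i}", "i0", "glia", "chr1", "+", chains[key]])
                i += 1
        reads = pd.DataFrame(
            rows, columns=["read_id", "individual", "cell_type", "chrom", "strand", "exons"]
        )
        a = sd.SyntheticExon("a", "g", "chr1", "+", *ex_a, (0, 50), (500, 550))
        b = sd.SyntheticExon("b", "g", "chr1", "+", *ex_b, (0, 50), (500, 550))
        return reads, a, b

    def test_perfect_association(self):
        reads, a, b = self._two_exon_reads({(1, 1): 10, (0, 0): 10})
        res = pq.coordination_test(reads, a, b)
        assert res["p_value"] < 0.05
        assert np.isinf(res["odds_ratio"]) or res["odds_ratio"] > 100

    def test_balanced_table_odds_ratio_one(self):
        reads, a, b = self._two_exon_reads({(1, 1): 5, (1, 0): 5, (0, 1): 5, (0, 0): 5})
        res = pq.coordination_test(reads, a, b)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_null_calibration(self):
        # independent inclusion at PSI=0.5: the Fisher test should reject
        # at ~5% over replicates
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 200
            ain = rng.random(n) < 0.5
            bin_ = rng.random(n) < 0.5
            counts = {
                (1, 1): int((ain & bin_).sum()),
                (1, 0): int((ain & ~bin_).sum()),
                (0, 1): int((~ain & bin_).sum()),
                (0, 0): int((~ain & ~bin_).sum()),
            }
            reads, a, b = self._two_exon_reads(counts)
            if pq.coordination_test(reads, a, b)["p_value"] < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.09

    def test_no_spanning_chain_errors(self):
        reads, a, b = self._two_exon_reads({(1, 1): 0})
        with pytest.raises(ValueError, match="span"):
            pq.coordination_test(reads, a, b)


class TestPipelineProperties:
    def test_psi_in_unit_interval_and_accurate(self, small_ds, small_wide):
        vals = small_wide[["psi_glia", "psi_neuron"]].to_numpy()
        vals = vals[~np.isnan(vals)]
        assert ((vals >= 0) & (vals <= 1)).all()
        true = {e.exon_id: e.true_psi for e in small_ds.exons}
        err = [
            abs(r.psi_glia - true[r.exon_id]["glia"])
            for r in small_wide.itertuples()
            if not np.isnan(r.psi_glia)
        ]
        # depth 150 x 2 individuals: binomial sd ~ 0.03
        assert np.median(err) < 0.05

    def test_psi_monotone_in_x_in(self):
        base = dict(x_out=5.0, x_acc=1.0, x_don=1.0)
        prev = -1.0
        for x_in in [0, 1, 5, 20, 100]:
            pb = pd.DataFrame(
                {
                    "exon_id": ["e"],
                    "cell_type": ["glia"],
                    "x_in_norm": [float(x_in)],
                    "x_out_norm": [base["x_out"]],
                    "x_acc_in_norm": [base["x_acc"]],
                    "x_don_in_norm": [base["x_don"]],
                    "raw_tot": [100],
                }
            )
            cur = pq.compute_psi(pb)["psi_overall"].iloc[0]
            assert cur >= prev
            prev = cur

    def test_strand_symmetry(self):
        # the same design generated all-plus vs all-minus: estimates stay
        # accurate in both orientations
        for rate in (0.0, 1.0):
            genome, ann = sd.gen_genome(10, 3, seed=5, minus_strand_rate=rate)
            exons = sd.cassette_exons(genome, ann)
            for e in exons:
                e.true_psi = {ct: 0.4 for ct in sd.CELL_TYPES}
            reads = sd.gen_reads(exons, sd.uniform_depth_table(1, 2000), seed=2)
            wide = pq.quantify(reads, exons, ann)
            assert np.allclose(wide["psi_glia"], 0.4, atol=0.05)
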