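"""Synthetic genomes, peaks, long-read exon chains and variants with a
planted position-dependent splicing grammar.

The generator emulates the input side of a long-read single-nucleus splicing
study: corrected exon-chain reads for two cell types (glia, neuron) across
multiple individuals, eCLIP-style peak tracks for many RBPs, and
single-nucleotide variants linked to introns with a signed slope.  Every
exon's true inclusion rate is a logistic function of the planted peaks:

    logit(psi[exon, cell]) = baseline[cell] + sum over placed peaks of
                             effect[(rbp, category, cell)]

so grammar recovery by downstream models can be checked against ground
truth.  RBP motifs are additionally written into the genome underneath each
placed peak, giving sequence-based models the same signal.

Coordinates are 0-based half-open everywhere internally; BED output is
native 0-based, the GFF-like annotation is written 1-based closed at the
I/O boundary only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seqs

CELL_TYPES = ("glia", "neuron")

#: The six positional categories of the splicing code, in transcription
#: order.  "acc" = 3' splice site (exon start in transcript sense),
#: "don" = 5' splice site.
CATEGORIES = ("upstream", "acc_overlap", "exonic", "spanning", "don_overlap", "downstream")

FLANK = 400  # bp of intronic flank considered on each side of an exon


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Grammar:
    """Planted positional RBP effects on the inclusion logit.

    rbp_effects maps (rbp, category, cell_type) -> additive logit weight;
    entries absent from the map are zero.  motif_map holds the short
    nucleotide motif written into the genome wherever that RBP's peaks are
    placed.  cell_specific lists the RBPs whose effects flip sign between
    the two cell types.
    """

    rbp_effects: dict
    baseline_logit: dict
    motif_map: dict
    cell_specific: tuple = ()

    def effect(self, rbp: str, category: str, cell_type: str) -> float:
        return self.rbp_effects.get((rbp, category, cell_type), 0.0)

    def active_categories(self, rbp: str) -> list:
        cats = {
            c for (r, c, _t), w in self.rbp_effects.items() if r == rbp and w != 0.0
        }
        return [c for c in CATEGORIES if c in cats]


@dataclasses.dataclass
class SyntheticExon:
    exon_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    acc_flank: tuple  # flanking constitutive exon on the acceptor side (transcript 5')
    don_flank: tuple  # flanking constitutive exon on the donor side (transcript 3')
    true_psi: dict = dataclasses.field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate`; ground truth for every stage."""

    genome: dict  # chrom -> uint8 code array
    annotation: pd.DataFrame
    grammar: Grammar
    exons: list  # SyntheticExon, cassette exons only
    placements: pd.DataFrame  # exon_id, rbp, category, chrom, start, end
    peaksets: dict  # rbp -> {chrom: [(start, end), ...]}
    reads: pd.DataFrame
    variants: pd.DataFrame | None = None

    def exon_by_id(self, exon_id: str) -> SyntheticExon:
        for ex in self.exons:
            if ex.exon_id == exon_id:
                return ex
        raise KeyError(exon_id)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

_GT = _seqs.encode("GT")
_AG = _seqs.encode("AG")


def _draw_exon_len(rng: np.random.Generator, cassette: bool) -> int:
    if cassette and rng.random() < 0.12:
        return int(rng.integers(12, 28))  # microexon (<=27 bp)
    return int(rng.integers(28, 241))


def _draw_intron_len(rng: np.random.Generator) -> int:
    u = rng.random()
    if u < 0.2:
        return int(rng.integers(60, 101))
    if u < 0.85:
        return int(rng.integers(200, 901))
    return int(rng.integers(1100, 2200))


def gen_genome(
    n_genes: int,
    exons_per_gene: int = 3,
    seed: int = 0,
    minus_strand_rate: float = 0.5,
    pad: int = 700,
):
    """Generate a random genome with one gene per chromosome.

    Each gene carries exactly one cassette exon (the middle internal exon),
    flanked by constitutive exons of >=60 bp, with canonical GT/AG intron
    dinucleotides on the coding strand.  Returns (genome, annotation) where
    genome maps chrom -> uint8 code array and the annotation has 0-based
    half-open exon intervals.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if exons_per_gene < 3:
        raise ValueError(f"exons_per_gene must be >= 3, got {exons_per_gene}")
    rng = np.random.default_rng(seed)
    genome: dict = {}
    rows = []
    cassette_idx = exons_per_gene // 2
    for g in range(n_genes):
        gene_id = f"g{g:04d}"
        chrom = f"chr_{gene_id}"
        strand = "-" if rng.random() < minus_strand_rate else "+"
        # design in transcript orientation first
        exon_lens = []
        for i in range(exons_per_gene):
            if i == cassette_idx:
                exon_lens.append(_draw_exon_len(rng, cassette=True))
            else:
                exon_lens.append(int(rng.integers(80, 201)))
        intron_lens = [_draw_intron_len(rng) for _ in range(exons_per_gene - 1)]
        total = pad * 2 + sum(exon_lens) + sum(intron_lens)
        seq = _seqs.random_codes(rng, total)
        exon_ivs = []
        pos = pad
        for i, el in enumerate(exon_lens):
            exon_ivs.append((pos, pos + el))
            pos += el
            if i < exons_per_gene - 1:
                seq[pos : pos + 2] = _GT  # donor side of intron
                seq[pos + intron_lens[i] - 2 : pos + intron_lens[i]] = _AG
                pos += intron_lens[i]
        if strand == "-":
            seq = _seqs.revcomp(seq)
            exon_ivs = [(total - e, total - s) for (s, e) in exon_ivs]
            exon_ivs = exon_ivs[::-1]
            # keep transcript order for exon numbering
            order = list(range(exons_per_gene))[::-1]
        else:
            order = list(range(exons_per_gene))
        genome[chrom] = seq
        # rows in genomic coordinate order; exon_idx counts transcript order
        for genomic_i, (s, e) in enumerate(exon_ivs):
            tx_i = order[genomic_i]
            role = "cassette" if tx_i == cassette_idx else "constitutive"
            rows.append(
                {
                    "exon_id": f"{gene_id}_e{tx_i}",
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "start": s,
                    "end": e,
                    "exon_idx": tx_i,
                    "role": role,
                }
            )
    annotation = pd.DataFrame(rows)
    return genome, annotation


def cassette_exons(genome: dict, annotation: pd.DataFrame) -> list:
    """Extract SyntheticExon records (cassette exons with their flanks)."""
    out = []
    for gene_id, sub in annotation.groupby("gene_id", sort=True):
        sub = sub.sort_values("exon_idx")
        strand = sub["strand"].iloc[0]
        cass = sub[sub["role"] == "cassette"]
        for _, row in cass.iterrows():
            prev = sub[sub["exon_idx"] == row["exon_idx"] - 1].iloc[0]
            nxt = sub[sub["exon_idx"] == row["exon_idx"] + 1].iloc[0]
            out.append(
                SyntheticExon(
                    exon_id=row["exon_id"],
                    gene_id=gene_id,
                    chrom=row["chrom"],
                    strand=strand,
                    start=int(row["start"]),
                    end=int(row["end"]),
                    acc_flank=(int(prev["start"]), int(prev["end"])),
                    don_flank=(int(nxt["start"]), int(nxt["end"])),
                )
            )
    return out


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------


def plant_grammar(
    rbp_names: Sequence[str],
    n_cell_specific: int = 0,
    seed: int = 0,
    min_effect: float = 0.3,
    max_effect: float = 1.2,
    baseline: Mapping[str, float] | None = None,
    motif_len: int = 6,
) -> Grammar:
    """Plant one active positional category per RBP with a signed weight.

    Exactly ``n_cell_specific`` RBPs receive opposite-sign effects between
    the two cell types (QKI-like behaviour); all others share one effect.
    """
    names = list(rbp_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate rbp_names")
    if n_cell_specific > len(names):
        raise ValueError("n_cell_specific exceeds number of RBPs")
    rng = np.random.default_rng(seed)
    baseline = dict(baseline) if baseline is not None else {ct: 0.0 for ct in CELL_TYPES}
    effects: dict = {}
    motif_map: dict = {}
    specific = set(rng.choice(len(names), size=n_cell_specific, replace=False).tolist())
    for i, rbp in enumerate(names):
        cat = CATEGORIES[rng.integers(0, len(CATEGORIES))]
        w = float(rng.uniform(min_effect, max_effect)) * (1 if rng.random() < 0.5 else -1)
        if i in specific:
            effects[(rbp, cat, CELL_TYPES[0])] = w
            effects[(rbp, cat, CELL_TYPES[1])] = -w
        else:
            for ct in CELL_TYPES:
                effects[(rbp, cat, ct)] = w
        motif_map[rbp] = _seqs.decode(_seqs.random_codes(rng, motif_len))
    return Grammar(
        rbp_effects=effects,
        baseline_logit=baseline,
        motif_map=motif_map,
        cell_specific=tuple(names[i] for i in sorted(specific)),
    )


def effect_table(grammar: Grammar, rbp_names: Sequence[str]) -> pd.DataFrame:
    """Dense (rbp x category x cell_type) long table, zeros included."""
    rows = []
    for rbp in rbp_names:
        for cat in CATEGORIES:
            for ct in CELL_TYPES:
                rows.append(
                    {
                        "rbp": rbp,
                        "category": cat,
                        "cell_type": ct,
                        "effect": grammar.effect(rbp, cat, ct),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peak placement
# ---------------------------------------------------------------------------


def _category_interval(
    exon: SyntheticExon,
    category: str,
    rng: np.random.Generator,
    peak_len: int,
    flank_offset: int | None = None,
) -> tuple:
    """Genomic interval of a peak in the given positional category.

    Geometry is strand-aware: "upstream" is transcriptionally 5' of the
    acceptor.  ``flank_offset`` pins the near edge of flank peaks at a fixed
    distance from the splice site (used to plant motifs at reproducible
    positions for sequence models).
    """
    s, e, strand, L = exon.start, exon.end, exon.strand, exon.length
    if strand == "+":
        acc, don = s, e
    else:
        acc, don = e, s

    def flank_iv(site: int, direction: int) -> tuple:
        # direction +1: genomic right of site; -1: genomic left
        off = flank_offset if flank_offset is not None else int(rng.integers(5, FLANK - peak_len))
        off = min(off, FLANK - peak_len)
        if direction > 0:
            return site + off, site + off + peak_len
        return site - off - peak_len, site - off

    if category == "spanning":
        m = int(rng.integers(5, 20))
        return s - m, e + m
    if category == "exonic":
        if L <= 4:
            raise ValueError("exon too short for an exonic peak")
        ln = min(peak_len, L - 2)
        off = int(rng.integers(1, L - ln)) if L - ln > 1 else 1
        return s + off, s + off + ln
    if category == "acc_overlap":
        inside = max(2, min(peak_len // 2, L - 2))
        if strand == "+":
            return acc - peak_len + inside, acc + inside
        return acc - inside, acc + peak_len - inside
    if category == "don_overlap":
        inside = max(2, min(peak_len // 2, L - 2))
        if strand == "+":
            return don - inside, don + peak_len - inside
        return don - peak_len + inside, don + inside
    if category == "upstream":
        return flank_iv(acc, +1 if strand == "-" else -1)
    if category == "downstream":
        return flank_iv(don, +1 if strand == "+" else -1)
    raise ValueError(f"unknown category {category!r}")


def gen_peaks(
    exons: Sequence[SyntheticExon],
    grammar: Grammar,
    placement_rate: float = 0.5,
    seed: int = 0,
    peak_len: int = 40,
    flank_offset: int | None = None,
) -> tuple:
    """Place peaks for each RBP at its grammar-active categories.

    For every exon, each RBP independently receives one peak at one of its
    active categories with probability ``placement_rate``.  Returns
    (placements DataFrame, peaksets dict rbp -> {chrom: [(s, e)]}).
    """
    if not (0 < placement_rate <= 1):
        raise ValueError(f"placement_rate must be in (0, 1], got {placement_rate}")
    rng = np.random.default_rng(seed)
    rbps = sorted({r for (r, _c, _t) in grammar.rbp_effects})
    rows = []
    peaksets: dict = {r: {} for r in rbps}
    for exon in exons:
        for rbp in rbps:
            cats = grammar.active_categories(rbp)
            if not cats:
                continue
            if rng.random() >= placement_rate:
                continue
            cat = cats[int(rng.integers(0, len(cats)))]
            try:
                iv = _category_interval(exon, cat, rng, peak_len, flank_offset)
            except ValueError:
                continue
            rows.append(
                {
                    "exon_id": exon.exon_id,
                    "rbp": rbp,
                    "category": cat,
                    "chrom": exon.chrom,
                    "start": iv[0],
                    "end": iv[1],
                }
            )
            peaksets[rbp].setdefault(exon.chrom, []).append(iv)
    placements = pd.DataFrame(
        rows, columns=["exon_id", "rbp", "category", "chrom", "start", "end"]
    )
    for r in peaksets:
        for c in peaksets[r]:
            peaksets[r][c] = sorted(peaksets[r][c])
    return placements, peaksets


def plant_motifs(genome: dict, placements: pd.DataFrame, grammar: Grammar, annotation: pd.DataFrame) -> None:
    """Write each RBP's motif into the genome at the center of its peaks.

    Motifs are planted in transcript orientation: on minus-strand genes the
    reverse complement is written so the transcribed sequence carries the
    motif.  Mutates ``genome`` in place.
    """
    strand_of = annotation.drop_duplicates("chrom").set_index("chrom")["strand"]
    for _, row in placements.iterrows():
        motif = _seqs.encode(grammar.motif_map[row["rbp"]])
        if strand_of[row["chrom"]] == "-":
            motif = _seqs.revcomp(motif)
        mid = (row["start"] + row["end"]) // 2
        lo = mid - len(motif) // 2
        genome[row["chrom"]][lo : lo + len(motif)] = motif


def compute_true_psi(
    exons: Sequence[SyntheticExon],
    placements: pd.DataFrame,
    grammar: Grammar,
    logit_noise_sd: Mapping[str, float] | None = None,
    seed: int = 0,
) -> None:
    """Set each exon's true_psi per cell type from its placed peaks.

    ``logit_noise_sd`` adds per-exon Gaussian noise on the inclusion logit
    of a cell type; setting it large for one cell type while zeroing that
    cell type's grammar effects emulates a cell type whose splicing is
    decoupled from the measured binding sites.
    """

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    rng = np.random.default_rng(seed)
    noise = logit_noise_sd or {}
    by_exon = placements.groupby("exon_id") if len(placements) else None
    for exon in exons:
        for ct in CELL_TYPES:
            logit = grammar.baseline_logit.get(ct, 0.0)
            if by_exon is not None and exon.exon_id in by_exon.groups:
                for _, p in by_exon.get_group(exon.exon_id).iterrows():
                    logit += grammar.effect(p["rbp"], p["category"], ct)
            sd_ct = noise.get(ct, 0.0)
            if sd_ct:
                logit += float(rng.normal(0.0, sd_ct))
            exon.true_psi[ct] = float(sigmoid(logit))


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------


def _chain_str(intervals: Iterable[tuple]) -> str:
    return ";".join(f"{s}-{e}" for s, e in sorted(intervals))


def gen_reads(
    exons: Sequence[SyntheticExon],
    depth_table: Mapping[tuple, int],
    seed: int = 0,
    truncated_fraction: float = 0.05,
) -> pd.DataFrame:
    """Emit long-read exon chains per exon, individual and cell type.

    Inclusion reads ~ Binomial(depth, true_psi); a ``truncated_fraction`` of
    inclusion reads end on the cassette exon after supporting only the
    acceptor or only the donor (populating the acc-in/don-in count classes).
    Skipping reads join the two flanking exons, which are always >=50 bp, so
    the skip-counting rule can fire.
    """
    rng = np.random.default_rng(seed)
    if any(d < 0 for d in depth_table.values()):
        raise ValueError("depths must be >= 0")
    recs: dict = {k: [] for k in ("read_id", "individual", "cell_type", "chrom", "strand", "exons")}
    n = 0
    for exon in exons:
        accf, donf, cass = exon.acc_flank, exon.don_flank, (exon.start, exon.end)
        full = _chain_str([accf, cass, donf])
        skip = _chain_str([accf, donf])
        L = exon.length
        k = max(3, L // 2)
        if exon.strand == "+":
            acc_part = _chain_str([accf, (exon.start, exon.start + k)])
            don_part = _chain_str([(exon.end - k, exon.end), donf])
        else:
            acc_part = _chain_str([(exon.end - k, exon.end), accf])
            don_part = _chain_str([donf, (exon.start, exon.start + k)])
        for (ind, ct), depth in depth_table.items():
            if depth == 0:
                continue
            psi = exon.true_psi[ct]
            n_in = int(rng.binomial(depth, psi))
            n_out = depth - n_in
            n_trunc = int(rng.binomial(n_in, truncated_fraction))
            n_acc = int(rng.binomial(n_trunc, 0.5))
            n_don = n_trunc - n_acc
            n_full = n_in - n_trunc
            for chain, count in ((full, n_full), (skip, n_out), (acc_part, n_acc), (don_part, n_don)):
                if count == 0:
                    continue
                recs["read_id"].extend(f"r{j}" for j in range(n, n + count))
                n += count
                recs["individual"].extend([ind] * count)
                recs["cell_type"].extend([ct] * count)
                recs["chrom"].extend([exon.chrom] * count)
                recs["strand"].extend([exon.strand] * count)
                recs["exons"].extend([chain] * count)
    return pd.DataFrame(recs)


def uniform_depth_table(n_individuals: int, depth: int, cell_types=CELL_TYPES) -> dict:
    return {(f"ind{i}", ct): depth for i in range(n_individuals) for ct in cell_types}


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def gen_variants(
    exons: Sequence[SyntheticExon],
    grammar: Grammar,
    placements: pd.DataFrame,
    genome: dict,
    annotation: pd.DataFrame,
    seed: int = 0,
    n_planted: int = 20,
    n_neutral: int = 20,
    effect_cell: str = "glia",
) -> pd.DataFrame:
    """Variants inside planted motifs (labelled) plus neutral ones.

    A variant disrupting a motif whose planted effect raises inclusion gets
    a positive slope (more intron excision for the disrupting allele), so
    the expected prediction is dISM(alt-ref) < 0; and vice versa.  Neutral
    variants sit in intronic sequence away from any peak and get a
    random-sign slope.  POS is 1-based as in VCF; alleles are plus-strand.
    """
    rng = np.random.default_rng(seed)
    exon_by_id = {e.exon_id: e for e in exons}
    rows = []
    candidates = placements[placements["exon_id"].isin(exon_by_id)]
    candidates = candidates.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    n_done = 0
    for _, p in candidates.iterrows():
        if n_done >= n_planted:
            break
        w = grammar.effect(p["rbp"], p["category"], effect_cell)
        if w == 0.0:
            continue
        exon = exon_by_id[p["exon_id"]]
        mid = (p["start"] + p["end"]) // 2  # motif center (see plant_motifs)
        pos0 = int(mid)
        ref_code = int(genome[exon.chrom][pos0])
        alt_code = int((ref_code + rng.integers(1, 4)) % 4)
        expected_sign = -int(np.sign(w))
        slope = float(np.sign(w)) * float(rng.uniform(0.2, 0.8))
        rows.append(
            {
                "chrom": exon.chrom,
                "pos": pos0 + 1,
                "ref": _seqs.BASES[ref_code],
                "alt": _seqs.BASES[alt_code],
                "intron_start": exon.acc_flank[1] if exon.strand == "+" else exon.don_flank[1],
                "intron_end": exon.don_flank[0] if exon.strand == "+" else exon.acc_flank[0],
                "slope": slope,
                "pval": float(rng.uniform(1e-8, 1e-4)),
                "exon_id": exon.exon_id,
                "label": "planted",
                "expected_dism_sign": expected_sign,
            }
        )
        n_done += 1
    # neutral variants: intronic, >=60 bp clear of any peak and the exon
    peak_by_chrom: dict = {}
    for _, p in placements.iterrows():
        peak_by_chrom.setdefault(p["chrom"], []).append((p["start"], p["end"]))
    order = rng.permutation(len(exons))
    n_done = 0
    for idx in order:
        if n_done >= n_neutral:
            break
        exon = exons[int(idx)]
        lo = min(exon.acc_flank[1], exon.don_flank[1], exon.start)
        hi = max(exon.acc_flank[0], exon.don_flank[0], exon.end)
        for _attempt in range(50):
            pos0 = int(rng.integers(lo, hi))
            if exon.start - 10 <= pos0 < exon.end + 10:
                continue
            near_peak = any(
                s - 60 <= pos0 < e + 60 for (s, e) in peak_by_chrom.get(exon.chrom, [])
            )
            if near_peak:
                continue
            ref_code = int(genome[exon.chrom][pos0])
            alt_code = int((ref_code + rng.integers(1, 4)) % 4)
            rows.append(
                {
                    "chrom": exon.chrom,
                    "pos": pos0 + 1,
                    "ref": _seqs.BASES[ref_code],
                    "alt": _seqs.BASES[alt_code],
                    "intron_start": exon.acc_flank[1] if exon.strand == "+" else exon.don_flank[1],
                    "intron_end": exon.don_flank[0] if exon.strand == "+" else exon.acc_flank[0],
                    "slope": float(rng.uniform(0.2, 0.8)) * (1 if rng.random() < 0.5 else -1),
                    "pval": float(rng.uniform(1e-4, 1e-2)),
                    "exon_id": exon.exon_id,
                    "label": "neutral",
                    "expected_dism_sign": 0,
                }
            )
            n_done += 1
            break
    df = pd.DataFrame(rows)
    if len(df):
        validate_variants(df, annotation)
    return df


def validate_variants(variants: pd.DataFrame, annotation: pd.DataFrame) -> None:
    if (variants["ref"] == variants["alt"]).any():
        bad = variants[variants["ref"] == variants["alt"]].iloc[0]
        raise ValueError(f"variant at {bad['chrom']}:{bad['pos']} has ref == alt")
    spans = annotation.groupby("chrom").agg(lo=("start", "min"), hi=("end", "max"))
    for _, v in variants.iterrows():
        if v["chrom"] not in spans.index:
            raise ValueError(f"variant on unknown chromosome {v['chrom']}")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate(
    n_genes: int = 50,
    rbp_names: Sequence[str] | None = None,
    n_rbps: int = 20,
    n_cell_specific: int = 2,
    placement_rate: float = 0.3,
    depth: int = 100,
    n_individuals: int = 3,
    seed: int = 0,
    exons_per_gene: int = 3,
    truncated_fraction: float = 0.05,
    n_planted_variants: int = 0,
    n_neutral_variants: int = 0,
    grammar: Grammar | None = None,
    flank_offset: int | None = None,
    logit_noise_sd: Mapping[str, float] | None = None,
) -> SimulatedDataset:
    """Run the full generator: genome -> grammar -> peaks -> reads -> variants."""
    if rbp_names is None:
        rbp_names = [f"RBP{i:03d}" for i in range(n_rbps)]
    genome, annotation = gen_genome(n_genes, exons_per_gene, seed=seed)
    exons = cassette_exons(genome, annotation)
    if grammar is None:
        grammar = plant_grammar(rbp_names, n_cell_specific, seed=seed + 1)
    placements, peaksets = gen_peaks(
        exons, grammar, placement_rate, seed=seed + 2, flank_offset=flank_offset
    )
    plant_motifs(genome, placements, grammar, annotation)
    compute_true_psi(exons, placements, grammar, logit_noise_sd=logit_noise_sd, seed=seed + 5)
    depth_table = uniform_depth_table(n_individuals, depth)
    reads = gen_reads(exons, depth_table, seed=seed + 3, truncated_fraction=truncated_fraction)
    variants = None
    if n_planted_variants or n_neutral_variants:
        variants = gen_variants(
            exons,
            grammar,
            placements,
            genome,
            annotation,
            seed=seed + 4,
            n_planted=n_planted_variants,
            n_neutral=n_neutral_variants,
        )
    return SimulatedDataset(
        genome=genome,
        annotation=annotation,
        grammar=grammar,
        exons=exons,
        placements=placements,
        peaksets=peaksets,
        reads=reads,
        variants=variants,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_fasta(genome: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = _seqs.decode(genome[chrom])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: _seqs.encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation(annotation: pd.DataFrame, path) -> None:
    """GFF-like TSV, written 1-based closed (converted at this boundary)."""
    out = annotation.copy()
    out["start"] = out["start"] + 1  # 1-based closed
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    ann["start"] = ann["start"] - 1
    return ann


def write_beds(peaksets: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rbp, by_chrom in peaksets.items():
        with open(outdir / f"{rbp}.bed", "w") as fh:
            for chrom in sorted(by_chrom):
                for s, e in by_chrom[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{rbp}\t0\t.\n")


def write_reads(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_reads(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)
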