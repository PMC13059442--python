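"""Percent-spliced-in quantification from long-read exon chains.

Each molecule's ordered exon chain is classified against a cassette exon
into five read classes:

* ``x_in``      — chain contains the exon with both splice sites matching
* ``x_out``     — chain of the same gene skips the exon with >=50 aligned
                  bases on each genomic side
* ``x_acc_in``  — chain supports the acceptor junction and ends on the exon
* ``x_don_in``  — chain supports the donor junction and ends on the exon
* ``x_tot``     — chain whose genomic span overlaps the exon locus

after which the three inclusion ratios are

    psi_overall  = (x_in + x_acc_in + x_don_in) / (x_in + x_acc_in + x_don_in + x_out)
    psi_acceptor = (x_in + x_acc_in) / (x_in + x_acc_in + x_out)
    psi_donor    = (x_in + x_don_in) / (x_in + x_don_in + x_out)

computed on depth-normalized pseudo-bulk counts, with a value reported only
when at least ``min_reads`` (default 10) raw molecules cover the locus.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CELL_TYPES

logger = logging.getLogger(__name__)

COUNT_COLS = ["x_in", "x_out", "x_acc_in", "x_don_in", "x_tot"]

SKIP_MIN_BASES = 50  # aligned bases required on each side of a skipped exon
MIN_READS = 10  # raw molecules required to report a PSI value
PSI_RANGE = (0.02, 0.98)  # pseudo-bulk inclusion band retained for modelling
VARIABLE_DELTA = 0.25  # |delta PSI| beyond which an exon is called variable
VAR01_DELTA = 0.1


def parse_chain(chain: str) -> list:
    """'100-200;300-400' -> [(100, 200), (300, 400)] sorted."""
    ivs = []
    for part in chain.split(";"):
        s, e = part.split("-")
        ivs.append((int(s), int(e)))
    ivs.sort()
    return ivs


def _classify_chain(ivs: list, xs: int, xe: int, strand: str, gs: int, ge: int) -> str:
    """Classify one chain against exon [xs, xe); returns one of
    'in', 'out', 'acc', 'don', 'tot', 'none'."""
    span_s, span_e = ivs[0][0], ivs[-1][1]
    if span_e <= xs or span_s >= xe:
        return "none"  # span misses the locus entirely
    if (xs, xe) in ivs:
        return "in"
    overlapping = [(s, e) for s, e in ivs if s < xe and e > xs]
    if not overlapping:
        # skipping chain: same gene, >=50 aligned bases strictly on each side
        if span_e <= gs or span_s >= ge:
            return "none"
        left = sum(min(e, xs) - s for s, e in ivs if s < xs)
        right = sum(e - max(s, xe) for s, e in ivs if e > xe)
        if left >= SKIP_MIN_BASES and right >= SKIP_MIN_BASES:
            return "out"
        return "tot"
    if len(overlapping) == 1 and len(ivs) >= 2:
        s, e = overlapping[0]
        # partial exon that terminates the chain in transcription direction
        if strand == "+":
            if s == xs and e < xe and (s, e) == ivs[-1]:
                return "acc"
            if e == xe and s > xs and (s, e) == ivs[0]:
                return "don"
        else:
            if e == xe and s > xs and (s, e) == ivs[0]:
                return "acc"
            if s == xs and e < xe and (s, e) == ivs[-1]:
                return "don"
    return "tot"


def count_exon_reads(
    reads: pd.DataFrame, exon, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Count the five read classes for one exon per (individual, cell_type).

    ``exon`` needs attributes/keys exon_id, chrom, strand, start, end.
    Chains on other chromosomes are ignored (logged); the gene span is taken
    from the annotation.
    """
    ex = exon if hasattr(exon, "exon_id") else pd.Series(dict(exon))
    exon_id, chrom, strand = ex.exon_id, ex.chrom, ex.strand
    xs, xe = int(ex.start), int(ex.end)
    ann = annotation[annotation["chrom"] == chrom]
    if ann.empty or not ((ann["start"] == xs) & (ann["end"] == xe)).any():
        raise KeyError(f"exon {exon_id} ({chrom}:{xs}-{xe}) not in annotation")
    gs, ge = int(ann["start"].min()), int(ann["end"].max())
    sub = reads[reads["chrom"] == chrom]
    n_off = len(reads) - len(sub)
    if n_off:
        logger.debug("%d chains on other chromosomes ignored for %s", n_off, exon_id)
    if sub.empty:
        return pd.DataFrame(columns=["exon_id", "individual", "cell_type", *COUNT_COLS])
    classes = {
        chain: _classify_chain(parse_chain(chain), xs, xe, strand, gs, ge)
        for chain in sub["exons"].unique()
    }
    cls = sub["exons"].map(classes)
    df = pd.DataFrame(
        {"individual": sub["individual"], "cell_type": sub["cell_type"], "cls": cls}
    )
    df = df[df["cls"] != "none"]
    tab = (
        df.groupby(["individual", "cell_type", "cls"], observed=True)
        .size()
        .unstack("cls", fill_value=0)
    )
    for c in ("in", "out", "acc", "don", "tot"):
        if c not in tab.columns:
            tab[c] = 0
    out = pd.DataFrame(
        {
            "x_in": tab["in"],
            "x_out": tab["out"],
            "x_acc_in": tab["acc"],
            "x_don_in": tab["don"],
        }
    )
    out["x_tot"] = out.sum(axis=1) + tab["tot"]
    out = out.reset_index()
    out.insert(0, "exon_id", exon_id)
    return out


def count_all_exons(reads: pd.DataFrame, exons: Sequence, annotation: pd.DataFrame) -> pd.DataFrame:
    """Stack count_exon_reads over a list of cassette exons."""
    by_chrom = dict(tuple(reads.groupby("chrom", sort=False)))
    parts = []
    for exon in exons:
        sub = by_chrom.get(exon.chrom, reads.iloc[0:0])
        parts.append(count_exon_reads(sub, exon, annotation))
    if not parts:
        return pd.DataFrame(columns=["exon_id", "individual", "cell_type", *COUNT_COLS])
    return pd.concat(parts, ignore_index=True)


def exclude_retention_like(
    candidates: pd.DataFrame, annotation: pd.DataFrame, min_nonexonic: int = 70
) -> pd.DataFrame:
    """Drop intron-retention-like events among candidate exons.

    A candidate interval that is not itself annotated but shares one or two
    annotated splice sites and has >= ``min_nonexonic`` bases outside all
    annotated exons is removed (retention event or alternative
    acceptor/donor); annotated exons always pass.
    """
    keep = []
    ann_by_chrom = dict(tuple(annotation.groupby("chrom")))
    for _, row in candidates.iterrows():
        ann = ann_by_chrom.get(row["chrom"])
        if ann is None:
            keep.append(True)
            continue
        s, e = int(row["start"]), int(row["end"])
        annotated = ((ann["start"] == s) & (ann["end"] == e)).any()
        if annotated:
            keep.append(True)
            continue
        sites = set(ann["start"]).union(set(ann["end"]))
        n_sites = int(s in sites) + int(e in sites)
        if n_sites == 0:
            keep.append(True)
            continue
        cov = np.zeros(e - s, dtype=bool)
        for _, a in ann.iterrows():
            lo, hi = max(s, int(a["start"])), min(e, int(a["end"]))
            if hi > lo:
                cov[lo - s : hi - s] = True
        keep.append(int((~cov).sum()) < min_nonexonic)
    return candidates[np.array(keep, dtype=bool)].reset_index(drop=True)


def normalize_by_depth(
    counts: pd.DataFrame, individual_totals: Mapping[str, int]
) -> pd.DataFrame:
    """Depth-normalize per individual, then sum to pseudo-bulk.

    Each individual's five counts are divided by that individual's total
    read count before summing across individuals per exon and cell type.
    The raw (un-normalized) x_tot is retained for the minimum-read rule.
    Individuals with zero total reads are dropped with a warning.
    """
    totals = pd.Series(individual_totals, dtype=float)
    zero = totals[totals <= 0].index
    if len(zero):
        logger.warning("dropping individuals with zero reads: %s", list(zero))
        counts = counts[~counts["individual"].isin(zero)]
        totals = totals.drop(zero)
    df = counts.copy()
    scale = df["individual"].map(totals)
    for c in COUNT_COLS:
        df[f"{c}_norm"] = df[c] / scale
    grouped = df.groupby(["exon_id", "cell_type"], observed=True)
    out = grouped[[f"{c}_norm" for c in COUNT_COLS]].sum()
    out["raw_tot"] = grouped["x_tot"].sum()
    return out.reset_index()


def _psi_from_counts(x_in, x_acc, x_don, x_out):
    def ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return r

    overall = ratio(x_in + x_acc + x_don, x_in + x_acc + x_don + x_out)
    acceptor = ratio(x_in + x_acc, x_in + x_acc + x_out)
    donor = ratio(x_in + x_don, x_in + x_don + x_out)
    return overall, acceptor, donor


def compute_psi(pseudobulk: pd.DataFrame, min_reads: int = MIN_READS) -> pd.DataFrame:
    """Three PSI values per exon x cell type from pseudo-bulk counts.

    PSI is missing (NaN) when the raw molecule count is below ``min_reads``
    or the denominator is zero.
    """
    df = pseudobulk.copy()
    overall, acceptor, donor = _psi_from_counts(
        df["x_in_norm"].to_numpy(),
        df["x_acc_in_norm"].to_numpy(),
        df["x_don_in_norm"].to_numpy(),
        df["x_out_norm"].to_numpy(),
    )
    low = df["raw_tot"].to_numpy() < min_reads
    for name, vals in (("psi_overall", overall), ("psi_acceptor", acceptor), ("psi_donor", donor)):
        vals = np.asarray(vals, dtype=float)
        vals[low] = np.nan
        df[name] = vals
    return df[["exon_id", "cell_type", "psi_overall", "psi_acceptor", "psi_donor", "raw_tot"]]


def filter_psi_range(
    pseudobulk: pd.DataFrame, lo: float = PSI_RANGE[0], hi: float = PSI_RANGE[1]
) -> pd.Index:
    """Exons whose joint pseudo-bulk PSI values all lie in [lo, hi].

    The filter is evaluated on counts pooled over cell types (joint
    pseudo-bulk); bounds are inclusive.
    """
    pooled = (
        pseudobulk.groupby("exon_id")[
            ["x_in_norm", "x_acc_in_norm", "x_don_in_norm", "x_out_norm"]
        ]
        .sum()
        .reset_index()
    )
    overall, acceptor, donor = _psi_from_counts(
        pooled["x_in_norm"].to_numpy(),
        pooled["x_acc_in_norm"].to_numpy(),
        pooled["x_don_in_norm"].to_numpy(),
        pooled["x_out_norm"].to_numpy(),
    )
    ok = np.ones(len(pooled), dtype=bool)
    for vals in (overall, acceptor, donor):
        vals = np.asarray(vals, dtype=float)
        ok &= ~np.isnan(vals) & (vals >= lo) & (vals <= hi)
    return pd.Index(pooled.loc[ok, "exon_id"])


def classify_variability(psi_glia, psi_neuron) -> np.ndarray:
    """Label exons by |delta PSI| = |psi_glia - psi_neuron| (strict >)."""
    pg = np.asarray(psi_glia, dtype=float)
    pn = np.asarray(psi_neuron, dtype=float)
    delta = pg - pn
    out = np.full(pg.shape, "non_variable", dtype=object)
    out[np.abs(delta) > VAR01_DELTA] = "var0.1"
    out[np.abs(delta) > VARIABLE_DELTA] = "variable"
    out[np.isnan(delta)] = "unmeasured"
    return out


def psi_wide(psi_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the per-cell-type PSI table to one row per exon with
    psi_glia, psi_neuron, delta_psi (glia - neuron) and variability."""
    wide = psi_table.pivot(index="exon_id", columns="cell_type", values="psi_overall")
    wide = wide.rename(columns={ct: f"psi_{ct}" for ct in CELL_TYPES})
    for ct in CELL_TYPES:
        if f"psi_{ct}" not in wide.columns:
            wide[f"psi_{ct}"] = np.nan
    wide["delta_psi"] = wide["psi_glia"] - wide["psi_neuron"]
    wide["variability"] = classify_variability(wide["psi_glia"], wide["psi_neuron"])
    return wide.reset_index()


def downsample_skewed(
    records: pd.DataFrame,
    target: int = 5000,
    seed: int = 0,
    mode: str = "skew",
) -> pd.DataFrame:
    """Subsample the high-inclusion class to make training less skewed.

    mode='skew' targets {psi_neuron > 0.9, psi_glia > 0.9, |delta| < 0.03};
    mode='psi1' targets {psi == 1 in both} (the rule used for data where
    nearly all exons are fully included).  The class is subsampled without
    replacement to min(target, class size); all other rows are kept.
    """
    if mode == "skew":
        in_class = (
            (records["psi_neuron"] > 0.9)
            & (records["psi_glia"] > 0.9)
            & (records["delta_psi"].abs() < 0.03)
        )
    elif mode == "psi1":
        in_class = (records["psi_neuron"] == 1.0) & (records["psi_glia"] == 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    in_class = in_class.fillna(False).to_numpy(dtype=bool)
    idx = np.nonzero(in_class)[0]
    if len(idx) > target:
        rng = np.random.default_rng(seed)
        keep_class = rng.choice(idx, size=target, replace=False)
        keep = np.zeros(len(records), dtype=bool)
        keep[~in_class] = True
        keep[keep_class] = True
        return records[keep].reset_index(drop=True)
    return records.reset_index(drop=True)


def coordination_test(reads: pd.DataFrame, exon_a, exon_b) -> dict:
    """Test whether two exons co-occur non-randomly on the same molecules.

    Only chains whose genomic span covers both exon loci contribute; each
    is called in/out per exon (partial overlaps are discarded).  Returns
    the 2x2 table, odds ratio and two-sided Fisher exact p-value.
    """
    if exon_a.chrom != exon_b.chrom:
        raise ValueError("exons on different chromosomes never share a molecule")
    sub = reads[reads["chrom"] == exon_a.chrom]
    lo = min(exon_a.start, exon_b.start)
    hi = max(exon_a.end, exon_b.end)
    table = np.zeros((2, 2), dtype=int)
    n_span = 0
    for chain in sub["exons"]:
        ivs = parse_chain(chain)
        if ivs[0][0] > lo or ivs[-1][1] < hi:
            continue
        n_span += 1

        def state(ex):
            if (ex.start, ex.end) in ivs:
                return 0  # in
            if not any(s < ex.end and e > ex.start for s, e in ivs):
                return 1  # out
            return -1  # partial

        sa, sb = state(exon_a), state(exon_b)
        if sa < 0 or sb < 0:
            continue
        table[sa, sb] += 1
    if n_span < 1:
        raise ValueError("no chains span both exon loci")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": odds, "p_value": p, "n_spanning": n_span}


def quantify(
    reads: pd.DataFrame,
    exons: Sequence,
    annotation: pd.DataFrame,
    min_reads: int = MIN_READS,
    apply_range_filter: bool = False,
) -> pd.DataFrame:
    """Full pipeline: counts -> depth normalization -> PSI -> wide table."""
    counts = count_all_exons(reads, exons, annotation)
    totals = reads["individual"].value_counts().to_dict()
    pb = normalize_by_depth(counts, totals)
    psi = compute_psi(pb, min_reads=min_reads)
    wide = psi_wide(psi)
    if apply_range_filter:
        kept = filter_psi_range(pb)
        wide = wide[wide["exon_id"].isin(kept)].reset_index(drop=True)
    return wide
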