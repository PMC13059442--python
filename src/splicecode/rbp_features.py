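"""Positional RBP-binding features and metagene binding profiles.

Peaks from eCLIP-style BED tracks are merged per RBP and assigned, per
cassette exon, to one of six strand-aware positional categories:

    upstream | acc_overlap | exonic | spanning | don_overlap | downstream

("acc" = 3' splice site, transcriptionally 5' of the exon).  Counting peaks
per (RBP, category) gives the exon x (6 x n_rbp) feature matrix used by the
logistic splicing-code model (732 columns for 122 RBPs).  Binding profiles
summarize, per RBP and exon group, the fraction of exons covered by a peak
at each of 400 upstream flank positions + 50 exon-body bins + 400
downstream flank positions (850 positions, transcript orientation).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CATEGORIES, CELL_TYPES, FLANK

logger = logging.getLogger(__name__)

N_EXON_BINS = 50
MIN_PROFILE_EXON_LEN = 50
PROFILE_LEN = FLANK + N_EXON_BINS + FLANK  # 850


@dataclasses.dataclass
class PeakSet:
    """Merged, sorted, non-overlapping peak intervals for one RBP."""

    rbp_name: str
    intervals: dict  # chrom -> list of (start, end), 0-based half-open

    def on(self, chrom: str) -> list:
        return self.intervals.get(chrom, [])


def merge_intervals(intervals: Sequence) -> list:
    """Union-merge overlapping or bookended intervals."""
    ivs = sorted(intervals)
    out: list = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_bed(path) -> list:
    """Parse a 6-column BED (score/strand ignored) -> [(chrom, start, end)]."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: malformed BED line: {line!r}")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}:{i}: malformed BED line: {line!r}") from err
            rows.append((parts[0], s, e))
    return rows


def merge_replicates(rbp_name: str, bed_paths: Sequence) -> PeakSet:
    """Union-merge peaks across replicate/cell-line BED files of one RBP,
    so overlapping replicate peaks are counted only once."""
    by_chrom: dict = {}
    for path in bed_paths:
        for chrom, s, e in read_bed(path):
            by_chrom.setdefault(chrom, []).append((s, e))
    return PeakSet(rbp_name, {c: merge_intervals(v) for c, v in by_chrom.items()})


def peaksets_from_dir(bed_dir) -> dict:
    """One PeakSet per BED file in a directory (stem = RBP name)."""
    out = {}
    for path in sorted(Path(bed_dir).glob("*.bed")):
        out[path.stem] = merge_replicates(path.stem, [path])
    return out


def peaksets_from_intervals(raw: Mapping[str, Mapping[str, Sequence]]) -> dict:
    """Wrap {rbp: {chrom: [(s, e)]}} dicts (e.g. from the generator)."""
    return {
        rbp: PeakSet(rbp, {c: merge_intervals(v) for c, v in by_chrom.items()})
        for rbp, by_chrom in raw.items()
    }


def assign_category(peak: tuple, exon) -> str | None:
    """Map one peak interval to its positional category for an exon.

    Containment/crossing definitions make the six categories mutually
    exclusive: spanning contains the whole exon; acc/don_overlap cross one
    boundary without containing it; exonic is fully inside; upstream and
    downstream are fully intronic with the near edge within 400 bp of the
    splice site.  Returns None for peaks out of range.
    """
    s, e = peak
    xs, xe, strand = exon.start, exon.end, exon.strand
    if s <= xs and e >= xe:
        return "spanning"
    if s < xs < e:
        return "acc_overlap" if strand == "+" else "don_overlap"
    if s < xe < e:
        return "don_overlap" if strand == "+" else "acc_overlap"
    if s >= xs and e <= xe:
        return "exonic"
    if e <= xs:  # fully on the genomic left
        if e <= xs - FLANK:
            return None
        return "upstream" if strand == "+" else "downstream"
    if s >= xe:  # fully on the genomic right
        if s >= xe + FLANK:
            return None
        return "downstream" if strand == "+" else "upstream"
    return None


def feature_columns(rbp_names: Sequence[str]) -> list:
    return [f"{rbp}:{cat}" for rbp in sorted(rbp_names) for cat in CATEGORIES]


def build_feature_matrix(exons: Sequence, peaksets: Mapping[str, PeakSet]) -> pd.DataFrame:
    """Count merged peaks per (exon, RBP, category).

    Returns a DataFrame indexed by exon_id with 6 x n_rbp integer columns
    named ``RBP:category``.  Exons with zero peaks across all RBPs remain
    as all-zero rows (callers exclude them from model training/testing).
    """
    if not len(exons) or not peaksets:
        raise ValueError("need at least one exon and one peak set")
    cols = feature_columns(list(peaksets))
    col_idx = {c: i for i, c in enumerate(cols)}
    mat = np.zeros((len(exons), len(cols)), dtype=np.int64)
    for i, exon in enumerate(exons):
        for rbp, ps in peaksets.items():
            for iv in ps.on(exon.chrom):
                cat = assign_category(iv, exon)
                if cat is not None:
                    mat[i, col_idx[f"{rbp}:{cat}"]] += 1
    return pd.DataFrame(mat, index=[e.exon_id for e in exons], columns=cols)


def zero_feature_mask(fm: pd.DataFrame) -> pd.Series:
    """True for exons without any binding site for any RBP."""
    return fm.sum(axis=1) == 0


# ---------------------------------------------------------------------------
# binding profiles
# ---------------------------------------------------------------------------


def _exon_coverage_profile(exon, intervals: Sequence) -> np.ndarray:
    """Per-position peak coverage for one exon, transcript orientation.

    Positions 0..399: upstream flank (position 399 = last intronic base
    before the acceptor); 400..449: exon body in 50 equal bins; 450..849:
    downstream flank.
    """
    xs, xe = exon.start, exon.end
    win_lo, win_hi = xs - FLANK, xe + FLANK
    cov = np.zeros(win_hi - win_lo, dtype=bool)
    for s, e in intervals:
        lo, hi = max(s, win_lo), min(e, win_hi)
        if hi > lo:
            cov[lo - win_lo : hi - win_lo] = True
    up = cov[:FLANK]
    body = cov[FLANK : FLANK + (xe - xs)]
    down = cov[FLANK + (xe - xs) :]
    if exon.strand == "-":
        up, down = down[::-1], up[::-1]
        body = body[::-1]
    edges = np.linspace(0, len(body), N_EXON_BINS + 1)
    bins = np.array(
        [body[int(edges[i]) : max(int(edges[i]) + 1, int(edges[i + 1]))].any() for i in range(N_EXON_BINS)],
        dtype=float,
    )
    return np.concatenate([up.astype(float), bins, down.astype(float)])


def binding_profile(
    exons: Sequence,
    peakset: PeakSet,
    qualifying_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Fraction of group exons with a peak of this RBP at each of the 850
    positions.  Only exons >=50 bp (and, when ``qualifying_ids`` is given,
    in that set — typically exons with >=1 binding site of any RBP)
    contribute."""
    qual = set(qualifying_ids) if qualifying_ids is not None else None
    group = [
        e
        for e in exons
        if e.end - e.start >= MIN_PROFILE_EXON_LEN and (qual is None or e.exon_id in qual)
    ]
    if not group:
        raise ValueError("no qualifying exons (>=50 bp with binding sites) in group")
    acc = np.zeros(PROFILE_LEN)
    for e in group:
        acc += _exon_coverage_profile(e, peakset.on(e.chrom))
    return acc / len(group)


def profile_divergence(
    exons: Sequence,
    peaksets: Mapping[str, PeakSet],
    psi_wide: pd.DataFrame,
    psi_threshold: float = 0.5,
) -> tuple:
    """Per-RBP binding-profile divergence between variable and non-variable
    exons, with the paired cell-type comparison.

    For each cell type, exons are split into variable / non-variable (|delta
    PSI| > 0.25) and high / low PSI (threshold 0.5); the mean squared error
    between the variable and non-variable profile is computed per RBP for
    the high and low strata separately (four comparisons per RBP).  The
    neuron and glia MSE distributions are then compared with a two-sided
    paired Wilcoxon signed-rank test over (RBP, stratum) pairs.

    Returns (divergence DataFrame, test dict).
    """
    info = psi_wide.set_index("exon_id")
    exons = [e for e in exons if e.exon_id in info.index]
    fm_any = {
        e.exon_id: any(
            assign_category(iv, e) is not None
            for ps in peaksets.values()
            for iv in ps.on(e.chrom)
        )
        for e in exons
    }
    qualifying = {eid for eid, has in fm_any.items() if has}

    def group(cell_type: str, variable: bool, high: bool) -> list:
        psi_col = f"psi_{cell_type}"
        ids = []
        for e in exons:
            row = info.loc[e.exon_id]
            if pd.isna(row["delta_psi"]) or pd.isna(row[psi_col]):
                continue
            is_var = abs(row["delta_psi"]) > 0.25
            is_high = row[psi_col] >= psi_threshold
            if is_var == variable and is_high == high:
                ids.append(e.exon_id)
        return ids

    groups = {
        (ct, var, hi): set(group(ct, var, hi))
        for ct in CELL_TYPES
        for var in (True, False)
        for hi in (True, False)
    }
    rows = []
    for rbp, ps in peaksets.items():
        for hi in (True, False):
            rec = {"rbp": rbp, "stratum": "high" if hi else "low"}
            ok = True
            for ct in CELL_TYPES:
                try:
                    var_prof = binding_profile(
                        [e for e in exons if e.exon_id in groups[(ct, True, hi)]], ps, qualifying
                    )
                    nonvar_prof = binding_profile(
                        [e for e in exons if e.exon_id in groups[(ct, False, hi)]], ps, qualifying
                    )
                except ValueError:
                    logger.info("skipping %s (%s stratum): empty group", rbp, rec["stratum"])
                    ok = False
                    break
                rec[f"mse_{ct}"] = float(np.mean((var_prof - nonvar_prof) ** 2))
            if ok:
                rows.append(rec)
    div = pd.DataFrame(rows)
    test: dict = {"n_pairs": len(div)}
    if len(div) >= 10:
        res = stats.wilcoxon(div["mse_neuron"], div["mse_glia"], alternative="two-sided")
        test.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    return div, test


def write_feature_matrix(fm: pd.DataFrame, path) -> None:
    fm.to_csv(path, sep="\t", index_label="exon_id")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="exon_id")
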