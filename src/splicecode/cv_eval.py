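"""Gene-grouped cross-validation, rank-correlation evaluation and
subgroup error analyses.

Folds are built over groups (connected components of gene + homolog edges)
so that exons of one gene — and homologous genes, when a homolog map is
supplied — always share a test fold.  The headline metric is the per-fold
Spearman correlation between true and predicted PSI and its median across
folds; subgroup analyses report MSE for exon-length, frame-consistency,
intron-length and exon-density strata.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LENGTH_GROUPS = ((None, 27, "<=27"), (28, 100, "28-100"), (101, 200, "101-200"), (201, None, ">200"))
INTRON_GROUPS = ((None, 100, "<101"), (101, 1000, "101-1000"), (1001, None, ">1000"))


def make_folds(
    exon_genes: Mapping[str, str] | pd.Series,
    k: int = 10,
    seed: int = 0,
    homolog_map: Mapping[str, str] | None = None,
) -> pd.Series:
    """Assign exons to k folds, keeping genes (and homolog clusters) intact.

    ``exon_genes`` maps exon_id -> gene_id; ``homolog_map`` maps gene_id ->
    cluster id for genes that must share a fold.  Groups are distributed
    greedily, largest first, onto the currently smallest fold; ties are
    broken by a seeded shuffle, so the assignment is deterministic.
    """
    genes = pd.Series(exon_genes)
    homolog_map = homolog_map or {}
    group_of = {g: homolog_map.get(g, g) for g in genes.unique()}
    group_sizes: dict = {}
    for eid, g in genes.items():
        grp = group_of[g]
        group_sizes[grp] = group_sizes.get(grp, 0) + 1
    if k > len(group_sizes):
        raise ValueError(f"k={k} exceeds the number of gene groups ({len(group_sizes)})")
    rng = np.random.default_rng(seed)
    order = sorted(group_sizes)
    rng.shuffle(order)
    order.sort(key=lambda g: -group_sizes[g])
    fold_load = np.zeros(k, dtype=int)
    fold_of_group = {}
    for grp in order:
        f = int(np.argmin(fold_load))
        fold_of_group[grp] = f + 1
        fold_load[f] += group_sizes[grp]
    return pd.Series({eid: fold_of_group[group_of[g]] for eid, g in genes.items()}, name="fold")


def spearman_eval(
    y_true: pd.Series,
    y_pred: pd.Series,
    folds: pd.Series,
    subset: Sequence[str] | None = None,
) -> dict:
    """Per-fold Spearman correlation and its median across folds.

    Folds with < 3 usable pairs or a constant vector yield NaN and are
    excluded from the median.
    """
    ids = y_true.index.intersection(y_pred.index)
    if subset is not None:
        ids = ids.intersection(pd.Index(subset))
    per_fold = {}
    for fold in sorted(folds.loc[folds.index.intersection(ids)].unique()):
        fid = folds.index[folds == fold].intersection(ids)
        t, p = y_true.loc[fid], y_pred.loc[fid]
        ok = t.notna() & p.notna()
        t, p = t[ok], p[ok]
        if len(t) < 3 or t.nunique() == 1 or p.nunique() == 1:
            per_fold[fold] = np.nan
            continue
        per_fold[fold] = float(stats.spearmanr(t, p).statistic)
    vals = [v for v in per_fold.values() if not np.isnan(v)]
    return {
        "per_fold": per_fold,
        "median": float(np.median(vals)) if vals else np.nan,
        "n": int(len(ids)),
    }


def exon_metadata(annotation: pd.DataFrame, exons: Sequence, window: int = 6144) -> pd.DataFrame:
    """Length/frame/intron/density metadata per cassette exon."""
    rows = []
    for e in exons:
        sub = annotation[annotation["chrom"] == e.chrom]
        if e.strand == "+":
            up_intron = e.start - e.acc_flank[1]
            down_intron = e.don_flank[0] - e.end
        else:
            up_intron = e.acc_flank[0] - e.end
            down_intron = e.start - e.don_flank[1]
        c = (e.start + e.end) // 2
        w_lo, w_hi = c - window // 2, c + window // 2
        n_in_window = int(((sub["end"] > w_lo) & (sub["start"] < w_hi)).sum())
        rows.append(
            {
                "exon_id": e.exon_id,
                "length": e.length,
                "length_group": _bucket(e.length, LENGTH_GROUPS),
                "frame_consistent": e.length % 3 == 0,
                "upstream_intron_group": _bucket(up_intron, INTRON_GROUPS),
                "downstream_intron_group": _bucket(down_intron, INTRON_GROUPS),
                "n_exons_in_window": n_in_window,
            }
        )
    return pd.DataFrame(rows).set_index("exon_id")


def _bucket(value: int, groups) -> str:
    for lo, hi, label in groups:
        if (lo is None or value >= lo) and (hi is None or value <= hi):
            return label
    raise ValueError(f"value {value} fits no group")


def subgroup_mse(
    y_true: pd.Series, y_pred: pd.Series, metadata: pd.DataFrame, by: str
) -> pd.Series:
    """MSE per subgroup of ``metadata[by]``; empty groups are NaN."""
    ids = y_true.index.intersection(y_pred.index).intersection(metadata.index)
    err = (y_true.loc[ids] - y_pred.loc[ids]) ** 2
    grouped = err.groupby(metadata.loc[ids, by], observed=False).mean()
    return grouped.rename(f"mse_by_{by}")


# thin named wrappers so distribution comparisons are scriptable ------------


def ks_test(a, b) -> dict:
    r = stats.ks_2samp(a, b, alternative="two-sided")
    return {"statistic": float(r.statistic), "p_value": float(r.pvalue)}


def ranksum_test(a, b) -> dict:
    r = stats.ranksums(a, b)
    return {"statistic": float(r.statistic), "p_value": float(r.pvalue)}


def signed_rank_test(a, b) -> dict:
    r = stats.wilcoxon(a, b, alternative="two-sided")
    return {"statistic": float(r.statistic), "p_value": float(r.pvalue)}


def fisher_test(table) -> dict:
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return {"odds_ratio": float(odds), "p_value": float(p)}
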