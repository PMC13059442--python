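"""In-silico saturation mutagenesis (ISM) and downstream summaries.

For every window position p and nucleotide n the model predicts PSI with n
substituted at p; the ISM score subtracts the per-position mean:

    ISM[p, n] = psi_pred(p -> n) - (1/4) * sum over i in {A,C,G,T} psi_pred(p -> i)

so the four scores at a position always sum to zero.  Predictions are
averaged over replicate runs before differencing.  Only the nucleotide
one-hot channels are mutated; splice-site and RBP channels stay fixed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seqs
from .seq_model import InputWindow, SeqPsiModel, predict_seq

NEIGHBOR_FLANK = 150  # bp around a neighboring exon scanned for high scores
MIN_STRAND_SEQS = 25  # strand-consistency threshold for motif-discovery export


def ism(
    replicates: Sequence[SeqPsiModel],
    window: InputWindow,
    head: str = "default",
    chunk: int = 64,
) -> np.ndarray:
    """(window, 4) ISM matrix, run-averaged.

    Mutants are evaluated in chunks of positions; results are independent
    of the chunking.  Returns scores ordered A, C, G, T per position.
    """
    W = window.x.shape[0]
    preds = np.zeros((W, 4))
    base = window.x
    for lo in range(0, W, chunk):
        hi = min(lo + chunk, W)
        npos = hi - lo
        batch = np.repeat(base[None, :, :], npos * 4, axis=0)
        for i, p in enumerate(range(lo, hi)):
            for n in range(4):
                row = batch[i * 4 + n]
                row[p, :4] = 0.0
                row[p, n] = 1.0
        out = predict_seq(replicates, batch, head=head)
        preds[lo:hi] = out.reshape(npos, 4)
    return preds - preds.mean(axis=1, keepdims=True)


def ism_for_exons(
    replicates_by_fold,
    windows: Sequence[InputWindow],
    folds: pd.Series | None = None,
    head: str = "default",
) -> dict:
    """ISM per exon, using the replicate set of the fold where the exon was
    held out (``replicates_by_fold`` may also be a single replicate list)."""
    out = {}
    for w in windows:
        if folds is not None and isinstance(replicates_by_fold, dict):
            reps = replicates_by_fold[folds.loc[w.exon_id]]
        else:
            reps = replicates_by_fold
        out[w.exon_id] = ism(reps, w, head=head)
    return out


def _rescale_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of ``values`` over ``n_bins`` equal-width segments."""
    if len(values) == 0:
        return np.full(n_bins, np.nan)
    edges = np.linspace(0, len(values), n_bins + 1).astype(int)
    return np.array(
        [values[edges[i] : max(edges[i] + 1, edges[i + 1])].mean() for i in range(n_bins)]
    )


def ism_profile(
    matrices: dict,
    windows: Sequence[InputWindow],
    exon_bins: int = 300,
    flank_bins: int = 300,
) -> dict:
    """Aggregate |ISM| traces for upstream flank, exon body and downstream
    flank, each rescaled per exon into fixed bins before averaging."""
    if not matrices:
        raise ValueError("need >=1 ISM matrix")
    ups, bodies, downs = [], [], []
    for w in windows:
        m = np.abs(matrices[w.exon_id]).mean(axis=1)
        s, e = w.exon_span
        ups.append(_rescale_bins(m[:s], flank_bins))
        bodies.append(_rescale_bins(m[s:e], exon_bins))
        downs.append(_rescale_bins(m[e:], flank_bins))
    return {
        "upstream": np.nanmean(ups, axis=0),
        "exon": np.nanmean(bodies, axis=0),
        "downstream": np.nanmean(downs, axis=0),
    }


def neighbor_exon_scores(
    matrix: np.ndarray,
    window: InputWindow,
    annotation: pd.DataFrame,
    flank: int = NEIGHBOR_FLANK,
) -> pd.DataFrame:
    """Max |ISM| inside each neighboring exon +/- ``flank`` bp, ranked.

    Neighbors are annotated exons (other than the exon of interest) that
    overlap the window; their genomic intervals are mapped into window
    coordinates, strand-aware.  Empty result if no neighbor is in range.
    """
    W = matrix.shape[0]
    ws = window.win_start
    sub = annotation[
        (annotation["chrom"] == window.chrom)
        & (annotation["end"] > ws)
        & (annotation["start"] < ws + W)
        & (annotation["exon_id"] != window.exon_id)
    ]
    scores = np.abs(matrix).max(axis=1)
    rows = []
    for _, ex in sub.iterrows():
        a, b = int(ex["start"]) - ws, int(ex["end"]) - ws
        if window.strand == "-":
            a, b = W - b, W - a
        lo, hi = max(a - flank, 0), min(b + flank, W)
        if hi <= lo:
            continue
        rows.append(
            {
                "exon_id": window.exon_id,
                "neighbor_id": ex["exon_id"],
                "max_abs_ism": float(scores[lo:hi].max()),
            }
        )
    df = pd.DataFrame(rows, columns=["exon_id", "neighbor_id", "max_abs_ism"])
    return df.sort_values("max_abs_ism", ascending=False).reset_index(drop=True)


def top_neighbor_pairs(per_exon_tables: Sequence[pd.DataFrame], top_k: int = 10) -> pd.DataFrame:
    """Pool neighbor tables and keep the top-k (exon, neighbor) pairs by
    score — the candidates for the coordination follow-up."""
    pooled = pd.concat(per_exon_tables, ignore_index=True)
    return pooled.sort_values("max_abs_ism", ascending=False).head(top_k).reset_index(drop=True)


def export_scores(matrices: dict, windows: Sequence[InputWindow], outdir) -> Path:
    """Write one-hot sequences and ISM arrays for external motif discovery.

    Layout: ``ism_scores.npz`` with arrays ``onehot`` (n, window, 4) and
    ``scores`` (n, window, 4), a per-exon TSV (position, A, C, G, T,
    ref_base), and ``metadata.json`` recording the exon order and the
    strand-consistency threshold (>=25 sequences) used downstream.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = {matrices[w.exon_id].shape[0] for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent window lengths: {sorted(lengths)}")
    onehots = np.stack([_seqs.one_hot(w.codes) for w in windows])
    scores = np.stack([matrices[w.exon_id] for w in windows])
    np.savez(outdir / "ism_scores.npz", onehot=onehots, scores=scores)
    for w in windows:
        m = matrices[w.exon_id]
        df = pd.DataFrame(m, columns=list(_seqs.BASES))
        df.insert(0, "position", np.arange(m.shape[0]))
        df["ref_base"] = list(_seqs.decode(w.codes))
        df.to_csv(outdir / f"{w.exon_id}.ism.tsv", sep="\t", index=False)
    meta = {
        "exon_ids": [w.exon_id for w in windows],
        "window": int(next(iter(lengths))),
        "min_strand_sequences": MIN_STRAND_SEQS,
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return outdir / "ism_scores.npz"
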