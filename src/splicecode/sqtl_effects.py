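"""Splicing-QTL effect prediction and sign-concordance analysis.

Variants are linked to introns with a signed intron-excision slope.  For
the best (lowest-p) variants of each intron whose intron spans a measured
exon, the model predicts PSI with the reference and the alternative allele
substituted in the exon's input window; the difference

    dISM(alt - ref) = psi_pred(alt) - psi_pred(ref)

(averaged over replicate runs before differencing) is the predicted effect.
A variant carries an effect when |dISM| > 0.005.  Because a negative slope
means less intron excision — more exon inclusion — the expected relation is
slope < 0 <=> dISM > 0; concordance is evaluated among effect-carrying
variants, and for exons with several such variants the largest |dISM| is
the prioritized call.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seqs
from .seq_model import InputWindow, SeqPsiModel, predict_seq

EFFECT_THRESHOLD = 0.005


@dataclasses.dataclass
class VariantEffect:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    slope: float
    exon_id: str
    delta_ism: float
    distance_to_splice_site: int
    in_exon: bool

    @property
    def has_effect(self) -> bool:
        return abs(self.delta_ism) > EFFECT_THRESHOLD

    @property
    def expected_sign(self) -> int:
        return 1 if self.slope < 0 else -1

    @property
    def concordant(self) -> bool | None:
        if not self.has_effect:
            return None
        return int(np.sign(self.delta_ism)) == self.expected_sign


def split_multiallelic(variants: pd.DataFrame) -> pd.DataFrame:
    """Expand comma-separated ALT alleles into biallelic rows."""
    rows = []
    for _, v in variants.iterrows():
        for alt in str(v["alt"]).split(","):
            r = v.copy()
            r["alt"] = alt
            rows.append(r)
    return pd.DataFrame(rows).reset_index(drop=True)


def select_best_variants(
    variants: pd.DataFrame,
    exons: Sequence,
    window: int,
) -> pd.DataFrame:
    """Filter to minimal-p variants per intron, linked to a measured exon.

    The intron must span an exon in the given list and the variant must
    fall inside that exon's model window; dropped rows get a ``reason``
    (kept rows have reason 'kept').
    """
    df = split_multiallelic(variants).copy()
    if (df["ref"] == df["alt"]).any():
        raise ValueError("variant with ref == alt")
    exon_by_id = {e.exon_id: e for e in exons}
    reasons = []
    linked = []
    for _, v in df.iterrows():
        exon = exon_by_id.get(v.get("exon_id"))
        if exon is None:
            # fall back to containment: intron interval spans the exon
            for e in exons:
                if (
                    e.chrom == v["chrom"]
                    and v["intron_start"] <= e.start
                    and e.end <= v["intron_end"]
                ):
                    exon = e
                    break
        if exon is None:
            reasons.append("no_spanning_exon")
            linked.append(None)
            continue
        center = (exon.start + exon.end) // 2
        pos0 = int(v["pos"]) - 1
        ws = center - window // 2
        if not (ws <= pos0 < ws + window):
            reasons.append("out_of_range")
            linked.append(exon.exon_id)
            continue
        reasons.append("kept")
        linked.append(exon.exon_id)
    df["reason"] = reasons
    df["exon_id"] = linked
    kept = df[df["reason"] == "kept"].copy()
    if len(kept):
        intron_key = (
            kept[["chrom", "intron_start", "intron_end"]].astype(str).agg(":".join, axis=1)
        )
        best_p = kept.groupby(intron_key)["pval"].transform("min")
        kept = kept[kept["pval"] == best_p]
    dropped = df[df["reason"] != "kept"]
    return pd.concat([kept, dropped], ignore_index=True)


def delta_ism(
    replicates: Sequence[SeqPsiModel],
    window: InputWindow,
    variant: Mapping,
    head: str = "default",
) -> VariantEffect:
    """Predicted effect of one variant on its exon's inclusion.

    Alleles are given on the plus strand; for minus-strand windows the
    position is mirrored and the alleles complemented.  Errors out if the
    window's reference base does not match the stated REF allele.
    """
    pos0 = int(variant["pos"]) - 1
    ref, alt = str(variant["ref"]).upper(), str(variant["alt"]).upper()
    if ref == alt:
        raise ValueError("variant with ref == alt")
    W = window.x.shape[0]
    p = pos0 - window.win_start
    if not (0 <= p < W):
        raise ValueError(f"variant position {pos0 + 1} outside window of {window.exon_id}")
    if window.strand == "-":
        p = W - 1 - p
        ref = _seqs.complement_base(ref)
        alt = _seqs.complement_base(alt)
    obs = int(window.codes[p])
    if obs > 3 or _seqs.BASES[obs] != ref:
        observed = "N" if obs > 3 else _seqs.BASES[obs]
        raise ValueError(
            f"reference mismatch at {variant['chrom']}:{variant['pos']}: "
            f"window has {observed}, variant says {ref}"
        )
    x_ref = window.x[None, :, :]
    x_alt = window.x.copy()
    x_alt[p, :4] = 0.0
    x_alt[p, _seqs.BASES.index(alt)] = 1.0
    pred_ref = float(predict_seq(replicates, x_ref, head=head)[0])
    pred_alt = float(predict_seq(replicates, x_alt[None, :, :], head=head)[0])
    s, e = window.exon_span
    dist = min(abs(p - s), abs(p - (e - 1)))
    return VariantEffect(
        chrom=str(variant["chrom"]),
        pos=int(variant["pos"]),
        ref=str(variant["ref"]),
        alt=str(variant["alt"]),
        slope=float(variant["slope"]),
        exon_id=window.exon_id,
        delta_ism=pred_alt - pred_ref,
        distance_to_splice_site=int(dist),
        in_exon=bool(s <= p < e),
    )


def effects_table(effects: Sequence[VariantEffect]) -> pd.DataFrame:
    rows = []
    for ef in effects:
        rows.append(
            {
                "chrom": ef.chrom,
                "pos": ef.pos,
                "ref": ef.ref,
                "alt": ef.alt,
                "exon_id": ef.exon_id,
                "slope": ef.slope,
                "delta_ism": ef.delta_ism,
                "has_effect": ef.has_effect,
                "expected_sign": ef.expected_sign,
                "concordant": ef.concordant,
                "distance_to_splice_site": ef.distance_to_splice_site,
                "in_exon": ef.in_exon,
            }
        )
    return pd.DataFrame(rows)


def concordance_report(effects: Sequence[VariantEffect] | pd.DataFrame) -> dict:
    """Quadrant counts, concordance among effect-carrying variants, and the
    per-exon prioritized call (largest |dISM|)."""
    df = effects if isinstance(effects, pd.DataFrame) else effects_table(effects)
    if df.empty:
        raise ValueError("no variant effects to report")
    eff = df[df["has_effect"]]
    quad = {
        "neg_slope_pos_dism": int(((df["slope"] < 0) & (df["delta_ism"] > 0)).sum()),
        "neg_slope_neg_dism": int(((df["slope"] < 0) & (df["delta_ism"] < 0)).sum()),
        "pos_slope_pos_dism": int(((df["slope"] > 0) & (df["delta_ism"] > 0)).sum()),
        "pos_slope_neg_dism": int(((df["slope"] > 0) & (df["delta_ism"] < 0)).sum()),
    }
    prioritized = (
        eff.loc[eff.groupby("exon_id")["delta_ism"].apply(lambda s: s.abs().idxmax())]
        if len(eff)
        else eff
    )
    return {
        "n_variants": int(len(df)),
        "n_effect": int(len(eff)),
        "n_concordant": int(eff["concordant"].sum()) if len(eff) else 0,
        "concordance": float(eff["concordant"].mean()) if len(eff) else np.nan,
        "quadrants": quad,
        "prioritized": prioritized.reset_index(drop=True),
    }


def read_variants(path) -> pd.DataFrame:
    """VCF-like TSV with columns chrom, pos, ref, alt, intron_start,
    intron_end, slope, pval (case-insensitive header accepted)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower().lstrip("#") for c in df.columns]
    return df
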