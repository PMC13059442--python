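"""Sequence-based PSI predictor: convolutional + recurrent trunk.

The input is a fixed-length nucleotide window (default 6,144 bp) with the
exon of interest centered, read in transcription orientation.  Channels:
4 one-hot nucleotide channels, an optional splice-site channel marking the
exon's start and end, and optionally one presence channel per RBP peak
track.  The trunk is a stack of 1-D convolution blocks (conv -> ReLU ->
2x max pool) followed by a GRU scanned across the downsampled positions;
per-dataset dense heads end in a sigmoid, so multiple datasets can share
the trunk while keeping their own output layer.  Training minimizes binary
cross-entropy on continuous PSI targets with Adam and early stopping; test
predictions are averaged over independently seeded replicate runs.

The full-scale default (window 6,144, 6 conv blocks, 64 filters, hidden 64)
is configurable; tests and examples use a small desk-scale preset.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _nn, _seqs
from .rbp_features import PeakSet

DEFAULT_WINDOW = 6144


@dataclasses.dataclass
class SeqModelConfig:
    window: int = DEFAULT_WINDOW
    n_conv_blocks: int = 6
    conv_width: int = 5
    n_filters: int = 64
    hidden: int = 64
    heads: tuple = ("default",)
    channels: tuple = ("seq", "splice")  # subset of {"seq","splice","rbp"}
    rbp_names: tuple = ()
    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 3e-3
    weight_decay: float = 1e-4
    val_fraction: float = 0.1
    patience: int = 5
    runs_per_fold: int = 5

    def __post_init__(self):
        if self.n_conv_blocks < 1:
            raise ValueError("need >=1 conv block")
        if not self.heads:
            raise ValueError("need >=1 head")
        if "seq" not in self.channels and "rbp" not in self.channels:
            raise ValueError("channels must include 'seq' and/or 'rbp'")

    @property
    def n_channels(self) -> int:
        n = 0
        if "seq" in self.channels:
            n += 4
        if "splice" in self.channels:
            n += 1
        if "rbp" in self.channels:
            n += len(self.rbp_names)
        return n


def desk_config(**overrides) -> SeqModelConfig:
    """Small preset for single-CPU runs: 512 bp window, 2 conv blocks."""
    base = dict(
        window=512, n_conv_blocks=2, n_filters=40, hidden=24, conv_width=9,
        epochs=30, patience=15, weight_decay=3e-4,
    )
    base.update(overrides)
    return SeqModelConfig(**base)


# ---------------------------------------------------------------------------
# input windows
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class InputWindow:
    """Channel stack for one exon, transcript orientation.

    x is (window, n_channels); exon_span is the [start, end) of the exon in
    window coordinates; win_start is the genomic coordinate of window
    position 0 *before* any strand flip (minus-strand windows are stored
    reverse-complemented).
    """

    exon_id: str
    x: np.ndarray
    exon_span: tuple
    chrom: str
    strand: str
    win_start: int
    codes: np.ndarray  # uint8 nucleotide codes, transcript orientation


def build_input(
    genome: Mapping[str, np.ndarray],
    exon,
    config: SeqModelConfig,
    peaksets: Mapping[str, PeakSet] | None = None,
) -> InputWindow:
    """Build the centered channel stack for one exon.

    The window center ``window//2`` sits at floor((start+end)/2); sequence
    beyond chromosome ends is zero-padded.  On minus-strand exons the whole
    stack is flipped to transcript orientation (one-hot complemented).
    """
    W = config.window
    xs, xe = int(exon.start), int(exon.end)
    L = xe - xs
    if L > W:
        raise ValueError(f"exon {exon.exon_id} ({L} bp) longer than window ({W})")
    center = (xs + xe) // 2
    ws = center - W // 2
    chrom_seq = genome[exon.chrom]
    codes = np.full(W, _seqs.PAD, dtype=np.uint8)
    lo, hi = max(ws, 0), min(ws + W, len(chrom_seq))
    if hi > lo:
        codes[lo - ws : hi - ws] = chrom_seq[lo:hi]
    # exon span in plus-orientation window coordinates
    span = (xs - ws, xe - ws)
    rbp_cov = None
    if "rbp" in config.channels:
        rbp_cov = np.zeros((W, len(config.rbp_names)), dtype=np.float32)
        for j, rbp in enumerate(config.rbp_names):
            ps = peaksets[rbp] if peaksets else None
            for s, e in ps.on(exon.chrom) if ps else []:
                a, b = max(s, ws) - ws, min(e, ws + W) - ws
                if b > a:
                    rbp_cov[a:b, j] = 1.0
    if exon.strand == "-":
        codes = _seqs.revcomp(codes)
        span = (W - span[1], W - span[0])
        if rbp_cov is not None:
            rbp_cov = rbp_cov[::-1]
    parts = []
    if "seq" in config.channels:
        parts.append(_seqs.one_hot(codes))
    if "splice" in config.channels:
        splice = np.zeros((W, 1), dtype=np.float32)
        splice[span[0], 0] = 1.0
        splice[min(span[1], W - 1), 0] = 1.0
        parts.append(splice)
    if rbp_cov is not None:
        parts.append(rbp_cov)
    x = np.concatenate(parts, axis=1)
    return InputWindow(
        exon_id=exon.exon_id,
        x=x,
        exon_span=span,
        chrom=exon.chrom,
        strand=exon.strand,
        win_start=ws,
        codes=codes,
    )


def stack_windows(windows: Sequence[InputWindow]) -> np.ndarray:
    return np.stack([w.x for w in windows])


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class SeqPsiModel:
    """Conv blocks -> GRU, with a dual readout into per-head dense + sigmoid.

    The dense head reads the concatenation of (a) the position-wise max of
    the final conv-block activations — sharp credit assignment for local
    motifs anywhere in the window — and (b) the positional mean of the GRU
    hidden states scanning those activations, which carries longer-range,
    order-sensitive structure.
    """

    def __init__(self, config: SeqModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks = []
        c = config.n_channels
        for _ in range(config.n_conv_blocks):
            self.blocks.append(
                (
                    _nn.Conv1D(c, config.n_filters, config.conv_width, rng),
                    _nn.ReLU(),
                    _nn.MaxPool1D(2),
                )
            )
            c = config.n_filters
        self.gru = _nn.GRU(c, config.hidden, rng)
        self.heads = {
            h: _nn.Dense(config.n_filters + config.hidden, 1, rng) for h in config.heads
        }

    def params(self):
        out = []
        for conv, _r, _p in self.blocks:
            out += conv.params()
        out += self.gru.params()
        for head in self.heads.values():
            out += head.params()
        return out

    def forward(self, x: np.ndarray, head: str = "default") -> np.ndarray:
        """(B, L, C) -> predicted PSI in (0, 1), shape (B,)."""
        h = np.ascontiguousarray(x, dtype=np.float32)
        for conv, relu, pool in self.blocks:
            h = pool.forward(relu.forward(conv.forward(h)))
        self._conv_out_shape = h.shape
        self._conv_argmax = h.argmax(axis=1)
        conv_max = h.max(axis=1)
        states = self.gru.forward(h)  # (B, L', H)
        self._n_steps = states.shape[1]
        pooled = np.concatenate([conv_max, states.mean(axis=1)], axis=1)
        logit = self.heads[head].forward(pooled)[:, 0]
        return _nn.sigmoid(logit)

    def backward(self, dlogit: np.ndarray, head: str = "default") -> None:
        dpooled = self.heads[head].backward(dlogit[:, None])
        F = self.config.n_filters
        dmax, dmean = dpooled[:, :F], dpooled[:, F:]
        dstates = np.repeat(dmean[:, None, :], self._n_steps, axis=1) / self._n_steps
        dh = self.gru.backward(dstates)
        B, L, C = self._conv_out_shape
        bi, ci = np.ogrid[:B, :C]
        dh[bi, self._conv_argmax, ci] += dmax
        for conv, relu, pool in reversed(self.blocks):
            dh = conv.backward(relu.backward(pool.backward(dh)))

    def predict(self, X: np.ndarray, head: str = "default", batch_size: int = 256) -> np.ndarray:
        """Deterministic batched prediction (independent of the batch split)."""
        out = np.empty(len(X))
        for lo in range(0, len(X), batch_size):
            out[lo : lo + batch_size] = self.forward(X[lo : lo + batch_size], head)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """npz of all weights plus a JSON sidecar holding the config."""
        arrays = {f"p{i}": w for i, (w, _g) in enumerate(self.params())}
        np.savez(path, **arrays)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SeqPsiModel":
        with open(str(path) + ".json") as fh:
            cfg = json.load(fh)
        for key in ("heads", "channels", "rbp_names"):
            cfg[key] = tuple(cfg[key])
        model = cls(SeqModelConfig(**cfg))
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        for i, (w, _g) in enumerate(model.params()):
            w[...] = data[f"p{i}"]
        return model


def train_seq_model(
    X: np.ndarray,
    y: np.ndarray,
    config: SeqModelConfig,
    seed: int = 0,
    heads: Sequence[str] | None = None,
) -> SeqPsiModel:
    """Train one model with Adam + early stopping on a validation split.

    ``heads`` optionally labels each sample with its dataset; batches are
    drawn within a head so the shared trunk sees every dataset while each
    dense head only trains on its own samples.
    """
    y = np.asarray(y, dtype=np.float64)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("targets must lie in [0, 1]")
    if X.shape[1] != config.window or X.shape[2] != config.n_channels:
        raise ValueError(
            f"window/channel mismatch: got {X.shape[1:]}, expected "
            f"({config.window}, {config.n_channels})"
        )
    heads = np.asarray(heads if heads is not None else [config.heads[0]] * len(X))
    rng = np.random.default_rng(seed)
    model = SeqPsiModel(config, seed=int(rng.integers(2**31)))
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    n = len(X)
    n_val = int(round(n * config.val_fraction)) if n >= 30 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    best_loss, best_weights, stall = np.inf, None, 0
    for _epoch in range(config.epochs):
        batches = []
        for head in np.unique(heads[tr_idx]):
            ids = tr_idx[heads[tr_idx] == head]
            ids = ids[rng.permutation(len(ids))]
            batches += [
                (head, ids[lo : lo + config.batch_size])
                for lo in range(0, len(ids), config.batch_size)
            ]
        order = rng.permutation(len(batches))
        for bi in order:
            head, ids = batches[bi]
            opt.zero_grad()
            p = model.forward(X[ids], head=head)
            _loss, dlogit = _nn.bce_loss(p, y[ids])
            model.backward(dlogit.astype(np.float32), head=head)
            if config.weight_decay:
                # decay weight matrices only; biases stay unpenalized
                for w, grad in model.params():
                    if w.ndim >= 2:
                        grad += config.weight_decay * w
            opt.step()
        if n_val:
            val_loss = 0.0
            for head in np.unique(heads[val_idx]):
                ids = val_idx[heads[val_idx] == head]
                p = model.predict(X[ids], head=head)
                val_loss += _nn.bce_loss(p, y[ids])[0] * len(ids)
            val_loss /= n_val
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_weights = [w.copy() for w, _g in model.params()]
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if best_weights is not None:
        for (w, _g), saved in zip(model.params(), best_weights):
            w[...] = saved
    return model


def train_replicates(
    X: np.ndarray,
    y: np.ndarray,
    config: SeqModelConfig,
    seed: int = 0,
    n_runs: int | None = None,
    heads: Sequence[str] | None = None,
) -> list:
    """Independently seeded replicate fits (the per-fold "runs")."""
    n_runs = n_runs if n_runs is not None else config.runs_per_fold
    rng = np.random.default_rng(seed)
    return [
        train_seq_model(X, y, config, seed=int(rng.integers(2**31)), heads=heads)
        for _ in range(n_runs)
    ]


def predict_seq(
    replicates: Sequence[SeqPsiModel], X: np.ndarray, head: str = "default"
) -> np.ndarray:
    """Mean prediction across replicate runs; each in (0, 1)."""
    if not replicates:
        raise ValueError("need >=1 replicate")
    return np.mean([m.predict(X, head=head) for m in replicates], axis=0)
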