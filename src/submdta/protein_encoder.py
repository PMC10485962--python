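"""Multi-scale n-gram BiLSTM protein encoder.

A protein sequence is tokenized into overlapping n-grams (stride 1) at
three scales n = 2, 3, 4.  Each n-gram maps to an integer index by
positional base-|Sigma| encoding over a 25-letter alphabet (20 standard
residues + B, Z, U, O, with X as the unknown symbol); the full table is
kept for n = 2 and n = 3, while the n = 4 space (25^4 ~ 390k) is hashed
into a fixed number of buckets by reducing the positional code modulo the
bucket count.  Each scale has its own embedding table (standard-normal
initialized) and one BiLSTM layer; per step the forward and backward
hidden states are concatenated, a global max over time pools the sequence
(padded positions excluded), and the three pooled vectors are concatenated
in order n = 2, 3, 4, giving a representation of length 3 x 2H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Parameter, Tensor, concatenate, stack
from .mol_io import AMINO_ALPHABET, UNKNOWN_RESIDUE, normalize_sequence

__all__ = ["NGramTokens", "ProteinConfig", "ProteinParams", "ngram_tokenize",
           "encode_protein_scale", "encode_protein_multiscale",
           "encode_protein_batch", "NGRAM_SIZES", "NGRAM_HASH_BUCKETS"]

ALPHABET = AMINO_ALPHABET + UNKNOWN_RESIDUE  # 25 symbols, X last
_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}
NGRAM_SIZES = (2, 3, 4)
NGRAM_HASH_BUCKETS = 16384  # n=4 vocabulary is hashed into this many slots


def vocabulary_size(n: int) -> int:
    if n in (2, 3):
        return len(ALPHABET) ** n
    if n == 4:
        return NGRAM_HASH_BUCKETS
    raise ValueError(f"unsupported n-gram size {n}")


@dataclass(frozen=True)
class NGramTokens:
    """Integer token sequence of one protein at one n-gram scale."""

    n: int
    indices: np.ndarray  # (source_length - n + 1,) int64
    source_length: int


def ngram_tokenize(sequence: str, n: int) -> NGramTokens:
    """Overlapping n-gram windows, stride 1, positionally base-25 encoded.

    Characters outside the alphabet are normalized to X first.  For n = 4
    the positional code is reduced modulo the hash-bucket count.
    """
    if n not in NGRAM_SIZES:
        raise ValueError(f"unsupported n-gram size {n}")
    seq = normalize_sequence(sequence)
    if len(seq) < n:
        raise ValueError(f"sequence {sequence!r} shorter than n-gram size {n}")
    codes = np.array([_CHAR_INDEX[c] for c in seq], dtype=np.int64)
    base = len(ALPHABET)
    idx = np.zeros(len(seq) - n + 1, dtype=np.int64)
    for k in range(n):
        idx = idx * base + codes[k:len(seq) - n + 1 + k]
    if n == 4:
        idx = idx % NGRAM_HASH_BUCKETS
    return NGramTokens(n=n, indices=idx, source_length=len(seq))


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinConfig:
    embed_dim: int = 128
    hidden: int = 64       # per-direction LSTM width H; output is 3 * 2H
    max_len: int = 1200    # token truncation per scale


class _ScaleParams:
    """Embedding table + BiLSTM weights of one n-gram scale."""

    def __init__(self, rng: np.random.Generator, vocab: int, embed_dim: int,
                 hidden: int):
        self.embedding = Parameter(rng.standard_normal((vocab, embed_dim)))
        self.lstm = {}
        for direction in ("fwd", "bwd"):
            limit = np.sqrt(6.0 / (embed_dim + hidden))
            bias = np.zeros(4 * hidden)
            bias[hidden:2 * hidden] = 1.0  # forget-gate bias
            self.lstm[direction] = {
                "Wx": Parameter(rng.uniform(-limit, limit, (embed_dim, 4 * hidden))),
                "Wh": Parameter(rng.uniform(-limit, limit, (hidden, 4 * hidden))),
                "b": Parameter(bias),
            }

    def parameters(self):
        out = [self.embedding]
        for d in ("fwd", "bwd"):
            out.extend(self.lstm[d].values())
        return out


class ProteinParams:
    """Unshared per-scale parameters for n = 2, 3, 4."""

    def __init__(self, config: ProteinConfig | None = None, seed: int = 0):
        self.config = config or ProteinConfig()
        rng = np.random.default_rng(seed)
        self.scales = {n: _ScaleParams(rng, vocabulary_size(n),
                                       self.config.embed_dim, self.config.hidden)
                       for n in NGRAM_SIZES}

    @property
    def output_dim(self) -> int:
        return len(NGRAM_SIZES) * 2 * self.config.hidden

    def parameters(self):
        out = []
        for n in NGRAM_SIZES:
            out.extend(self.scales[n].parameters())
        return out

    def state_arrays(self) -> dict:
        state = {}
        for n in NGRAM_SIZES:
            sc = self.scales[n]
            state[f"n{n}_embedding"] = sc.embedding.data
            for d in ("fwd", "bwd"):
                for k, p in sc.lstm[d].items():
                    state[f"n{n}_{d}_{k}"] = p.data
        return state

    def load_state_arrays(self, state: dict) -> None:
        for n in NGRAM_SIZES:
            sc = self.scales[n]
            sc.embedding.data = np.array(state[f"n{n}_embedding"])
            for d in ("fwd", "bwd"):
                for k in ("Wx", "Wh", "b"):
                    sc.lstm[d][k].data = np.array(state[f"n{n}_{d}_{k}"])


# --------------------------------------------------------------------------
# encoding
# --------------------------------------------------------------------------

def _lstm_direction(emb_steps: list, masks: np.ndarray, weights: dict,
                    hidden: int, reverse: bool) -> list:
    """Run one LSTM direction over (B, E) embedding steps with update masks.

    Padded steps (mask 0) keep the previous state, so states and hence the
    pooled output are independent of the padding length.
    """
    B = emb_steps[0].shape[0]
    h = Tensor(np.zeros((B, hidden)))
    c = Tensor(np.zeros((B, hidden)))
    order = range(len(emb_steps) - 1, -1, -1) if reverse else range(len(emb_steps))
    out: list = [None] * len(emb_steps)
    for t in order:
        gates = emb_steps[t] @ weights["Wx"] + h @ weights["Wh"] + weights["b"]
        i = gates[:, 0:hidden].sigmoid()
        f = gates[:, hidden:2 * hidden].sigmoid()
        g = gates[:, 2 * hidden:3 * hidden].tanh()
        o = gates[:, 3 * hidden:4 * hidden].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        m = Tensor(masks[:, t:t + 1])  # (B, 1)
        c = c_new * m + c * (1.0 - m)
        h = h_new * m + h * (1.0 - m)
        out[t] = h
    return out


def _encode_scale_batch(token_rows: list[np.ndarray], scale: _ScaleParams,
                        hidden: int, max_len: int) -> Tensor:
    """Encode a batch of token sequences at one scale -> (B, 2H)."""
    rows = [r[:max_len] for r in token_rows]
    lengths = np.array([len(r) for r in rows])
    if np.any(lengths == 0):
        raise ValueError("empty token sequence")
    B, L = len(rows), int(lengths.max())
    padded = np.zeros((B, L), dtype=np.int64)
    masks = np.zeros((B, L))
    for b, r in enumerate(rows):
        padded[b, :len(r)] = r
        masks[b, :len(r)] = 1.0
    emb = scale.embedding[padded]          # (B, L, E) with gradient scatter
    emb_steps = [emb[:, t, :] for t in range(L)]
    fwd = _lstm_direction(emb_steps, masks, scale.lstm["fwd"], hidden, reverse=False)
    bwd = _lstm_direction(emb_steps, masks, scale.lstm["bwd"], hidden, reverse=True)
    steps = [concatenate([f, b], axis=1) for f, b in zip(fwd, bwd)]  # (B, 2H) each
    stacked = stack(steps, axis=0)                                   # (L, B, 2H)
    # exclude padded positions from the max pool
    neg_inf = (masks.T[:, :, None] - 1.0) * 1e30
    return (stacked + Tensor(neg_inf)).max(axis=0)                   # (B, 2H)


def encode_protein_scale(tokens: NGramTokens, params: ProteinParams) -> Tensor:
    """Pooled BiLSTM representation (length 2H) of one token sequence."""
    if tokens.indices.size == 0:
        raise ValueError("empty token sequence")
    cfg = params.config
    out = _encode_scale_batch([tokens.indices], params.scales[tokens.n],
                              cfg.hidden, cfg.max_len)
    return out.reshape(-1)


def encode_protein_multiscale(sequence: str, params: ProteinParams) -> Tensor:
    """Concatenated n = 2, 3, 4 representations (length 3 x 2H)."""
    if len(normalize_sequence(sequence)) < max(NGRAM_SIZES):
        raise ValueError(f"sequence too short to encode (needs >= {max(NGRAM_SIZES)} residues)")
    parts = [encode_protein_scale(ngram_tokenize(sequence, n), params)
             for n in NGRAM_SIZES]
    return concatenate(parts, axis=0)


def encode_protein_batch(sequences: list[str], params: ProteinParams) -> Tensor:
    """Batched multi-scale encoding -> (B, 3 x 2H)."""
    if not sequences:
        raise ValueError("empty sequence batch")
    cfg = params.config
    parts = []
    for n in NGRAM_SIZES:
        token_rows = [ngram_tokenize(s, n).indices for s in sequences]
        parts.append(_encode_scale_batch(token_rows, params.scales[n],
                                         cfg.hidden, cfg.max_len))
    return concatenate(parts, axis=1)
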