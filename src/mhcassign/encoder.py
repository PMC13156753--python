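"""Peptide/pseudosequence tokenization and the transformer sequence encoder.

Sequences are tokenized over the 20 canonical residues plus [CLS] and
[PAD], right-padded only to the batch maximum, and encoded by a small
transformer trained from scratch.  The attention mask guarantees that
padding never influences the pooled representation, so a sequence's vector
is identical whatever batch it is encoded in.  The pooled [CLS] state goes
through a tanh projection to form the sequence vector.  The same encoder is
applied to peptides and to HLA binding-groove pseudosequences (shared
weights); an adapter implementing ``encode(sequences) -> matrix`` can stand
in for it, e.g. to plug in a pretrained protein language model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .io import CANONICAL_AA

PAD, CLS = 0, 1
VOCAB = {aa: i + 2 for i, aa in enumerate(CANONICAL_AA)}
VOCAB_SIZE = len(VOCAB) + 2
MAX_POSITIONS = 64  # generous cap; batches pad only to their own max


@dataclass(frozen=True)
class TokenBatch:
    """Token ids and attention mask, padded to the batch maximum length."""

    token_ids: np.ndarray      # (batch, max_len) int
    attention_mask: np.ndarray  # (batch, max_len) 0/1

    def __post_init__(self):
        if self.token_ids.shape != self.attention_mask.shape:
            raise ValueError("token_ids and attention_mask shapes differ")


def tokenize_batch(sequences: list[str]) -> TokenBatch:
    """Tokenize sequences with a prepended [CLS], right-padding to batch max.

    The mask is 1 exactly over non-pad tokens.  Out-of-alphabet characters
    raise with the sequence and position named.
    """
    if not sequences:
        raise ValueError("empty batch")
    for seq in sequences:
        for pos, aa in enumerate(seq):
            if aa not in VOCAB:
                raise ValueError(
                    f"sequence {seq!r}: non-canonical residue {aa!r} at position {pos + 1}"
                )
    max_len = max(len(s) for s in sequences) + 1  # + [CLS]
    ids = np.full((len(sequences), max_len), PAD, dtype=np.int64)
    mask = np.zeros((len(sequences), max_len), dtype=np.int64)
    for row, seq in enumerate(sequences):
        ids[row, 0] = CLS
        for col, aa in enumerate(seq, start=1):
            ids[row, col] = VOCAB[aa]
        mask[row, : len(seq) + 1] = 1
    return TokenBatch(token_ids=ids, attention_mask=mask)


def _init(rng: np.random.Generator, *shape, scale: float | None = None) -> ad.Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return ad.Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class TransformerEncoder:
    """A small pre-LN transformer with masked self-attention and CLS pooling."""

    def __init__(self, n_layers: int = 2, dim: int = 64, n_heads: int = 4,
                 ffn_mult: int = 2, seed: int = 0):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_layers = n_layers
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        rng = np.random.default_rng(seed)
        p: dict[str, ad.Tensor] = {
            "tok_emb": _init(rng, VOCAB_SIZE, dim, scale=0.02),
            "pos_emb": _init(rng, MAX_POSITIONS, dim, scale=0.02),
            "pool_w": _init(rng, dim, dim),
            "pool_b": ad.Tensor(np.zeros(dim), requires_grad=True),
            "final_ln_g": ad.Tensor(np.ones(dim), requires_grad=True),
            "final_ln_b": ad.Tensor(np.zeros(dim), requires_grad=True),
        }
        for i in range(n_layers):
            p.update({
                f"l{i}.ln1_g": ad.Tensor(np.ones(dim), requires_grad=True),
                f"l{i}.ln1_b": ad.Tensor(np.zeros(dim), requires_grad=True),
                f"l{i}.wq": _init(rng, dim, dim),
                f"l{i}.wk": _init(rng, dim, dim),
                f"l{i}.wv": _init(rng, dim, dim),
                f"l{i}.wo": _init(rng, dim, dim),
                f"l{i}.ln2_g": ad.Tensor(np.ones(dim), requires_grad=True),
                f"l{i}.ln2_b": ad.Tensor(np.zeros(dim), requires_grad=True),
                f"l{i}.w1": _init(rng, dim, ffn_mult * dim),
                f"l{i}.b1": ad.Tensor(np.zeros(ffn_mult * dim), requires_grad=True),
                f"l{i}.w2": _init(rng, ffn_mult * dim, dim),
                f"l{i}.b2": ad.Tensor(np.zeros(dim), requires_grad=True),
            })
        self.params = p

    def _attention(self, x: ad.Tensor, mask: np.ndarray, layer: int) -> ad.Tensor:
        p = self.params
        batch, seq_len, dim = x.shape
        heads, hd = self.n_heads, self.head_dim

        def split(t: ad.Tensor) -> ad.Tensor:
            return t.reshape(batch, seq_len, heads, hd).transpose((0, 2, 1, 3))

        q = split(ad.linear(x, p[f"l{layer}.wq"]))
        k = split(ad.linear(x, p[f"l{layer}.wk"]))
        v = split(ad.linear(x, p[f"l{layer}.wv"]))
        scores = q.matmul(k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(hd))
        # keys at pad positions are removed from every query's softmax
        neg = (1.0 - mask[:, None, None, :]) * -1e9
        attn = (scores + ad.Tensor(neg)).softmax(axis=-1)
        ctx = attn.matmul(v).transpose((0, 2, 1, 3)).reshape(batch, seq_len, dim)
        return ad.linear(ctx, p[f"l{layer}.wo"])

    def forward_tokens(self, batch: TokenBatch) -> ad.Tensor:
        """Contextual states for every position, (batch, seq_len, dim)."""
        p = self.params
        ids, mask = batch.token_ids, batch.attention_mask.astype(np.float64)
        seq_len = ids.shape[1]
        if seq_len > MAX_POSITIONS:
            raise ValueError(f"sequence length {seq_len} exceeds {MAX_POSITIONS}")
        x = ad.embedding(p["tok_emb"], ids) + p["pos_emb"][:seq_len]
        for i in range(self.n_layers):
            h = ad.layer_norm(x, p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])
            x = x + self._attention(h, mask, i)
            h = ad.layer_norm(x, p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
            h = ad.linear(h, p[f"l{i}.w1"], p[f"l{i}.b1"]).relu()
            x = x + ad.linear(h, p[f"l{i}.w2"], p[f"l{i}.b2"])
        return ad.layer_norm(x, p["final_ln_g"], p["final_ln_b"])

    def forward(self, batch: TokenBatch) -> ad.Tensor:
        """Pooled sequence vectors: tanh-projected [CLS] state, (batch, dim)."""
        states = self.forward_tokens(batch)
        cls = states[:, 0, :]
        return ad.linear(cls, self.params["pool_w"], self.params["pool_b"]).tanh()

    def encode(self, sequences: list[str]) -> np.ndarray:
        """Inference-only embedding of raw sequences."""
        return self.forward(tokenize_batch(sequences)).data
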