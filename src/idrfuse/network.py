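"""The fusion network core.

The model is a residue tagger with three stages:

1. **Multi-semantic interaction layer** — a gated recurrent cell ("fusion
   cell") that fuses the two feature streams. At residue j the traditional
   biological feature vector r_b modulates the previous memory cell,

       C^b = sigma(W_c C_{j-1} + b_c) (*) sigma(W_r r_b + b_r),

   while the PLM embedding r_p drives the gates and candidate memory exactly
   as in an LSTM:

       [f, i, o] = sigma(W_g [r_p; h_{j-1}] + b_g)
       C_hat     = tanh(W_c^ [r_p; h_{j-1}] + b_c^)
       C_j       = f (*) C^b + i (*) C_hat
       h_j       = o (*) tanh(C_j)

   so the streams interact multiplicatively instead of being concatenated.
   A ``concat_lstm`` mode replaces the fusion cell with a textbook LSTM over
   the concatenated streams [r_b; r_p] — the ablation baseline.

2. **Transformer encoder** — N post-norm sublayers of masked multi-head
   scaled dot-product attention plus a position-wise ReLU feed-forward
   network.

3. **Output head** — a linear map to two logits and a softmax; the returned
   score is the disordered-class probability, binarized at 0.5 by default
   (score >= threshold -> disordered).

Padded positions are masked everywhere: the recurrent layer zeroes their
outputs, attention assigns them zero weight, and the loss/metrics ignore
them, so a padded forward pass reproduces the unpadded one at valid
positions.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._autodiff import Adam, Tensor, as_tensor, concat, gather_rows, stack

__all__ = [
    "ModelConfig",
    "FusionCellParams",
    "FusionState",
    "LSTMParams",
    "EncoderLayerParams",
    "FusionNetwork",
    "fused_memory",
    "fusion_cell_step",
    "run_interaction_layer",
    "scaled_dot_attention",
    "multi_head_attention",
    "ffn",
    "encoder_stack",
    "output_head",
    "binarize",
    "save_checkpoint",
    "load_checkpoint",
]

_NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Architecture and inference configuration.

    ``d_b``/``d_p`` are the input widths of the traditional and PLM streams,
    ``d_h`` the recurrent hidden width, ``d_model``/``n_layers``/``n_heads``
    the encoder geometry. ``fusion_mode`` selects the fusion cell or the
    concatenation LSTM baseline. ``additive_memory`` switches to an
    experimental update C_j = f (*) C_{j-1} + i (*) C_hat + C^b (off by
    default; the standard reading consumes C^b inside the forget path).
    """

    d_b: int = 80
    d_p: int = 3102
    d_h: int = 64
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int | None = None
    dropout: float = 0.1
    bidirectional: bool = False
    positional_encoding: bool = False
    fusion_mode: str = "fusioncell"
    additive_memory: bool = False
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.fusion_mode not in ("fusioncell", "concat_lstm"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model

    @property
    def d_out(self) -> int:
        return 2 * self.d_h if self.bidirectional else self.d_h


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


@dataclass
class FusionCellParams:
    """All weights of one fusion cell direction.

    Gate stack order in ``W_g``/``b_g`` is [forget, input, output].
    """

    W_c: Tensor
    b_c: Tensor
    W_r: Tensor
    b_r: Tensor
    W_g: Tensor
    b_g: Tensor
    W_chat: Tensor
    b_chat: Tensor
    d_h: int
    d_b: int
    d_p: int

    @classmethod
    def init(cls, d_h: int, d_b: int, d_p: int, rng: np.random.Generator):
        b_g = np.zeros(3 * d_h)
        b_g[:d_h] = 1.0  # forget-gate bias +1, standard LSTM practice
        return cls(
            W_c=_uniform(rng, (d_h, d_h), d_h),
            b_c=_zeros(d_h),
            W_r=_uniform(rng, (d_h, d_b), d_b),
            b_r=_zeros(d_h),
            W_g=_uniform(rng, (3 * d_h, d_p + d_h), d_p + d_h),
            b_g=Tensor(b_g, requires_grad=True),
            W_chat=_uniform(rng, (d_h, d_p + d_h), d_p + d_h),
            b_chat=_zeros(d_h),
            d_h=d_h,
            d_b=d_b,
            d_p=d_p,
        )

    def tensors(self) -> list[Tensor]:
        return [self.W_c, self.b_c, self.W_r, self.b_r,
                self.W_g, self.b_g, self.W_chat, self.b_chat]


@dataclass
class LSTMParams:
    """Textbook LSTM weights (gate stack [forget, input, output, candidate])."""

    W: Tensor
    b: Tensor
    d_h: int
    d_in: int

    @classmethod
    def init(cls, d_h: int, d_in: int, rng: np.random.Generator):
        b = np.zeros(4 * d_h)
        b[:d_h] = 1.0
        return cls(
            W=_uniform(rng, (4 * d_h, d_in + d_h), d_in + d_h),
            b=Tensor(b, requires_grad=True),
            d_h=d_h,
            d_in=d_in,
        )

    def tensors(self) -> list[Tensor]:
        return [self.W, self.b]


@dataclass(frozen=True)
class FusionState:
    """Recurrent carriers: memory cell C and hidden state h."""

    C: np.ndarray
    h: np.ndarray


# ---------------------------------------------------------------------------
# Fusion cell (tensor-level internals + numpy public wrappers)
# ---------------------------------------------------------------------------

def _fused_memory_t(C_prev: Tensor, r_b: Tensor, p: FusionCellParams) -> Tensor:
    return ((C_prev @ p.W_c.T + p.b_c).sigmoid()
            * (r_b @ p.W_r.T + p.b_r).sigmoid())


def _fusion_cell_step_t(
    C_prev: Tensor, h_prev: Tensor, r_b: Tensor, r_p: Tensor,
    p: FusionCellParams, additive: bool = False,
) -> tuple[Tensor, Tensor]:
    d_h = p.d_h
    Cb = _fused_memory_t(C_prev, r_b, p)
    x = concat([r_p, h_prev], axis=-1)
    gates = (x @ p.W_g.T + p.b_g).sigmoid()
    f = gates[..., 0:d_h]
    i = gates[..., d_h:2 * d_h]
    o = gates[..., 2 * d_h:3 * d_h]
    chat = (x @ p.W_chat.T + p.b_chat).tanh()
    if additive:
        C_new = f * C_prev + i * chat + Cb
    else:
        C_new = f * Cb + i * chat
    h_new = o * C_new.tanh()
    return C_new, h_new


def _lstm_step_t(
    C_prev: Tensor, h_prev: Tensor, r: Tensor, p: LSTMParams
) -> tuple[Tensor, Tensor]:
    d_h = p.d_h
    x = concat([r, h_prev], axis=-1)
    pre = x @ p.W.T + p.b
    f = pre[..., 0:d_h].sigmoid()
    i = pre[..., d_h:2 * d_h].sigmoid()
    o = pre[..., 2 * d_h:3 * d_h].sigmoid()
    g = pre[..., 3 * d_h:4 * d_h].tanh()
    C_new = f * C_prev + i * g
    h_new = o * C_new.tanh()
    return C_new, h_new


def fused_memory(C_prev: np.ndarray, r_b: np.ndarray,
                 params: FusionCellParams) -> np.ndarray:
    """C^b = sigma(W_c C_prev + b_c) (*) sigma(W_r r_b + b_r); entries in (0,1)."""
    C_prev = np.asarray(C_prev, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if C_prev.shape[-1] != params.d_h or r_b.shape[-1] != params.d_b:
        raise ValueError(
            f"shape mismatch: C_prev {C_prev.shape}, r_b {r_b.shape} for "
            f"d_h={params.d_h}, d_b={params.d_b}"
        )
    return _fused_memory_t(as_tensor(C_prev), as_tensor(r_b), params).data


def fusion_cell_step(state: FusionState, r_b: np.ndarray, r_p: np.ndarray,
                     params: FusionCellParams,
                     additive: bool = False) -> FusionState:
    """One fusion-cell update from ``state`` given the two feature vectors."""
    r_p = np.asarray(r_p, dtype=float)
    if r_p.shape[-1] != params.d_p:
        raise ValueError(f"r_p width {r_p.shape[-1]} != d_p {params.d_p}")
    C, h = _fusion_cell_step_t(
        as_tensor(np.asarray(state.C, dtype=float)),
        as_tensor(np.asarray(state.h, dtype=float)),
        as_tensor(np.asarray(r_b, dtype=float)),
        as_tensor(r_p), params, additive,
    )
    return FusionState(C=C.data, h=h.data)


def _check_prefix_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    flat = mask if mask.ndim == 2 else mask[None, :]
    for row in flat:
        n = int(row.sum())
        if not row[:n].all():
            raise ValueError("mask must be a valid prefix (trailing padding only)")
    return mask


def _run_recurrent_t(
    R_b: np.ndarray, R_p: np.ndarray, mask: np.ndarray,
    params: FusionCellParams | LSTMParams, mode: str, additive: bool,
) -> Tensor:
    """Run one direction over (B, L, .) arrays; returns (B, L, d_h) Tensor."""
    B, L = R_b.shape[0], R_b.shape[1]
    d_h = params.d_h
    C = as_tensor(np.zeros((B, d_h)))
    h = as_tensor(np.zeros((B, d_h)))
    outs = []
    for t in range(L):
        if mode == "fusioncell":
            C, h = _fusion_cell_step_t(
                C, h, as_tensor(R_b[:, t]), as_tensor(R_p[:, t]),
                params, additive)
        else:
            C, h = _lstm_step_t(
                C, h, as_tensor(np.concatenate([R_b[:, t], R_p[:, t]], axis=-1)),
                params)
        outs.append(h)
    H = stack(outs, axis=1)  # (B, L, d_h)
    return H * mask[:, :, None].astype(float)


def _reverse_valid(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    idx = _reverse_index(X.shape[1], lengths)
    return np.take_along_axis(X, idx[..., None], axis=1)


def _reverse_index(L: int, lengths: np.ndarray) -> np.ndarray:
    base = np.arange(L)[None, :]
    n = lengths[:, None]
    return np.where(base < n, n - 1 - base, base)


def run_interaction_layer(
    R_b: np.ndarray, R_p: np.ndarray,
    params: FusionCellParams | tuple[FusionCellParams, FusionCellParams],
    mask: np.ndarray | None = None,
    additive: bool = False,
) -> np.ndarray:
    """Apply the fusion cell along a single sequence (numpy in/out).

    ``params`` is one cell (unidirectional, output L x d_h) or a (forward,
    backward) pair (bidirectional, output L x 2 d_h). Rows at masked (padded)
    positions are zero; the mask must be a prefix.
    """
    R_b = np.asarray(R_b, dtype=float)
    R_p = np.asarray(R_p, dtype=float)
    if R_b.shape[0] != R_p.shape[0]:
        raise ValueError("R_b and R_p must have equal row counts")
    L = R_b.shape[0]
    if mask is None:
        mask = np.ones(L, dtype=bool)
    mask = _check_prefix_mask(mask)
    if mask.ndim == 1:
        mask = mask[None, :]
    pair = params if isinstance(params, tuple) else (params,)
    Rb3, Rp3 = R_b[None], R_p[None]
    H = _run_recurrent_t(Rb3, Rp3, mask, pair[0], "fusioncell", additive)
    if len(pair) == 2:
        lengths = mask.sum(axis=1)
        Hb = _run_recurrent_t(
            _reverse_valid(Rb3, lengths), _reverse_valid(Rp3, lengths),
            mask, pair[1], "fusioncell", additive)
        Hb = gather_rows(Hb, _reverse_index(L, lengths))
        Hb = Hb * mask[:, :, None].astype(float)
        H = concat([H, Hb], axis=-1)
    return H.data[0]


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

@dataclass
class EncoderLayerParams:
    W_q: Tensor
    W_k: Tensor
    W_v: Tensor
    W_m: Tensor
    W_1: Tensor
    b_1: Tensor
    W_2: Tensor
    b_2: Tensor
    ln1_g: Tensor
    ln1_b: Tensor
    ln2_g: Tensor
    ln2_b: Tensor
    n_heads: int
    d_model: int

    @classmethod
    def init(cls, d_model: int, n_heads: int, d_ff: int,
             rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        return cls(
            W_q=_uniform(rng, (d_model, d_model), d_model),
            W_k=_uniform(rng, (d_model, d_model), d_model),
            W_v=_uniform(rng, (d_model, d_model), d_model),
            W_m=_uniform(rng, (d_model, d_model), d_model),
            W_1=_uniform(rng, (d_model, d_ff), d_model),
            b_1=_zeros(d_ff),
            W_2=_uniform(rng, (d_ff, d_model), d_ff),
            b_2=_zeros(d_model),
            ln1_g=Tensor(np.ones(d_model), requires_grad=True),
            ln1_b=_zeros(d_model),
            ln2_g=Tensor(np.ones(d_model), requires_grad=True),
            ln2_b=_zeros(d_model),
            n_heads=n_heads,
            d_model=d_model,
        )

    def tensors(self) -> list[Tensor]:
        return [self.W_q, self.W_k, self.W_v, self.W_m, self.W_1, self.b_1,
                self.W_2, self.b_2, self.ln1_g, self.ln1_b, self.ln2_g,
                self.ln2_b]


def _layer_norm_t(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    m = x.mean(axis=-1, keepdims=True)
    xc = x - m
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * g + b


def _dropout_t(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate).astype(float) / (1.0 - rate)
    return x * keep


def _attention_t(Q: Tensor, K: Tensor, V: Tensor,
                 key_mask: np.ndarray | None) -> Tensor:
    d_k = Q.shape[-1]
    scores = (Q @ K.T) * (1.0 / np.sqrt(d_k))
    if key_mask is not None:
        bias = np.where(key_mask, 0.0, _NEG_INF)
        scores = scores + bias
    return scores.softmax(axis=-1) @ V


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V with masked key positions excluded.

    ``mask`` marks valid key positions; attention weights over the unmasked
    keys sum to 1 for every query row.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if K.shape[0] != V.shape[0] or Q.shape[-1] != K.shape[-1]:
        raise ValueError("inconsistent attention shapes")
    key_mask = None
    if mask is not None:
        key_mask = np.asarray(mask, dtype=bool)
        if not key_mask.any():
            raise ValueError("all key positions are masked")
    return _attention_t(as_tensor(Q), as_tensor(K), as_tensor(V), key_mask).data


def _multi_head_attention_t(X: Tensor, p: EncoderLayerParams,
                            key_mask: np.ndarray | None) -> Tensor:
    B, L, d = X.shape
    k, d_k = p.n_heads, p.d_model // p.n_heads
    def heads(W):
        return (X @ W).reshape(B, L, k, d_k).swapaxes(1, 2)  # (B,k,L,d_k)
    Q, K, V = heads(p.W_q), heads(p.W_k), heads(p.W_v)
    mask4 = None if key_mask is None else key_mask[:, None, None, :]
    A = _attention_t(Q, K, V, mask4)  # (B,k,L,d_k)
    return A.swapaxes(1, 2).reshape(B, L, d) @ p.W_m


def multi_head_attention(X: np.ndarray, params: EncoderLayerParams,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """k parallel attention heads on projected Q/K/V, concatenated, projected."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    X3 = X[None] if single else X
    key_mask = None
    if mask is not None:
        key_mask = np.asarray(mask, dtype=bool)
        if key_mask.ndim == 1:
            key_mask = key_mask[None, :]
    out = _multi_head_attention_t(as_tensor(X3), params, key_mask).data
    return out[0] if single else out


def _ffn_t(X: Tensor, p: EncoderLayerParams) -> Tensor:
    return (X @ p.W_1 + p.b_1).relu() @ p.W_2 + p.b_2


def ffn(X: np.ndarray, params: EncoderLayerParams) -> np.ndarray:
    """Position-wise feed-forward network: max(0, x W1 + b1) W2 + b2."""
    return _ffn_t(as_tensor(np.asarray(X, dtype=float)), params).data


def _encoder_layer_t(X: Tensor, p: EncoderLayerParams,
                     key_mask: np.ndarray | None, dropout: float,
                     rng: np.random.Generator | None) -> Tensor:
    a = _dropout_t(_multi_head_attention_t(X, p, key_mask), dropout, rng)
    X = _layer_norm_t(X + a, p.ln1_g, p.ln1_b)
    f = _dropout_t(_ffn_t(X, p), dropout, rng)
    return _layer_norm_t(X + f, p.ln2_g, p.ln2_b)


def _encoder_stack_t(X: Tensor, layers: Sequence[EncoderLayerParams],
                     key_mask: np.ndarray | None, dropout: float = 0.0,
                     rng: np.random.Generator | None = None) -> Tensor:
    for p in layers:
        X = _encoder_layer_t(X, p, key_mask, dropout, rng)
    return X


def encoder_stack(H: np.ndarray, layers: Sequence[EncoderLayerParams],
                  mask: np.ndarray | None = None) -> np.ndarray:
    """N post-norm transformer sublayers; N=0 is the identity mapping."""
    H = np.asarray(H, dtype=float)
    single = H.ndim == 2
    H3 = H[None] if single else H
    key_mask = None
    if mask is not None:
        key_mask = np.asarray(mask, dtype=bool)
        if key_mask.ndim == 1:
            key_mask = key_mask[None, :]
    out = _encoder_stack_t(as_tensor(H3), layers, key_mask).data
    return out[0] if single else out


def sinusoidal_positions(L: int, d_model: int) -> np.ndarray:
    pos = np.arange(L)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def output_head(H: np.ndarray, W: Tensor | np.ndarray,
                b: Tensor | np.ndarray) -> np.ndarray:
    """Two-class softmax per residue; returns the disordered-class probability."""
    H = np.asarray(H, dtype=float)
    logits = as_tensor(H) @ as_tensor(W if isinstance(W, np.ndarray) else W.data) \
        + as_tensor(b if isinstance(b, np.ndarray) else b.data)
    probs = logits.softmax(axis=-1).data
    return probs[..., 1]


def binarize(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Disordered iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return (scores >= threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class FusionNetwork:
    """The full residue tagger: interaction layer -> encoder -> softmax head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.fusion_mode == "fusioncell":
            self.cell_fw = FusionCellParams.init(config.d_h, config.d_b,
                                                 config.d_p, rng)
            self.cell_bw = (FusionCellParams.init(config.d_h, config.d_b,
                                                  config.d_p, rng)
                            if config.bidirectional else None)
        else:
            d_in = config.d_b + config.d_p
            self.cell_fw = LSTMParams.init(config.d_h, d_in, rng)
            self.cell_bw = (LSTMParams.init(config.d_h, d_in, rng)
                            if config.bidirectional else None)
        d_out = config.d_out
        if d_out != config.d_model:
            self.W_in = _uniform(rng, (d_out, config.d_model), d_out)
            self.b_in = _zeros(config.d_model)
        else:
            self.W_in = None
            self.b_in = None
        self.layers = [
            EncoderLayerParams.init(config.d_model, config.n_heads,
                                    config.d_ff, rng)
            for _ in range(config.n_layers)
        ]
        self.W_out = _uniform(rng, (config.d_model, 2), config.d_model)
        self.b_out = _zeros(2)

    def parameters(self) -> list[Tensor]:
        ps = self.cell_fw.tensors()
        if self.cell_bw is not None:
            ps += self.cell_bw.tensors()
        if self.W_in is not None:
            ps += [self.W_in, self.b_in]
        for layer in self.layers:
            ps += layer.tensors()
        ps += [self.W_out, self.b_out]
        return ps

    # -- forward ---------------------------------------------------------------
    def _interaction(self, R_b: np.ndarray, R_p: np.ndarray,
                     mask: np.ndarray) -> Tensor:
        mode = self.config.fusion_mode
        H = _run_recurrent_t(R_b, R_p, mask, self.cell_fw, mode,
                             self.config.additive_memory)
        if self.cell_bw is not None:
            lengths = mask.sum(axis=1)
            L = R_b.shape[1]
            Hb = _run_recurrent_t(
                _reverse_valid(R_b, lengths), _reverse_valid(R_p, lengths),
                mask, self.cell_bw, mode, self.config.additive_memory)
            Hb = gather_rows(Hb, _reverse_index(L, lengths))
            Hb = Hb * mask[:, :, None].astype(float)
            H = concat([H, Hb], axis=-1)
        return H

    def forward(self, R_b: np.ndarray, R_p: np.ndarray, mask: np.ndarray,
                train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Batched forward pass to per-residue logits (B, L, 2).

        ``R_b`` (B, L, d_b), ``R_p`` (B, L, d_p), ``mask`` (B, L) prefix-valid.
        Dropout is active only with ``train=True`` and an rng supplied.
        """
        R_b = np.asarray(R_b, dtype=float)
        R_p = np.asarray(R_p, dtype=float)
        mask = _check_prefix_mask(mask)
        drop_rng = rng if train else None
        H = self._interaction(R_b, R_p, mask)
        if self.W_in is not None:
            H = H @ self.W_in + self.b_in
        if self.config.positional_encoding:
            pe = sinusoidal_positions(R_b.shape[1], self.config.d_model)
            H = H + pe[None] * mask[:, :, None].astype(float)
        H = _encoder_stack_t(H, self.layers, mask, self.config.dropout,
                             drop_rng)
        return H @ self.W_out + self.b_out

    def predict_scores(self, R_b: np.ndarray, R_p: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
        """Disordered-class probabilities for one sequence (L,) or batch (B, L)."""
        single = np.asarray(R_b).ndim == 2
        R_b3 = R_b[None] if single else np.asarray(R_b)
        R_p3 = R_p[None] if single else np.asarray(R_p)
        if mask is None:
            mask = np.ones(R_b3.shape[:2], dtype=bool)
        elif np.asarray(mask).ndim == 1:
            mask = np.asarray(mask)[None, :]
        logits = self.forward(R_b3, R_p3, mask)
        probs = logits.softmax(axis=-1).data[..., 1]
        return probs[0] if single else probs

    def export_hidden_states(self, R_b: np.ndarray, R_p: np.ndarray,
                             taps: Sequence[str] = ("traditional_in", "plm_in",
                                                    "fused_h", "encoder_out"),
                             ) -> dict[str, np.ndarray]:
        """Per-residue matrices at named taps for external visualization.

        Taps: ``traditional_in`` (L, d_b), ``plm_in`` (L, d_p), ``fused_h``
        (L, d_out) and ``encoder_out`` (L, d_model). Deterministic (no
        dropout).
        """
        known = {"traditional_in", "plm_in", "fused_h", "encoder_out"}
        unknown = set(taps) - known
        if unknown:
            raise ValueError(f"unknown tap name(s): {sorted(unknown)}")
        R_b = np.asarray(R_b, dtype=float)
        R_p = np.asarray(R_p, dtype=float)
        mask = np.ones((1, R_b.shape[0]), dtype=bool)
        out: dict[str, np.ndarray] = {}
        if "traditional_in" in taps:
            out["traditional_in"] = R_b.copy()
        if "plm_in" in taps:
            out["plm_in"] = R_p.copy()
        H = self._interaction(R_b[None], R_p[None], mask)
        if "fused_h" in taps:
            out["fused_h"] = H.data[0].copy()
        if "encoder_out" in taps:
            X = H
            if self.W_in is not None:
                X = X @ self.W_in + self.b_in
            if self.config.positional_encoding:
                X = X + sinusoidal_positions(R_b.shape[0],
                                             self.config.d_model)[None]
            X = _encoder_stack_t(X, self.layers, mask)
            out["encoder_out"] = X.data[0].copy()
        return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, network: FusionNetwork,
                    meta: Mapping | None = None) -> None:
    """Write a self-describing checkpoint: parameters + config + metadata."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(network.parameters())}
    header = {"config": asdict(network.config), "meta": dict(meta or {})}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[FusionNetwork, dict]:
    """Rebuild a :class:`FusionNetwork` from a checkpoint archive."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        config = ModelConfig(**header["config"])
        net = FusionNetwork(config)
        params = net.parameters()
        for i, p in enumerate(params):
            stored = z[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint/config mismatch at parameter {i}: "
                    f"{stored.shape} vs {p.data.shape}")
            p.data = stored.astype(np.float64)
    return net, header["meta"]
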