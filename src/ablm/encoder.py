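"""Transformer encoder with disentangled relative-position attention.

Attention scores sum three dot products per pair (i, j): content-to-content,
content-to-position through a clamped relative-offset table, and a third
term with two selectable readings (``p2c_variant``):

* ``as_printed`` — the query of the third term is content-derived,
* ``deberta_original`` — the query is position-derived and indexed by the
  transposed relative offset, as in the original disentangled-attention
  formulation.

Scores are scaled by 1/sqrt(3*d_k) in disentangled mode (three summed dot
products) and by 1/sqrt(d_k) in plain/absolute mode.  An
``absolute_learned`` position mode is provided for ablation.

The module exposes two routes to the same math: small functional single-head
operations on plain NumPy arrays (``attention_scores``/``attention_output``/
``feed_forward``), and the batched multi-head :class:`Encoder` built on the
autodiff engine; tests assert their agreement.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import DTYPE, Tensor
from .abcore import DEFAULT_ALPHABET, ResidueAlphabet

__all__ = [
    "EncoderConfig",
    "DisentangledAttentionWeights",
    "FeedForwardWeights",
    "rel_index",
    "rel_index_matrix",
    "attention_scores",
    "attention_output",
    "feed_forward",
    "Encoder",
]

NEG_INF = -1e9
CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 2
    d_model: int = 64
    n_heads: int = 4
    d_ff: int = 256
    k_max: int = 128
    vocab_size: int = 25
    max_len: int = 512  # absolute-position table size
    activation: str = "relu"  # or "gelu"
    position_mode: str = "relative_disentangled"  # or "absolute_learned"
    p2c_variant: str = "as_printed"  # or "deberta_original"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.position_mode not in ("relative_disentangled", "absolute_learned"):
            raise ValueError(f"unknown position_mode {self.position_mode!r}")
        if self.p2c_variant not in ("as_printed", "deberta_original"):
            raise ValueError(f"unknown p2c_variant {self.p2c_variant!r}")
        if self.activation not in ("gelu", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @property
    def score_scale(self) -> float:
        """1/sqrt(3*d_k) for disentangled attention, 1/sqrt(d_k) otherwise."""
        if self.position_mode == "relative_disentangled":
            return 1.0 / np.sqrt(3.0 * self.d_k)
        return 1.0 / np.sqrt(self.d_k)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        return cls(**d)


#: desk-scale default used throughout the tests
DESK = EncoderConfig()
#: approximate full-scale preset (not exercised in tests)
PAPERLIKE = EncoderConfig(n_layers=12, d_model=768, n_heads=12, d_ff=3072)


def rel_index(i: int, j: int, k: int) -> int:
    """Clamped relative position index: clamp(i - j, -k, k) + k, in [0, 2k]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return int(np.clip(i - j, -k, k)) + k


def rel_index_matrix(n: int, k: int) -> np.ndarray:
    """delta[i, j] for all pairs of an n-token sequence."""
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    return (np.clip(i - j, -k, k) + k).astype(np.int64)


# ---------------------------------------------------------------------------
# Functional single-head reference operations (plain NumPy)
# ---------------------------------------------------------------------------


@dataclass
class DisentangledAttentionWeights:
    """Single-head projections, each of shape (d, d_k)."""

    w_qc: np.ndarray
    w_kc: np.ndarray
    w_vc: np.ndarray
    w_qr: np.ndarray
    w_kr: np.ndarray

    def __post_init__(self) -> None:
        shape = self.w_qc.shape
        for name in ("w_kc", "w_vc", "w_qr", "w_kr"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")


@dataclass
class FeedForwardWeights:
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray


def attention_scores(
    H: np.ndarray,
    P: np.ndarray | None,
    weights: DisentangledAttentionWeights,
    cfg: EncoderConfig,
) -> np.ndarray:
    """Unscaled pairwise attention scores A' (N x N) for one head."""
    n, d = H.shape
    if weights.w_qc.shape[0] != d:
        raise ValueError(f"H has width {d} but w_qc expects {weights.w_qc.shape[0]}")
    qc = H @ weights.w_qc
    kc = H @ weights.w_kc
    scores = qc @ kc.T
    if cfg.position_mode != "relative_disentangled":
        return scores
    if P is None:
        raise ValueError("relative mode requires a position table P")
    if P.shape[0] != 2 * cfg.k_max + 1:
        raise ValueError(f"P has {P.shape[0]} rows, expected {2 * cfg.k_max + 1}")
    delta = rel_index_matrix(n, cfg.k_max)
    kr = P @ weights.w_kr
    scores = scores + np.take_along_axis(qc @ kr.T, delta, axis=1)
    if cfg.p2c_variant == "as_printed":
        qr = H @ weights.w_qr
        scores = scores + qr @ kc.T
    else:
        qr_tab = P @ weights.w_qr
        m = kc @ qr_tab.T  # m[j, r] = Kc_j . Qr_r
        scores = scores + np.take_along_axis(m, delta, axis=1).T  # term[i,j]=m[j, delta(j,i)]
    return scores


def attention_output(scores: np.ndarray, V: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    """softmax(scores * scale) @ V with row-wise softmax."""
    z = scores * cfg.score_scale
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    return probs @ V


def feed_forward(x: np.ndarray, w: FeedForwardWeights, activation: str = "gelu") -> np.ndarray:
    h = x @ w.w1 + w.b1
    if activation == "relu":
        h = np.maximum(h, 0.0)
    elif activation == "gelu":
        t = Tensor(h).gelu().data
        h = np.asarray(t, dtype=h.dtype)
    else:
        raise ValueError(f"unknown activation {activation!r}")
    return h @ w.w2 + w.b2


# ---------------------------------------------------------------------------
# Trainable batched multi-head encoder
# ---------------------------------------------------------------------------


class Encoder:
    """Batched multi-head encoder over the autodiff engine.

    Parameters live in ``self.params`` (name -> Tensor); the relative
    position table is shared across layers.
    """

    def __init__(
        self,
        cfg: EncoderConfig = DESK,
        seed: int = 0,
        alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
    ):
        if cfg.vocab_size != alphabet.size:
            raise ValueError(
                f"config vocab_size {cfg.vocab_size} != alphabet size {alphabet.size}"
            )
        self.cfg = cfg
        self.seed = seed
        self.alphabet = alphabet
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    def _param(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array.astype(DTYPE), requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        d, s = cfg.d_model, 0.02
        self._param("embed", rng.normal(0, s, (cfg.vocab_size, d)))
        self._param("emb_ln_g", np.ones(d))
        self._param("emb_ln_bias", np.zeros(d))
        if cfg.position_mode == "absolute_learned":
            self._param("abs_pos", rng.normal(0, s, (cfg.max_len, d)))
        else:
            self._param("rel_P", rng.normal(0, s, (2 * cfg.k_max + 1, d)))
            self._param("rel_ln_g", np.ones(d))
            self._param("rel_ln_bias", np.zeros(d))
        for li in range(cfg.n_layers):
            p = f"l{li}."
            for w in ("w_qc", "w_kc", "w_vc"):
                self._param(p + w, rng.normal(0, s, (d, d)))
            if cfg.position_mode == "relative_disentangled":
                for w in ("w_qr", "w_kr"):
                    self._param(p + w, rng.normal(0, s, (d, d)))
            self._param(p + "attn_out_w", rng.normal(0, s, (d, d)))
            self._param(p + "attn_out_bias", np.zeros(d))
            self._param(p + "ln_1_g", np.ones(d))
            self._param(p + "ln_1_bias", np.zeros(d))
            self._param(p + "ffn_w1", rng.normal(0, s, (d, cfg.d_ff)))
            self._param(p + "ffn_bias1", np.zeros(cfg.d_ff))
            self._param(p + "ffn_w2", rng.normal(0, s, (cfg.d_ff, d)))
            self._param(p + "ffn_bias2", np.zeros(d))
            self._param(p + "ln_2_g", np.ones(d))
            self._param(p + "ln_2_bias", np.zeros(d))
        self._param("mlm_w", rng.normal(0, s, (d, cfg.vocab_size)))
        self._param("mlm_bias", np.zeros(cfg.vocab_size))

    # -- forward -----------------------------------------------------------

    def _split_heads(self, x: Tensor, b: int, n: int) -> Tensor:
        cfg = self.cfg
        return x.reshape(b, n, cfg.n_heads, cfg.d_k).transpose(0, 2, 1, 3)

    def _act(self, x: Tensor) -> Tensor:
        return x.gelu() if self.cfg.activation == "gelu" else x.relu()

    def forward(
        self,
        token_ids: np.ndarray,
        pad_mask: np.ndarray | None = None,
        position_offset: int = 0,
    ) -> Tensor:
        """Final-layer hidden states (B, N, d).

        ``pad_mask``: bool (B, N), True at real tokens.  ``position_offset``
        shifts absolute position ids; it has no effect in relative mode
        (translation equivariance).
        """
        cfg = self.cfg
        token_ids = np.atleast_2d(np.asarray(token_ids, dtype=np.int64))
        if token_ids.min() < 0 or token_ids.max() >= cfg.vocab_size:
            raise ValueError("token id out of vocabulary range")
        b, n = token_ids.shape
        x = self.params["embed"].embed(token_ids)
        if cfg.position_mode == "absolute_learned":
            if position_offset + n > cfg.max_len:
                raise ValueError("sequence exceeds absolute position table")
            pos = np.arange(position_offset, position_offset + n)
            x = x + self.params["abs_pos"].embed(pos)
        # normalize embeddings so first-layer attention scores start O(1)
        x = x.layer_norm(self.params["emb_ln_g"], self.params["emb_ln_bias"])
        if pad_mask is None:
            attn_bias = None
        else:
            attn_bias = np.where(pad_mask, 0.0, NEG_INF).astype(DTYPE)[:, None, None, :]
        delta = (
            rel_index_matrix(n, cfg.k_max)
            if cfg.position_mode == "relative_disentangled"
            else None
        )
        for li in range(cfg.n_layers):
            x = self._layer(x, li, b, n, delta, attn_bias)
        return x

    def _layer(self, x, li, b, n, delta, attn_bias) -> Tensor:
        cfg = self.cfg
        p = self.params
        pre = f"l{li}."
        # fold the score scale into the queries: cheaper than scaling (B,h,N,N)
        qc = self._split_heads(x @ p[pre + "w_qc"], b, n) * cfg.score_scale
        kc = self._split_heads(x @ p[pre + "w_kc"], b, n)
        v = self._split_heads(x @ p[pre + "w_vc"], b, n)
        scores = qc @ kc.transpose(0, 1, 3, 2)
        if delta is not None:
            m = 2 * cfg.k_max + 1
            rel_p = p["rel_P"].layer_norm(p["rel_ln_g"], p["rel_ln_bias"])
            kr = (rel_p @ p[pre + "w_kr"]).reshape(m, cfg.n_heads, cfg.d_k).transpose(1, 0, 2)
            scores = scores + (qc @ kr.transpose(0, 2, 1)).gather_last(delta)
            if cfg.p2c_variant == "as_printed":
                qr = self._split_heads(x @ p[pre + "w_qr"], b, n) * cfg.score_scale
                scores = scores + qr @ kc.transpose(0, 1, 3, 2)
            else:
                qr_tab = (rel_p @ p[pre + "w_qr"]).reshape(m, cfg.n_heads, cfg.d_k).transpose(1, 0, 2)
                mt = (kc * cfg.score_scale) @ qr_tab.transpose(0, 2, 1)  # (B,h,N,M)
                scores = scores + mt.gather_last(delta).transpose(0, 1, 3, 2)
        if attn_bias is not None:
            scores = scores + attn_bias
        probs = scores.softmax(axis=-1)
        ho = (probs @ v).transpose(0, 2, 1, 3).reshape(b, n, cfg.d_model)
        ho = ho @ p[pre + "attn_out_w"] + p[pre + "attn_out_bias"]
        x = (x + ho).layer_norm(p[pre + "ln_1_g"], p[pre + "ln_1_bias"])
        ff = self._act(x @ p[pre + "ffn_w1"] + p[pre + "ffn_bias1"]) @ p[pre + "ffn_w2"] + p[pre + "ffn_bias2"]
        return (x + ff).layer_norm(p[pre + "ln_2_g"], p[pre + "ln_2_bias"])

    def mlm_logits(self, hidden: Tensor) -> Tensor:
        """Single affine map from hidden states to vocabulary scores."""
        return hidden @ self.params["mlm_w"] + self.params["mlm_bias"]

    # -- convenience -------------------------------------------------------

    def encode(self, token_ids: np.ndarray, pad_mask=None, position_offset: int = 0) -> np.ndarray:
        """Forward pass returning a plain array (no gradient use intended)."""
        return self.forward(token_ids, pad_mask, position_offset).data

    def param_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k].data).tobytes())
        return h.hexdigest()

    # -- checkpointing -----------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": self.cfg.to_dict(),
            "alphabet": self.alphabet.to_dict(),
            "seed": self.seed,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        arrays = {k: self.params[k].data for k in sorted(self.params)}
        with open(directory / "params.npz", "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, directory) -> "Encoder":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        cfg = EncoderConfig.from_dict(meta["config"])
        alphabet = ResidueAlphabet.from_dict(meta["alphabet"])
        enc = cls(cfg, seed=meta["seed"], alphabet=alphabet)
        with np.load(directory / "params.npz") as npz:
            if set(npz.files) != set(enc.params):
                raise ValueError("checkpoint parameter names do not match config")
            for k in npz.files:
                if npz[k].shape != enc.params[k].data.shape:
                    raise ValueError(f"checkpoint shape mismatch for {k}")
                enc.params[k].data = npz[k].astype(DTYPE)
        return enc
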