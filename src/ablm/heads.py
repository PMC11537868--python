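"""Frozen-encoder downstream heads.

Pairing: mean-pooled chain representations are mapped by per-chain-type
two-layer MLPs into a shared space, L2-normalized, and compared by cosine
similarity (reported rescaled to [0, 1]); training minimizes an InfoNCE
loss over one positive and sampled negative light chains whose identity to
the true partner is below 0.85.

Binding: the hidden states of the CDR3 tokens only are projected per
position by a single linear layer, flattened at a fixed padded length, and
classified by a two-layer MLP under cross-entropy.

The encoder is never updated: features are precomputed with plain forward
passes and a parameter hash is asserted unchanged around head training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from ._nn import DTYPE, AdamW, Tensor
from .abcore import AnnotatedChain, region_token_indices, tokenize
from .curation import pairwise_identity
from .encoder import Encoder

logger = logging.getLogger(__name__)

__all__ = [
    "PairingHeadConfig",
    "PairingHead",
    "PairingExample",
    "BindingHeadConfig",
    "BindingHead",
    "BindingExample",
    "mean_pool",
    "pooled_embedding",
    "pairing_score",
    "info_nce",
    "sample_negatives",
    "train_pairing",
    "eval_pairing",
    "binding_forward",
    "train_eval_binding",
    "read_pairs_csv",
    "write_pairs_csv",
    "read_binding_csv",
    "write_binding_csv",
]


# ---------------------------------------------------------------------------
# Shared pieces
# ---------------------------------------------------------------------------


def mean_pool(hidden: np.ndarray, token_mask: np.ndarray) -> np.ndarray:
    """Mean over residue tokens only ([CLS]/[SEP]/pad excluded)."""
    hidden = np.asarray(hidden)
    token_mask = np.asarray(token_mask, dtype=bool)
    if hidden.shape[0] != token_mask.shape[0]:
        raise ValueError("hidden and token_mask length mismatch")
    if not token_mask.any():
        raise ValueError("no residue tokens to pool")
    return hidden[token_mask].mean(axis=0)


def pooled_embedding(encoder: Encoder, chain: AnnotatedChain) -> np.ndarray:
    tok = tokenize(chain, encoder.alphabet)
    ids = np.array(tok.token_ids)
    hidden = encoder.encode(ids[None, :])[0]
    mask = np.zeros(len(ids), dtype=bool)
    mask[list(tok.residue_indices)] = True
    return mean_pool(hidden, mask)


def _l2norm(z: Tensor) -> Tensor:
    return z * ((z * z).sum(axis=-1, keepdims=True) + 1e-12).power(-0.5)


def _mlp2(x: Tensor, w1, b1, w2, b2) -> Tensor:
    return (x @ w1 + b1).relu() @ w2 + b2


# ---------------------------------------------------------------------------
# Pairing head
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairingHeadConfig:
    d_proj: int = 64
    temperature: float = 0.1
    n_neg: int = 15
    shared_projection: bool = False
    epochs: int = 40
    lr: float = 1e-3
    batch_size: int = 64

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_neg < 1:
            raise ValueError("n_neg must be >= 1")


class PairingHead:
    """Two-layer projection MLPs (separate or shared across chain types)."""

    def __init__(self, d_model: int, cfg: PairingHeadConfig, seed: int = 0):
        self.cfg = cfg
        self.d_model = d_model
        rng = np.random.default_rng(seed)
        dp = cfg.d_proj
        scale = 1.0 / np.sqrt(d_model)
        self.params: dict[str, Tensor] = {}
        kinds = ("shared",) if cfg.shared_projection else ("heavy", "light")
        for kind in kinds:
            self.params[f"{kind}_w1"] = Tensor(rng.normal(0, scale, (d_model, dp)), requires_grad=True)
            self.params[f"{kind}_bias1"] = Tensor(np.zeros(dp), requires_grad=True)
            self.params[f"{kind}_w2"] = Tensor(rng.normal(0, 1 / np.sqrt(dp), (dp, dp)), requires_grad=True)
            self.params[f"{kind}_bias2"] = Tensor(np.zeros(dp), requires_grad=True)

    def project(self, pooled: Tensor | np.ndarray, chain_type: str) -> Tensor:
        """Projected, L2-normalized representation."""
        kind = "shared" if self.cfg.shared_projection else chain_type
        x = pooled if isinstance(pooled, Tensor) else Tensor(pooled)
        z = _mlp2(
            x,
            self.params[f"{kind}_w1"],
            self.params[f"{kind}_bias1"],
            self.params[f"{kind}_w2"],
            self.params[f"{kind}_bias2"],
        )
        norms = np.sqrt((z.data**2).sum(axis=-1))
        if np.any(norms < 1e-30):
            raise ValueError("zero-norm projected vector")
        return _l2norm(z)


@dataclass(frozen=True)
class PairingExample:
    heavy: AnnotatedChain
    true_light: AnnotatedChain
    negatives: tuple[AnnotatedChain, ...] = ()


def pairing_score(h_vec: np.ndarray, l_vec: np.ndarray) -> float:
    """(cosine + 1) / 2 of two unit vectors; the [0, 1]-rescaled report score."""
    h = np.asarray(h_vec, dtype=np.float64)
    l = np.asarray(l_vec, dtype=np.float64)
    if min(np.linalg.norm(h), np.linalg.norm(l)) < 1e-30:
        raise ValueError("zero-norm vector")
    cos = float(h @ l / (np.linalg.norm(h) * np.linalg.norm(l)))
    return (cos + 1.0) / 2.0


def info_nce(pos_sim: float, neg_sims, tau: float = 0.1) -> float:
    """-log( e^{pos/tau} / (e^{pos/tau} + sum_i e^{neg_i/tau}) )."""
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    sims = np.concatenate([[pos_sim], np.asarray(neg_sims, dtype=np.float64)]) / tau
    z = sims - sims.max()
    return float(-(z[0] - np.log(np.exp(z).sum())))


def sample_negatives(
    true_light: AnnotatedChain,
    light_pool: list[AnnotatedChain],
    n: int,
    rng: np.random.Generator,
    max_identity: float = 0.85,
) -> list[AnnotatedChain]:
    """Uniform sample of lights with identity(candidate, true partner) < max_identity."""
    eligible = [
        l
        for l in light_pool
        if l.id != true_light.id
        and pairwise_identity(l.sequence, true_light.sequence) < max_identity
    ]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible negatives (< {n}) below identity {max_identity}"
        )
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in idx]


def train_pairing(
    encoder: Encoder,
    examples: list[PairingExample],
    cfg: PairingHeadConfig = PairingHeadConfig(),
    seed: int = 0,
) -> PairingHead:
    """Train the projection layers on a frozen encoder; InfoNCE per positive."""
    hash_before = encoder.param_hash()
    head = PairingHead(encoder.cfg.d_model, cfg, seed=seed)
    # frozen encoder: features are plain arrays, gradients cannot reach it
    h_feats = np.stack([pooled_embedding(encoder, ex.heavy) for ex in examples])
    l_feats = np.stack([pooled_embedding(encoder, ex.true_light) for ex in examples])
    neg_feats = np.stack(
        [[pooled_embedding(encoder, n) for n in ex.negatives] for ex in examples]
    )  # (n, n_neg, d)
    if neg_feats.shape[1] < 1:
        raise ValueError("pairing examples carry no negatives")
    opt = AdamW(head.params, lr=cfg.lr, weight_decay=0.0)
    rng = np.random.default_rng(seed)
    n = len(examples)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            h = head.project(h_feats[idx], "heavy")  # (b, dp)
            pos = head.project(l_feats[idx], "light")
            b, n_neg = len(idx), neg_feats.shape[1]
            neg = head.project(neg_feats[idx].reshape(b * n_neg, -1), "light").reshape(b, n_neg, -1)
            pos_sim = (h * pos).sum(axis=-1, keepdims=True)  # (b, 1)
            neg_sim = (neg @ h.reshape(b, -1, 1)).reshape(b, n_neg)
            logits = _concat_cols(pos_sim, neg_sim) * (1.0 / cfg.temperature)
            loss = logits.cross_entropy_smoothed(np.zeros(b, dtype=np.int64), 0.0)
            opt.zero_grad()
            loss.backward()
            opt.step(clip_norm=None)
    if encoder.param_hash() != hash_before:
        raise RuntimeError("encoder parameters changed during head training (freeze contract)")
    return head


def _concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Column concatenation built from padding-by-matmul (avoids a concat op)."""
    na, nb = a.shape[-1], b.shape[-1]
    ea = np.zeros((na, na + nb), dtype=DTYPE)
    ea[:, :na] = np.eye(na)
    eb = np.zeros((nb, na + nb), dtype=DTYPE)
    eb[:, na:] = np.eye(nb)
    return a @ Tensor(ea) + b @ Tensor(eb)


def eval_pairing(
    head: PairingHead,
    encoder: Encoder,
    test_pairs: list[PairingExample],
    light_pool: list[AnnotatedChain],
    rng: np.random.Generator,
    n_repeats: int = 5,
    n_neg: int | None = None,
    max_identity: float = 0.85,
) -> dict:
    """Mean auROC / auPRC over repeats with fresh negative resampling."""
    n_neg = n_neg if n_neg is not None else head.cfg.n_neg
    h_proj = {
        ex.heavy.id: head.project(pooled_embedding(encoder, ex.heavy), "heavy").data
        for ex in test_pairs
    }
    l_cache: dict[str, np.ndarray] = {}

    def light_vec(chain: AnnotatedChain) -> np.ndarray:
        if chain.id not in l_cache:
            l_cache[chain.id] = head.project(pooled_embedding(encoder, chain), "light").data
        return l_cache[chain.id]

    aurocs, auprcs = [], []
    for _ in range(n_repeats):
        y, s = [], []
        for ex in test_pairs:
            hv = h_proj[ex.heavy.id]
            y.append(1)
            s.append(pairing_score(hv, light_vec(ex.true_light)))
            for neg in sample_negatives(ex.true_light, light_pool, n_neg, rng, max_identity):
                y.append(0)
                s.append(pairing_score(hv, light_vec(neg)))
        if len(set(y)) < 2:
            raise ValueError("a repeat produced a single class; cannot compute auROC")
        aurocs.append(roc_auc_score(y, s))
        auprcs.append(average_precision_score(y, s))
    return {
        "auroc_mean": float(np.mean(aurocs)),
        "auprc_mean": float(np.mean(auprcs)),
        "auroc": [float(x) for x in aurocs],
        "auprc": [float(x) for x in auprcs],
    }


# ---------------------------------------------------------------------------
# Binding head
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingHeadConfig:
    cdr3_max_len: int = 20
    d_proj: int = 16
    d_hidden: int = 64
    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 64
    crop_long_cdr3: bool = True


@dataclass(frozen=True)
class BindingExample:
    id: str
    vh_seq: str
    cdr3: tuple[int, int]
    label: int

    def __post_init__(self) -> None:
        a, b = self.cdr3
        if not 0 <= a < b <= len(self.vh_seq):
            raise ValueError(f"invalid CDR3 interval {self.cdr3} for length {len(self.vh_seq)}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


class BindingHead:
    def __init__(self, d_model: int, cfg: BindingHeadConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        flat = cfg.cdr3_max_len * cfg.d_proj
        self.params = {
            "proj_w": Tensor(rng.normal(0, 1 / np.sqrt(d_model), (d_model, cfg.d_proj)), requires_grad=True),
            "proj_bias": Tensor(np.zeros(cfg.d_proj), requires_grad=True),
            "cls_w1": Tensor(rng.normal(0, 1 / np.sqrt(flat), (flat, cfg.d_hidden)), requires_grad=True),
            "cls_bias1": Tensor(np.zeros(cfg.d_hidden), requires_grad=True),
            "cls_w2": Tensor(rng.normal(0, 1 / np.sqrt(cfg.d_hidden), (cfg.d_hidden, 2)), requires_grad=True),
            "cls_bias2": Tensor(np.zeros(2), requires_grad=True),
        }

    def logits(self, feats: np.ndarray | Tensor) -> Tensor:
        """(b, cdr3_max_len, d_model) zero-padded CDR3 features -> (b, 2) logits."""
        x = feats if isinstance(feats, Tensor) else Tensor(feats)
        b = x.shape[0]
        z = x @ self.params["proj_w"] + self.params["proj_bias"]
        flat = z.reshape(b, self.cfg.cdr3_max_len * self.cfg.d_proj)
        return _mlp2(flat, self.params["cls_w1"], self.params["cls_bias1"], self.params["cls_w2"], self.params["cls_bias2"])


def cdr3_features(encoder: Encoder, example: BindingExample, cfg: BindingHeadConfig) -> np.ndarray:
    """Padded/cropped CDR3 hidden states (cdr3_max_len, d); zero-vector padding."""
    chain = AnnotatedChain(example.id, "heavy", example.vh_seq)
    tok = tokenize(chain, encoder.alphabet)
    hidden = encoder.encode(np.array(tok.token_ids)[None, :])[0]
    a, b = example.cdr3
    rows = hidden[a + 1 : b + 1]  # +1 for [CLS]
    if rows.shape[0] > cfg.cdr3_max_len:
        if not cfg.crop_long_cdr3:
            raise ValueError(f"CDR3 length {rows.shape[0]} exceeds cdr3_max_len {cfg.cdr3_max_len}")
        logger.warning("cropping CDR3 of %s from %d to %d", example.id, rows.shape[0], cfg.cdr3_max_len)
        rows = rows[: cfg.cdr3_max_len]
    out = np.zeros((cfg.cdr3_max_len, hidden.shape[-1]), dtype=hidden.dtype)
    out[: rows.shape[0]] = rows
    return out


def binding_forward(encoder: Encoder, example: BindingExample, head: BindingHead) -> float:
    """Probability of label 1 for a single example."""
    feats = cdr3_features(encoder, example, head.cfg)[None, :, :]
    logits = head.logits(feats).data[0]
    z = logits - logits.max()
    p = np.exp(z) / np.exp(z).sum()
    return float(p[1])


def _fit_binding(feats, labels, train_idx, val_idx, d_model, cfg, seed):
    head = BindingHead(d_model, cfg, seed=seed)
    opt = AdamW(head.params, lr=cfg.lr, weight_decay=0.0)
    rng = np.random.default_rng(seed)
    best_val, best_state = -1.0, None
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        for s in range(0, len(train_idx), cfg.batch_size):
            idx = train_idx[order[s : s + cfg.batch_size]]
            logits = head.logits(feats[idx])
            loss = logits.cross_entropy_smoothed(labels[idx], 0.0)
            opt.zero_grad()
            loss.backward()
            opt.step(clip_norm=None)
        val_pred = head.logits(feats[val_idx]).data.argmax(axis=-1)
        val_acc = float((val_pred == labels[val_idx]).mean())
        if val_acc > best_val:
            best_val = val_acc
            best_state = {k: v.data.copy() for k, v in head.params.items()}
    for k, v in best_state.items():
        head.params[k].data = v
    return head, best_val


def _metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    return {
        "accuracy": float((pred == truth).mean()),
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
    }


def train_eval_binding(
    encoder: Encoder,
    dataset: list[BindingExample],
    cfg: BindingHeadConfig = BindingHeadConfig(),
    n_splits: int = 5,
    seeds: list[int] | None = None,
    subsample: float | None = None,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> dict:
    """Repeated random sub-sampling validation of the binding head.

    Per seed: random train/val/test split, optional training-set subsample
    (e.g. 0.01 for the low-data protocol), head training with cross-entropy,
    best-on-validation epoch selection, then test metrics; means over seeds.
    """
    seeds = seeds if seeds is not None else list(range(n_splits))
    hash_before = encoder.param_hash()
    feats = np.stack([cdr3_features(encoder, ex, cfg) for ex in dataset])
    labels = np.array([ex.label for ex in dataset], dtype=np.int64)
    results: list[dict] = []
    queue = list(seeds)
    extra = max(seeds) + 1 if seeds else 0
    while queue:
        seed = queue.pop(0)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(dataset))
        n_train = int(round(split_fractions[0] * len(dataset)))
        n_val = int(round(split_fractions[1] * len(dataset)))
        train_idx = order[:n_train]
        val_idx = order[n_train : n_train + n_val]
        test_idx = order[n_train + n_val :]
        if subsample is not None:
            n_sub = int(round(subsample * len(train_idx)))
            train_idx = train_idx[rng.permutation(len(train_idx))[:n_sub]]
        if len(set(labels[train_idx])) < 2:
            logger.warning("seed %d training split lacks a class; resampling with seed %d", seed, extra)
            queue.append(extra)
            extra += 1
            continue
        head, val_acc = _fit_binding(feats, labels, train_idx, val_idx, encoder.cfg.d_model, cfg, seed)
        test_pred = head.logits(feats[test_idx]).data.argmax(axis=-1)
        val_pred = head.logits(feats[val_idx]).data.argmax(axis=-1)
        rec = {"seed": seed, "n_train": int(len(train_idx))}
        rec.update({f"test_{k}": v for k, v in _metrics(test_pred, labels[test_idx]).items()})
        rec.update({f"val_{k}": v for k, v in _metrics(val_pred, labels[val_idx]).items()})
        results.append(rec)
    if encoder.param_hash() != hash_before:
        raise RuntimeError("encoder parameters changed during head training (freeze contract)")
    summary = {"splits": results, "n_train": results[0]["n_train"]}
    for key in ("test_accuracy", "test_recall", "test_precision", "val_accuracy", "val_recall", "val_precision"):
        summary[f"{key}_mean"] = float(np.mean([r[key] for r in results]))
    return summary


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_pairs_csv(path, pairs: list[PairingExample]) -> None:
    pd.DataFrame(
        {
            "pair_id": [p.heavy.id for p in pairs],
            "heavy_seq": [p.heavy.sequence for p in pairs],
            "light_seq": [p.true_light.sequence for p in pairs],
        }
    ).to_csv(path, index=False)


def read_pairs_csv(path) -> list[PairingExample]:
    df = pd.read_csv(path)
    return [
        PairingExample(
            AnnotatedChain(f"{r.pair_id}_H", "heavy", r.heavy_seq),
            AnnotatedChain(f"{r.pair_id}_L", "light", r.light_seq),
        )
        for r in df.itertuples()
    ]


def write_binding_csv(path, examples: list[BindingExample]) -> None:
    pd.DataFrame(
        {
            "id": [e.id for e in examples],
            "vh_seq": [e.vh_seq for e in examples],
            "cdr3_start": [e.cdr3[0] for e in examples],
            "cdr3_end": [e.cdr3[1] for e in examples],
            "label": [e.label for e in examples],
        }
    ).to_csv(path, index=False)


def read_binding_csv(path) -> list[BindingExample]:
    df = pd.read_csv(path)
    return [
        BindingExample(str(r.id), r.vh_seq, (int(r.cdr3_start), int(r.cdr3_end)), int(r.label))
        for r in df.itertuples()
    ]
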