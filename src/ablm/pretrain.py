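"""Masked-language-model training loop.

Heavy and light chains are trained jointly in one model; each step applies
truncation augmentation, tokenizes, corrupts per the configured masking
strategy, and takes an AdamW step on a label-smoothed cross-entropy over the
selected positions only, under a cosine-with-warmup schedule.

Three independent rng streams (data order + augmentation, mask sampling,
parameter init) are derived from the config seed so that ablations with
different masking strategies see identical data order.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import log_softmax

from ._nn import AdamW, Tensor
from .abcore import (
    DEFAULT_ALPHABET,
    AnnotatedChain,
    RegionAnnotation,
    TokenizedSequence,
    tokenize,
)
from .encoder import Encoder, EncoderConfig
from .masking import IGNORE_LABEL, MaskingConfig, apply_mask, mask_heavy, mask_light, random_mask

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "truncation_augment",
    "label_smoothed_ce",
    "cosine_warmup_lr",
    "train_mlm",
    "stream_rng",
    "mlm_accuracy",
]


@dataclass(frozen=True)
class TrainConfig:
    """Desk-scale defaults; the full-scale preset uses batch 784 over 200 epochs
    with 15 warmup epochs."""

    base_lr: float = 3e-4
    betas: tuple[float, float] = (0.9, 0.99)
    weight_decay: float = 0.01
    batch_size: int = 32
    epochs: int = 3
    warmup_epochs: float = 1.0
    label_smoothing: float = 0.1
    grad_clip: float | None = 1.0
    augment: bool = True
    strategy: str = "cdr3_focus"  # or "uniform_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.warmup_epochs < self.epochs:
            raise ValueError("warmup_epochs must be < epochs")
        if not 0 <= self.label_smoothing < 1:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.strategy not in ("cdr3_focus", "uniform_random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["betas"] = list(self.betas)
        return d


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named rng stream: stable under addition of new stream names."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def truncation_augment(chain: AnnotatedChain, rng: np.random.Generator) -> AnnotatedChain:
    """Remove Uniform{0..3} residues independently from each terminus.

    Region intervals are shifted/clipped.  If the truncation would empty any
    region the augmentation is skipped for this sample.
    """
    L = len(chain.sequence)
    if L <= 8:
        return chain
    n = int(rng.integers(4))
    m = int(rng.integers(4))
    if n == 0 and m == 0:
        return chain
    new_len = L - n - m
    seq = chain.sequence[n : L - m]
    regions = chain.regions
    if regions is not None:
        intervals = []
        for a, b in regions.intervals:
            a2 = min(max(a - n, 0), new_len)
            b2 = min(max(b - n, 0), new_len)
            if b2 <= a2:
                logger.warning(
                    "truncation (%d, %d) would empty a region of chain %s; skipped", n, m, chain.id
                )
                return chain
            intervals.append((a2, b2))
        regions = RegionAnnotation(tuple(intervals))
    return replace(chain, sequence=seq, regions=regions)


def label_smoothed_ce(logits: np.ndarray, labels: np.ndarray, eps: float = 0.1) -> float:
    """Mean -sum_c q_c log p_c over rows with label != IGNORE_LABEL.

    ``q = (1-eps) * onehot + eps/V``.  Independent NumPy implementation used
    for reporting and as the reference for the training-loop loss.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    keep = labels != IGNORE_LABEL
    if not keep.any():
        raise ValueError("all labels are ignored; nothing to score")
    logits, labels = logits[keep], labels[keep]
    n, v = logits.shape
    logp = log_softmax(logits, axis=-1)
    q = np.full((n, v), eps / v)
    q[np.arange(n), labels] += 1.0 - eps
    return float(-(q * logp).sum() / n)


def cosine_warmup_lr(step: int, steps_per_epoch: int, cfg: TrainConfig) -> float:
    """Linear 0 -> base_lr over the warmup epochs, then cosine decay to 0."""
    if step < 0:
        raise ValueError("step must be >= 0")
    warmup = cfg.warmup_epochs * steps_per_epoch
    total = cfg.epochs * steps_per_epoch
    if step < warmup:
        return cfg.base_lr * step / warmup
    t = (step - warmup) / max(total - warmup, 1)
    t = min(t, 1.0)
    return cfg.base_lr * 0.5 * (1.0 + np.cos(np.pi * t))


def plan_for(
    chain: AnnotatedChain,
    tok: TokenizedSequence,
    masking_cfg: MaskingConfig,
    strategy: str,
    rng: np.random.Generator,
):
    if strategy == "uniform_random":
        return random_mask(tok, masking_cfg, rng)
    if chain.chain_type == "heavy":
        if chain.regions is None:
            raise ValueError(f"heavy chain {chain.id!r} lacks the CDR3 annotation required by cdr3_focus masking")
        return mask_heavy(tok, masking_cfg, rng)
    return mask_light(tok, masking_cfg, rng)


def _make_batch(items, pad_id):
    n = max(len(t[1].token_ids) for t in items)
    b = len(items)
    ids = np.full((b, n), pad_id, dtype=np.int64)
    labels = np.full((b, n), IGNORE_LABEL, dtype=np.int64)
    mask = np.zeros((b, n), dtype=bool)
    for r, (_, tok, corrupted, lab) in enumerate(items):
        L = len(corrupted)
        ids[r, :L] = corrupted
        labels[r, :L] = lab
        mask[r, :L] = True
    return ids, labels, mask


def train_mlm(
    corpus: list[AnnotatedChain],
    masking_cfg: MaskingConfig,
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    out_dir=None,
    resume_from=None,
) -> tuple[Encoder, list[dict]]:
    """Train an encoder on ``corpus``; returns (encoder, metrics records).

    With ``out_dir`` set, writes ``metrics.jsonl`` and an ``epoch_<e>``
    checkpoint (encoder + optimizer + rng state) after every epoch, from
    which :func:`train_mlm` can resume bit-for-bit via ``resume_from``.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    alphabet = DEFAULT_ALPHABET
    data_rng = stream_rng(train_cfg.seed, "data")
    mask_rng = stream_rng(train_cfg.seed, "masking")
    encoder = Encoder(encoder_cfg, seed=int(stream_rng(train_cfg.seed, "init").integers(2**31)))
    opt = AdamW(
        encoder.params,
        lr=train_cfg.base_lr,
        betas=train_cfg.betas,
        weight_decay=train_cfg.weight_decay,
    )
    steps_per_epoch = max(len(corpus) // train_cfg.batch_size, 1)
    metrics: list[dict] = []
    step = 0
    start_epoch = 0

    if resume_from is not None:
        resume_from = Path(resume_from)
        encoder = Encoder.load(resume_from / "encoder")
        opt = AdamW(
            encoder.params,
            lr=train_cfg.base_lr,
            betas=train_cfg.betas,
            weight_decay=train_cfg.weight_decay,
        )
        with np.load(resume_from / "optimizer.npz") as npz:
            opt.load_state_dict(
                {
                    "t": int(npz["t"]),
                    "m": {k[2:]: npz[k] for k in npz.files if k.startswith("m.")},
                    "v": {k[2:]: npz[k] for k in npz.files if k.startswith("v.")},
                }
            )
        state = json.loads((resume_from / "train_state.json").read_text())
        data_rng.bit_generator.state = state["data_rng"]
        mask_rng.bit_generator.state = state["mask_rng"]
        step = state["step"]
        start_epoch = state["epoch"]

    by_index = list(corpus)
    for epoch in range(start_epoch, train_cfg.epochs):
        order = data_rng.permutation(len(by_index))
        for bstart in range(0, steps_per_epoch * train_cfg.batch_size, train_cfg.batch_size):
            batch_chains = [by_index[i] for i in order[bstart : bstart + train_cfg.batch_size]]
            items = []
            realized = []
            for chain in batch_chains:
                if train_cfg.augment:
                    chain = truncation_augment(chain, data_rng)
                tok = tokenize(chain, alphabet)
                plan = plan_for(chain, tok, masking_cfg, train_cfg.strategy, mask_rng)
                corrupted, labels, _ = apply_mask(tok, plan, masking_cfg.policy, mask_rng, alphabet)
                items.append((chain, tok, corrupted, labels))
                realized.append(len(plan.selected) / tok.n_residues)
            ids, labels, pad_mask = _make_batch(items, alphabet.pad_id)
            hidden = encoder.forward(ids, pad_mask)
            logits = encoder.mlm_logits(hidden)
            flat = logits.reshape(ids.size, encoder_cfg.vocab_size)
            rows = np.flatnonzero(labels.reshape(-1) != IGNORE_LABEL)
            loss = flat.take_rows(rows).cross_entropy_smoothed(
                labels.reshape(-1)[rows], train_cfg.label_smoothing
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at step {step}; batch ids={[c.id for c in batch_chains]}"
                )
            opt.zero_grad()
            loss.backward()
            opt.lr = cosine_warmup_lr(step, steps_per_epoch, train_cfg)
            opt.step(clip_norm=train_cfg.grad_clip)
            metrics.append(
                {
                    "step": step,
                    "epoch": epoch,
                    "lr": float(opt.lr),
                    "loss": float(loss.data),
                    "realized_mask_rate": float(np.mean(realized)),
                }
            )
            step += 1
        if out_dir is not None:
            _checkpoint(Path(out_dir), epoch, step, encoder, opt, data_rng, mask_rng, metrics)
    if out_dir is not None:
        _write_metrics(Path(out_dir), metrics)
    return encoder, metrics


def _checkpoint(out_dir: Path, epoch, step, encoder, opt, data_rng, mask_rng, metrics) -> None:
    ckpt = out_dir / f"epoch_{epoch}"
    encoder.save(ckpt / "encoder")
    state = opt.state_dict()
    arrays = {"t": np.array(state["t"])}
    arrays.update({f"m.{k}": v for k, v in state["m"].items()})
    arrays.update({f"v.{k}": v for k, v in state["v"].items()})
    with open(ckpt / "optimizer.npz", "wb") as fh:
        np.savez(fh, **arrays)
    (ckpt / "train_state.json").write_text(
        json.dumps(
            {
                "epoch": epoch + 1,
                "step": step,
                "data_rng": data_rng.bit_generator.state,
                "mask_rng": mask_rng.bit_generator.state,
            }
        )
    )
    _write_metrics(out_dir, metrics)


def _write_metrics(out_dir: Path, metrics: list[dict]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "metrics.jsonl", "w") as fh:
        for rec in metrics:
            fh.write(json.dumps(rec) + "\n")


def mlm_accuracy(
    encoder: Encoder,
    chains: list[AnnotatedChain],
    masking_cfg: MaskingConfig,
    strategy: str,
    seed: int = 0,
) -> float:
    """Held-out masked-token top-1 accuracy under the given strategy."""
    rng = stream_rng(seed, "eval-mask")
    alphabet = encoder.alphabet
    correct = total = 0
    for chain in chains:
        tok = tokenize(chain, alphabet)
        plan = plan_for(chain, tok, masking_cfg, strategy, rng)
        corrupted, labels, _ = apply_mask(tok, plan, masking_cfg.policy, rng, alphabet)
        logits = encoder.mlm_logits(encoder.forward(corrupted[None, :])).data[0]
        sel = np.flatnonzero(labels != IGNORE_LABEL)
        correct += int((logits[sel].argmax(axis=-1) == labels[sel]).sum())
        total += len(sel)
    return correct / total
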