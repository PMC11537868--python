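"""Corruption planning for masked-language-model training.

The heavy-chain strategy first masks a fixed fraction of CDR3 (a contiguous
span at a random offset by default), then span-masks the remaining regions
until a total budget of ``round(total_rate * n_residues)`` positions is
selected.  Light chains are span-masked uniformly with no region targeting.
Budgets are counted over residue tokens only; special tokens are never
selected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .abcore import DEFAULT_ALPHABET, ResidueAlphabet, TokenizedSequence, region_token_indices

logger = logging.getLogger(__name__)

__all__ = [
    "MaskingConfig",
    "MaskPlan",
    "select_random",
    "select_spans",
    "mask_heavy",
    "mask_light",
    "random_mask",
    "apply_mask",
    "IGNORE_LABEL",
]

#: label value marking positions excluded from the MLM loss
IGNORE_LABEL = -100

STUDIED_RATES = (0.15, 0.30, 0.50, 0.70, 0.90)


@dataclass(frozen=True)
class MaskingConfig:
    total_rate: float = 0.70
    cdr3_internal_rate: float = 0.70
    cdr3_mode: str = "contiguous_span"  # or "random_subset"
    span_mean: float = 3.0
    span_cap: int = 10
    policy: str = "ALL_MASK"  # or "BERT_80_10_10"

    def __post_init__(self) -> None:
        for name in ("total_rate", "cdr3_internal_rate"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.span_cap < 1:
            raise ValueError("span_cap must be >= 1")
        if self.cdr3_mode not in ("contiguous_span", "random_subset"):
            raise ValueError(f"unknown cdr3_mode {self.cdr3_mode!r}")
        if self.policy not in ("ALL_MASK", "BERT_80_10_10"):
            raise ValueError(f"unknown policy {self.policy!r}")

    def to_dict(self) -> dict:
        return {
            "total_rate": self.total_rate,
            "cdr3_internal_rate": self.cdr3_internal_rate,
            "cdr3_mode": self.cdr3_mode,
            "span_mean": self.span_mean,
            "span_cap": self.span_cap,
            "policy": self.policy,
        }


@dataclass(frozen=True)
class MaskPlan:
    """Selected token indices (sorted) with their original token ids."""

    selected: tuple[int, ...]
    labels: tuple[int, ...]
    actions: tuple[str, ...] | None = None  # filled by apply_mask

    def __post_init__(self) -> None:
        if len(self.selected) != len(self.labels):
            raise ValueError("selected and labels length mismatch")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_random(eligible, rate: float, rng: np.random.Generator) -> tuple[int, ...]:
    """Uniform sample of exactly round(rate * |eligible|) indices."""
    eligible = sorted(eligible)
    if not eligible:
        raise ValueError("eligible index set is empty")
    n = _round_half_up(rate * len(eligible))
    if n == 0:
        logger.warning("rate %.3f over %d eligible positions rounds to 0", rate, len(eligible))
        return ()
    chosen = rng.choice(len(eligible), size=n, replace=False)
    return tuple(sorted(eligible[i] for i in chosen))


def _runs(indices) -> list[tuple[int, int]]:
    """Maximal contiguous runs of a sorted index set, as half-open (start, end)."""
    runs: list[tuple[int, int]] = []
    for i in sorted(indices):
        if runs and runs[-1][1] == i:
            runs[-1] = (runs[-1][0], i + 1)
        else:
            runs.append((i, i + 1))
    return runs


def select_spans(
    eligible_runs: list[tuple[int, int]],
    budget: int,
    cfg: MaskingConfig,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Draw spans until exactly ``budget`` indices are selected.

    Each draw picks an unselected run with probability proportional to its
    length, a start uniform within it, and a geometric span length
    (mean ``cfg.span_mean``, capped at ``cfg.span_cap``), clipped to the run
    and the remaining budget.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    runs = [(a, b) for a, b in eligible_runs if b > a]
    available = sum(b - a for a, b in runs)
    if budget > available:
        logger.warning("span budget %d exceeds %d available indices; selecting all", budget, available)
        return tuple(i for a, b in runs for i in range(a, b))
    p_geom = 1.0 / max(cfg.span_mean, 1.0)
    selected: list[int] = []
    remaining = budget
    while remaining > 0:
        lengths = np.array([b - a for a, b in runs], dtype=float)
        ri = rng.choice(len(runs), p=lengths / lengths.sum())
        a, b = runs[ri]
        start = a + int(rng.integers(b - a))
        span = min(int(rng.geometric(p_geom)), cfg.span_cap, b - start, remaining)
        selected.extend(range(start, start + span))
        remaining -= span
        # split the run around the selected span
        del runs[ri]
        if start > a:
            runs.append((a, start))
        if start + span < b:
            runs.append((start + span, b))
        runs.sort()
    return tuple(sorted(selected))


def _labels_for(tok: TokenizedSequence, selected) -> MaskPlan:
    return MaskPlan(tuple(selected), tuple(tok.token_ids[i] for i in selected))


def mask_heavy(
    tok: TokenizedSequence, cfg: MaskingConfig, rng: np.random.Generator
) -> MaskPlan:
    """Heavy-chain plan: CDR3-targeted step, then spans over the rest."""
    cdr3 = region_token_indices(tok, "CDR3")
    if not cdr3:
        raise ValueError(
            "heavy-chain masking requires a non-empty CDR3 annotation; "
            "use mask_light or random_mask for unannotated chains"
        )
    k1 = _round_half_up(cfg.cdr3_internal_rate * len(cdr3))
    if cfg.cdr3_mode == "contiguous_span":
        offset = int(rng.integers(len(cdr3) - k1 + 1))
        step1 = list(cdr3[offset : offset + k1])
    else:
        step1 = sorted(cdr3[i] for i in rng.choice(len(cdr3), size=k1, replace=False))

    n_res = tok.n_residues
    budget = _round_half_up(cfg.total_rate * n_res) - len(step1)
    if budget <= 0:
        if budget < 0:
            logger.warning(
                "CDR3 step selected %d positions, exceeding total budget %d",
                len(step1), _round_half_up(cfg.total_rate * n_res),
            )
        return _labels_for(tok, sorted(step1))
    cdr3_set = set(cdr3)
    others = [i for i in tok.residue_indices if i not in cdr3_set]
    step2 = select_spans(_runs(others), budget, cfg, rng)
    return _labels_for(tok, sorted(set(step1) | set(step2)))


def mask_light(
    tok: TokenizedSequence, cfg: MaskingConfig, rng: np.random.Generator
) -> MaskPlan:
    """Light-chain plan: spans over all residues, no region targeting."""
    budget = _round_half_up(cfg.total_rate * tok.n_residues)
    return _labels_for(tok, select_spans(_runs(tok.residue_indices), budget, cfg, rng))


def random_mask(
    tok: TokenizedSequence, cfg: MaskingConfig, rng: np.random.Generator
) -> MaskPlan:
    """Uniform random baseline (no spans, no region targeting)."""
    return _labels_for(tok, select_random(tok.residue_indices, cfg.total_rate, rng))


def apply_mask(
    tok: TokenizedSequence,
    plan: MaskPlan,
    policy: str,
    rng: np.random.Generator,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
) -> tuple[np.ndarray, np.ndarray, MaskPlan]:
    """Corrupt ``tok`` per ``plan``; returns (corrupted ids, labels, plan+actions).

    ``labels`` carries the original token id at selected positions and
    :data:`IGNORE_LABEL` elsewhere.
    """
    residue_set = set(tok.residue_indices)
    for i in plan.selected:
        if i not in residue_set:
            raise ValueError(f"mask plan selects non-residue token index {i}")
    corrupted = np.array(tok.token_ids, dtype=np.int64)
    labels = np.full(len(tok.token_ids), IGNORE_LABEL, dtype=np.int64)
    actions: list[str] = []
    residue_ids = np.array(alphabet.residue_ids)
    for i, orig in zip(plan.selected, plan.labels):
        labels[i] = orig
        if policy == "ALL_MASK":
            action = "mask"
        elif policy == "BERT_80_10_10":
            u = rng.random()
            action = "mask" if u < 0.8 else ("random_replace" if u < 0.9 else "keep")
        else:
            raise ValueError(f"unknown policy {policy!r}")
        if action == "mask":
            corrupted[i] = alphabet.mask_id
        elif action == "random_replace":
            corrupted[i] = int(residue_ids[rng.integers(len(residue_ids))])
        actions.append(action)
    return corrupted, labels, replace(plan, actions=tuple(actions))
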