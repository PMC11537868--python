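"""Region-restoration accuracy, truncation robustness, and CDR3
amino-acid distribution comparison.

Restoration masks whole regions (optionally after slice-style truncation
such as ``10:-5``) and scores top-k accuracy of the predictions, ranked
over the 20 canonical residues with ties broken in fixed residue order.
Distribution reports pool amino-acid frequencies over CDR3 positions per
(family, CDR3 length) group, for the true sequences and for the model's
top-1 reconstructions, summarized by Jensen-Shannon divergence (nats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .abcore import (
    CANONICAL_RESIDUES,
    REGION_NAMES,
    AnnotatedChain,
    RegionAnnotation,
    region_token_indices,
    tokenize,
)
from .encoder import Encoder

logger = logging.getLogger(__name__)

__all__ = [
    "RestorationProtocol",
    "DistributionReport",
    "TRUNCATION_GRID",
    "truncate_spec",
    "mask_region_predict",
    "topk_accuracy",
    "restoration_report",
    "cdr3_distribution",
    "js_divergence",
]

#: truncation protocols exercised alongside the untruncated case
TRUNCATION_GRID = (None, "10:-5", "10:-10", "20:-5")


@dataclass(frozen=True)
class RestorationProtocol:
    regions_to_mask: tuple[str, ...]
    truncation_spec: str | None = None
    topk: tuple[int, ...] = (1, 3)

    def __post_init__(self) -> None:
        if not self.regions_to_mask:
            raise ValueError("regions_to_mask must be non-empty")
        for r in self.regions_to_mask:
            if r not in REGION_NAMES:
                raise ValueError(f"unknown region {r!r}")
        if any(k < 1 for k in self.topk):
            raise ValueError("topk values must be >= 1")

    @property
    def label(self) -> str:
        trunc = self.truncation_spec or "none"
        return f"{'+'.join(self.regions_to_mask)}@{trunc}"


def truncate_spec(chain: AnnotatedChain, spec: str) -> AnnotatedChain:
    """Slice-style truncation ``"a:b"``: keep residues [a, L+b); re-clip regions.

    ``a`` is a non-negative start; ``b`` is negative (counted from the end)
    or empty for the sequence end.
    """
    try:
        a_str, b_str = spec.split(":")
        a = int(a_str) if a_str else 0
        b = int(b_str) if b_str else 0
    except ValueError:
        raise ValueError(f"malformed truncation spec {spec!r}; expected 'a:b'") from None
    if a < 0 or b > 0:
        raise ValueError(f"truncation spec {spec!r}: start must be >= 0 and end <= 0")
    L = len(chain.sequence)
    end = L + b
    if end <= a:
        raise ValueError(f"truncation {spec!r} empties a length-{L} sequence")
    seq = chain.sequence[a:end]
    regions = chain.regions
    if regions is not None:
        new_len = end - a
        intervals = tuple(
            (min(max(s - a, 0), new_len), min(max(e - a, 0), new_len))
            for s, e in regions.intervals
        )
        regions = RegionAnnotation(intervals)
    return replace(chain, sequence=seq, regions=regions)


def mask_region_predict(
    encoder: Encoder, chain: AnnotatedChain, protocol: RestorationProtocol
) -> tuple[np.ndarray, np.ndarray]:
    """Mask the protocol's regions entirely and predict them.

    Returns ``(scores, truth)``: scores of shape (n_masked, 20) over the
    canonical residues, and the true residue indices.
    """
    if protocol.truncation_spec:
        chain = truncate_spec(chain, protocol.truncation_spec)
    if chain.regions is None:
        raise ValueError(f"chain {chain.id!r} has no region annotation")
    tok = tokenize(chain, encoder.alphabet)
    indices: list[int] = []
    for region in protocol.regions_to_mask:
        idx = region_token_indices(tok, region)
        if not idx:
            raise ValueError(
                f"region {region} of chain {chain.id!r} is empty (removed by truncation?)"
            )
        indices.extend(idx)
    indices = sorted(indices)
    ids = np.array(tok.token_ids, dtype=np.int64)
    truth_ids = ids[indices]
    ids[indices] = encoder.alphabet.mask_id
    logits = encoder.mlm_logits(encoder.forward(ids[None, :])).data[0]
    residue_ids = np.array(encoder.alphabet.residue_ids)
    scores = logits[indices][:, residue_ids]
    # truth as indices into the canonical residue order
    id_to_res = {rid: i for i, rid in enumerate(residue_ids)}
    truth = np.array([id_to_res[int(t)] for t in truth_ids])
    return scores, truth


def topk_accuracy(scores: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Fraction of rows whose true class is among the k best scores.

    Ties are broken by fixed class order (stable sort on descending score).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores)
    truth = np.asarray(truth)
    if scores.shape[0] != truth.shape[0]:
        raise ValueError("scores and truth length mismatch")
    ranked = np.argsort(-scores, axis=-1, kind="stable")
    hits = (ranked[:, :k] == truth[:, None]).any(axis=-1)
    return float(hits.mean())


def restoration_report(
    encoder: Encoder,
    dataset: list[AnnotatedChain],
    protocols: list[RestorationProtocol],
) -> pd.DataFrame:
    """Mean per-sequence top-k accuracy for every protocol cell."""
    rows = []
    for protocol in protocols:
        per_seq: dict[int, list[float]] = {k: [] for k in protocol.topk}
        for chain in dataset:
            scores, truth = mask_region_predict(encoder, chain, protocol)
            for k in protocol.topk:
                per_seq[k].append(topk_accuracy(scores, truth, k))
        for k in protocol.topk:
            rows.append(
                {
                    "regions": "+".join(protocol.regions_to_mask),
                    "truncation": protocol.truncation_spec or "none",
                    "k": k,
                    "accuracy": float(np.mean(per_seq[k])),
                    "n_sequences": len(dataset),
                }
            )
    return pd.DataFrame(rows)


def default_protocols(
    regions: tuple[str, ...] = ("CDR3",),
    truncations: tuple[str | None, ...] = TRUNCATION_GRID,
) -> list[RestorationProtocol]:
    return [RestorationProtocol(regions, t) for t in truncations]


@dataclass(frozen=True)
class DistributionReport:
    family: str
    cdr3_length: int
    truth_freq: np.ndarray
    model_freq: np.ndarray | None
    divergence: float | None
    n_positions: int


def _freqs(residues: list[str]) -> np.ndarray:
    counts = np.zeros(len(CANONICAL_RESIDUES))
    index = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}
    for r in residues:
        counts[index[r]] += 1
    return counts / counts.sum()


def cdr3_distribution(
    chains: list[AnnotatedChain],
    encoder: Encoder | None = None,
    min_positions: int = 10,
) -> list[DistributionReport]:
    """Pooled CDR3 amino-acid frequencies per (family, CDR3 length) group.

    With an encoder, also pools the model's top-1 reconstructions of fully
    masked CDR3s and reports the Jensen-Shannon divergence to the truth.
    Groups with fewer than ``min_positions`` CDR3 positions are excluded.
    """
    groups: dict[tuple[str, int], list[AnnotatedChain]] = {}
    for c in chains:
        if c.regions is None:
            raise ValueError(f"chain {c.id!r} has no region annotation")
        a, b = c.regions["CDR3"]
        groups.setdefault((c.family or "unknown", b - a), []).append(c)
    reports = []
    protocol = RestorationProtocol(("CDR3",))
    for (family, length), members in sorted(groups.items()):
        n_positions = length * len(members)
        if n_positions < min_positions:
            logger.info("group (%s, %d) has %d CDR3 positions < %d; excluded", family, length, n_positions, min_positions)
            continue
        truth_res: list[str] = []
        model_res: list[str] = []
        for c in members:
            a, b = c.regions["CDR3"]
            truth_res.extend(c.sequence[a:b])
            if encoder is not None:
                scores, _ = mask_region_predict(encoder, c, protocol)
                model_res.extend(CANONICAL_RESIDUES[i] for i in scores.argmax(axis=-1))
        truth_freq = _freqs(truth_res)
        model_freq = _freqs(model_res) if encoder is not None else None
        div = js_divergence(truth_freq, model_freq) if model_freq is not None else None
        reports.append(DistributionReport(family, length, truth_freq, model_freq, div, n_positions))
    return reports


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence in nats: 0.5 KL(p||m) + 0.5 KL(q||m)."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries in a probability vector")
    if p.shape != q.shape:
        raise ValueError("p and q must share a support")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} does not sum to 1")
    return float(jensenshannon(p, q, base=np.e) ** 2)
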