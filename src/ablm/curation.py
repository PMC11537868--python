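"""Identity-based redundancy reduction and dataset splitting.

Two-stage curation: cluster at a high identity threshold, keep the longest
member of every multi-member cluster, then re-cluster the remaining
singletons at a lower threshold and keep the longest member of multi-member
clusters again.  Stage-2 singletons are discarded.

Identity metric: global alignment with unit match, zero mismatch and linear
gap penalty 1 (score units); identity = matched columns / alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from .abcore import AnnotatedChain

__all__ = [
    "SequenceCluster",
    "DatasetSplit",
    "pairwise_identity",
    "greedy_cluster",
    "curate",
    "split",
]


@dataclass(frozen=True)
class SequenceCluster:
    representative_id: str
    member_ids: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member of its own cluster")


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split parts are not pairwise disjoint")


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matched columns in the best global alignment of ``a``, ``b``."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    matches = counts.identities
    columns = aln.length
    return matches / columns


def _visit_order(seqs: Sequence[AnnotatedChain]) -> list[AnnotatedChain]:
    # decreasing length, ties lexicographic on sequence, then input order
    return [
        s
        for _, _, _, s in sorted(
            ((-len(s), s.sequence, i, s) for i, s in enumerate(seqs)),
            key=lambda t: t[:3],
        )
    ]


def greedy_cluster(
    seqs: Sequence[AnnotatedChain], threshold: float
) -> list[SequenceCluster]:
    """Deterministic single-pass greedy clustering by identity to representatives.

    Sequences are visited in order of decreasing length (ties broken
    lexicographically, then by input order); each joins the first existing
    cluster whose representative it matches at >= threshold, else founds a
    new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    reps: list[AnnotatedChain] = []
    members: list[list[str]] = []
    for s in _visit_order(seqs):
        for ci, rep in enumerate(reps):
            if pairwise_identity(s.sequence, rep.sequence) >= threshold:
                members[ci].append(s.id)
                break
        else:
            reps.append(s)
            members.append([s.id])
    return [
        SequenceCluster(rep.id, tuple(mem), threshold)
        for rep, mem in zip(reps, members)
    ]


def _longest_member(cluster: SequenceCluster, by_id: dict[str, AnnotatedChain]) -> AnnotatedChain:
    # longest sequence wins; ties broken lexicographically then by id for determinism
    return min(
        (by_id[m] for m in cluster.member_ids),
        key=lambda c: (-len(c.sequence), c.sequence, c.id),
    )


def curate(
    seqs: Sequence[AnnotatedChain],
    t1: float = 0.80,
    t2: float = 0.50,
    *,
    return_clusters: bool = False,
):
    """Two-stage redundancy reduction; returns kept representative chains.

    With ``return_clusters=True`` also returns ``(stage, cluster)`` pairs for
    reporting.
    """
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("duplicate sequence ids in input")
    stage1 = greedy_cluster(seqs, t1)
    kept: list[AnnotatedChain] = []
    singles: list[AnnotatedChain] = []
    for cl in stage1:
        if len(cl.member_ids) > 1:
            kept.append(_longest_member(cl, by_id))
        else:
            singles.append(by_id[cl.member_ids[0]])
    stage2 = greedy_cluster(singles, t2)
    for cl in stage2:
        if len(cl.member_ids) > 1:
            kept.append(_longest_member(cl, by_id))
    if return_clusters:
        tagged = [(1, cl) for cl in stage1] + [(2, cl) for cl in stage2]
        return kept, tagged
    return kept


def split(
    ids: Sequence[str],
    fractions: tuple[float, float, float],
    seed: int,
) -> DatasetSplit:
    """Random train/val/test partition; sizes differ from exact fractions by <1."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    # largest-remainder allocation
    exact = [f * len(ids) for f in fractions]
    sizes = [int(np.floor(x)) for x in exact]
    remainder = len(ids) - sum(sizes)
    by_frac = sorted(range(3), key=lambda i: exact[i] - sizes[i], reverse=True)
    for i in by_frac[:remainder]:
        sizes[i] += 1
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(
        tuple(shuffled[:a]), tuple(shuffled[a:b]), tuple(shuffled[b:]), seed
    )
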