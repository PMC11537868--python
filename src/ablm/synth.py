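"""Synthetic antibody-grammar generator.

Emits desk-scale corpora with the structural properties the real data has:
near-constant framework regions per family (low per-position entropy),
CDR1/2 drawn from small per-family motif sets (intermediate entropy), and a
highly variable CDR3 with family-determined first/last anchor residues and
family-biased interior composition (highest entropy).  Families stand in
for germline V genes.

Two planted, recoverable rules drive the downstream heads:

* pairing — a heavy family maps to one compatible light family, and both
  partners carry the same key residue at a fixed FR3 position;
* binding — label 1 iff a length-3 motif sits at a fixed CDR3 offset,
  flipped with a small label-noise rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .abcore import (
    CANONICAL_RESIDUES,
    AnnotatedChain,
    RegionAnnotation,
)
from .heads import BindingExample, PairingExample

__all__ = [
    "GrammarConfig",
    "Grammar",
    "PlantedPairingRule",
    "PlantedBindingRule",
    "build_grammar",
    "sample_heavy",
    "sample_light",
    "sample_corpus",
    "sample_paired_dataset",
    "sample_binding_dataset",
]

_AA = np.array(list(CANONICAL_RESIDUES))


@dataclass(frozen=True)
class GrammarConfig:
    n_families: int = 7
    n_light_families: int = 4
    fr_lengths: tuple[int, int, int, int] = (25, 17, 38, 11)
    light_fr_lengths: tuple[int, int, int, int] = (23, 15, 32, 10)
    cdr12_length: int = 8
    light_cdr12_length: int = 6
    n_cdr_motifs: int = 4
    fr_substitution_rate: float = 0.02
    cdr3_len_range: tuple[int, int] = (8, 20)  # inclusive
    light_cdr3_length: int = 9
    cdr3_bias_weight: float = 0.35  # probability mass on the family-preferred residue
    cdr3_markov_weight: float = 0.0  # P(next = family successor of prev); rest from the bias law
    key_fr3_offset: int = 10  # key-residue position within FR3 (pairing rule)
    binding_motif_offset: int = 3
    binding_motif_length: int = 3
    binding_cdr3_length: int = 10
    binding_label_noise: float = 0.05
    shared_fr4: bool = True  # FR4 is J-segment-derived: conserved across families
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_light_families < 1:
            raise ValueError("family counts must be >= 1")
        if any(n <= 0 for n in self.fr_lengths + self.light_fr_lengths):
            raise ValueError("all region lengths must be positive")
        lo, hi = self.cdr3_len_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid cdr3_len_range")
        if self.binding_motif_offset + self.binding_motif_length >= self.binding_cdr3_length:
            raise ValueError("binding motif must fit inside the CDR3 interior")

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dataclass_fields__.items()
            for v in [getattr(self, k)]
        }


@dataclass(frozen=True)
class PlantedPairingRule:
    compatible_light: dict[int, int]  # heavy family -> light family
    key_residue: dict[int, str]  # heavy family -> FR3 key residue
    heavy_key_pos: int  # residue coordinate within FR3
    light_key_pos: int


@dataclass(frozen=True)
class PlantedBindingRule:
    motif: str
    offset: int
    label_noise: float

    def matches(self, cdr3: str) -> bool:
        return cdr3[self.offset : self.offset + len(self.motif)] == self.motif


@dataclass
class FamilyTemplates:
    frs: tuple[str, str, str, str]
    cdr_motifs: dict[str, tuple[str, ...]]  # "CDR1"/"CDR2" -> motif set
    cdr3_anchor: tuple[str, str]
    cdr3_bias: np.ndarray  # 20-simplex over interior residues
    cdr3_successor: np.ndarray  # family permutation: preferred successor of each residue


@dataclass
class Grammar:
    cfg: GrammarConfig
    heavy: list[FamilyTemplates]
    light: list[FamilyTemplates]
    pairing_rule: PlantedPairingRule
    binding_rule: PlantedBindingRule


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA[rng.integers(len(_AA), size=n)])


def _family(rng: np.random.Generator, cfg: GrammarConfig, fr_lengths, cdr12_len, fam: int) -> FamilyTemplates:
    frs = tuple(_random_seq(rng, n) for n in fr_lengths)
    motifs = {
        cdr: tuple(_random_seq(rng, cdr12_len) for _ in range(cfg.n_cdr_motifs))
        for cdr in ("CDR1", "CDR2")
    }
    anchor = (str(_AA[rng.integers(len(_AA))]), str(_AA[rng.integers(len(_AA))]))
    bias = np.full(len(_AA), (1.0 - cfg.cdr3_bias_weight) / (len(_AA) - 1))
    bias[fam % len(_AA)] = cfg.cdr3_bias_weight
    successor = rng.permutation(len(_AA))
    return FamilyTemplates(frs, motifs, anchor, bias, successor)


def build_grammar(cfg: GrammarConfig) -> Grammar:
    """Deterministic grammar construction from ``cfg.seed``."""
    rng = np.random.default_rng([cfg.seed, 0xAB])
    heavy = [
        _family(rng, cfg, cfg.fr_lengths, cfg.cdr12_length, f)
        for f in range(cfg.n_families)
    ]
    light = [
        _family(rng, cfg, cfg.light_fr_lengths, cfg.light_cdr12_length, f)
        for f in range(cfg.n_light_families)
    ]
    if cfg.shared_fr4:
        for group in (heavy, light):
            fr4 = group[0].frs[3]
            for fam in group:
                fam.frs = fam.frs[:3] + (fr4,)
    key_residues = {f: str(_AA[rng.integers(len(_AA))]) for f in range(cfg.n_families)}
    rule = PlantedPairingRule(
        compatible_light={f: f % cfg.n_light_families for f in range(cfg.n_families)},
        key_residue=key_residues,
        heavy_key_pos=cfg.key_fr3_offset,
        light_key_pos=cfg.key_fr3_offset,
    )
    motif = _random_seq(rng, cfg.binding_motif_length)
    binding = PlantedBindingRule(motif, cfg.binding_motif_offset, cfg.binding_label_noise)
    return Grammar(cfg, heavy, light, rule, binding)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        chars[i] = str(_AA[rng.integers(len(_AA))])
    return "".join(chars)


def _sample_cdr3(
    tmpl: FamilyTemplates, length: int, rng: np.random.Generator, markov_weight: float
) -> str:
    """Anchored CDR3 with first-order interior dependencies.

    Each interior residue follows the family's preferred successor of the
    previous residue with probability ``markov_weight``, else the family
    bias law — local structure that full-context models can exploit but
    that vanishes when the whole loop is masked.
    """
    aa_index = {a: i for i, a in enumerate(_AA)}
    prev = tmpl.cdr3_anchor[0]
    chars = [prev]
    for _ in range(length - 2):
        if rng.random() < markov_weight:
            nxt = str(_AA[tmpl.cdr3_successor[aa_index[prev]]])
        else:
            nxt = str(_AA[rng.choice(len(_AA), p=tmpl.cdr3_bias)])
        chars.append(nxt)
        prev = nxt
    chars.append(tmpl.cdr3_anchor[1])
    return "".join(chars)


def _assemble(tmpl, cdr1, cdr2, cdr3, rate, rng) -> tuple[str, RegionAnnotation]:
    fr = [_mutate(f, rate, rng) for f in tmpl.frs]
    parts = [fr[0], cdr1, fr[1], cdr2, fr[2], cdr3, fr[3]]
    lengths = [len(p) for p in parts]
    return "".join(parts), RegionAnnotation.from_lengths(lengths)


def sample_heavy(
    grammar: Grammar, rng: np.random.Generator, uid: str | None = None, family: int | None = None
) -> AnnotatedChain:
    cfg = grammar.cfg
    fam = int(rng.integers(cfg.n_families)) if family is None else family
    tmpl = grammar.heavy[fam]
    cdr1 = tmpl.cdr_motifs["CDR1"][rng.integers(cfg.n_cdr_motifs)]
    cdr2 = tmpl.cdr_motifs["CDR2"][rng.integers(cfg.n_cdr_motifs)]
    lo, hi = cfg.cdr3_len_range
    cdr3 = _sample_cdr3(tmpl, int(rng.integers(lo, hi + 1)), rng, cfg.cdr3_markov_weight)
    seq, regions = _assemble(tmpl, cdr1, cdr2, cdr3, cfg.fr_substitution_rate, rng)
    # plant the pairing key residue at the fixed FR3 offset
    fr3_start = regions["FR3"][0]
    pos = fr3_start + grammar.pairing_rule.heavy_key_pos
    seq = seq[:pos] + grammar.pairing_rule.key_residue[fam] + seq[pos + 1 :]
    cid = uid if uid is not None else f"H{rng.integers(10**9):09d}"
    return AnnotatedChain(cid, "heavy", seq, regions, family=f"F{fam}")


def sample_light(
    grammar: Grammar,
    rng: np.random.Generator,
    uid: str | None = None,
    family: int | None = None,
    key_residue: str | None = None,
) -> AnnotatedChain:
    cfg = grammar.cfg
    fam = int(rng.integers(cfg.n_light_families)) if family is None else family
    tmpl = grammar.light[fam]
    cdr1 = tmpl.cdr_motifs["CDR1"][rng.integers(cfg.n_cdr_motifs)]
    cdr2 = tmpl.cdr_motifs["CDR2"][rng.integers(cfg.n_cdr_motifs)]
    cdr3 = _sample_cdr3(tmpl, cfg.light_cdr3_length, rng, cfg.cdr3_markov_weight)
    seq, regions = _assemble(tmpl, cdr1, cdr2, cdr3, cfg.fr_substitution_rate, rng)
    if key_residue is not None:
        pos = regions["FR3"][0] + grammar.pairing_rule.light_key_pos
        seq = seq[:pos] + key_residue + seq[pos + 1 :]
    cid = uid if uid is not None else f"L{rng.integers(10**9):09d}"
    return AnnotatedChain(cid, "light", seq, regions, family=f"F{fam}")


def sample_corpus(
    grammar: Grammar, n_heavy: int, n_light: int, rng: np.random.Generator
) -> list[AnnotatedChain]:
    chains = [sample_heavy(grammar, rng, uid=f"H{i:06d}") for i in range(n_heavy)]
    chains += [sample_light(grammar, rng, uid=f"L{i:06d}") for i in range(n_light)]
    return chains


def sample_paired_dataset(
    grammar: Grammar, n: int, rng: np.random.Generator, n_neg: int = 15
) -> list[PairingExample]:
    """True pairs satisfy the planted rule; negatives violate its family map."""
    cfg = grammar.cfg
    rule = grammar.pairing_rule
    out = []
    for i in range(n):
        fam = int(rng.integers(cfg.n_families))
        heavy = sample_heavy(grammar, rng, uid=f"PH{i:06d}", family=fam)
        light = sample_light(
            grammar,
            rng,
            uid=f"PL{i:06d}",
            family=rule.compatible_light[fam],
            key_residue=rule.key_residue[fam],
        )
        negatives = []
        while len(negatives) < n_neg:
            neg_fam = int(rng.integers(cfg.n_light_families))
            if neg_fam == rule.compatible_light[fam]:
                continue
            negatives.append(sample_light(grammar, rng, uid=f"PN{i:06d}_{len(negatives)}", family=neg_fam))
        out.append(PairingExample(heavy, light, tuple(negatives)))
    return out


def sample_binding_dataset(
    grammar: Grammar, n: int, rng: np.random.Generator
) -> list[BindingExample]:
    """Fixed-length CDR3 variants; label 1 iff the motif sits at its offset,
    then flipped with the label-noise rate.  Class balance ~1:1."""
    cfg = grammar.cfg
    rule = grammar.binding_rule
    out = []
    for i in range(n):
        fam = int(rng.integers(cfg.n_families))
        tmpl = grammar.heavy[fam]
        bind = bool(rng.random() < 0.5)
        cdr3 = _sample_cdr3(tmpl, cfg.binding_cdr3_length, rng, cfg.cdr3_markov_weight)
        if bind:
            a = rule.offset
            cdr3 = cdr3[:a] + rule.motif + cdr3[a + len(rule.motif) :]
        else:
            while rule.matches(cdr3):
                cdr3 = _sample_cdr3(tmpl, cfg.binding_cdr3_length, rng, cfg.cdr3_markov_weight)
        cdr1 = tmpl.cdr_motifs["CDR1"][rng.integers(cfg.n_cdr_motifs)]
        cdr2 = tmpl.cdr_motifs["CDR2"][rng.integers(cfg.n_cdr_motifs)]
        seq, regions = _assemble(tmpl, cdr1, cdr2, cdr3, cfg.fr_substitution_rate, rng)
        label = int(bind)
        if rng.random() < rule.label_noise:
            label = 1 - label
        out.append(BindingExample(f"B{i:06d}", seq, regions["CDR3"], label))
    return out


def write_manifest(path, cfg: GrammarConfig, extra: dict | None = None) -> None:
    rec = {"grammar": cfg.to_dict()}
    if extra:
        rec.update(extra)
    Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True))
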