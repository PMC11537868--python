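"""Alphabet, tokenizer, and region model shared by all other modules.

Coordinates are 0-based half-open everywhere in residue space.  The +1
offset introduced by the leading [CLS] token is applied in exactly one
place, :func:`region_token_indices`, so that off-by-one conversions cannot
accumulate elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CANONICAL_RESIDUES",
    "SPECIAL_TOKENS",
    "REGION_NAMES",
    "ResidueAlphabet",
    "RegionAnnotation",
    "AnnotatedChain",
    "TokenizedSequence",
    "tokenize",
    "detokenize",
    "region_token_indices",
    "validate_annotation",
    "read_fasta",
    "write_fasta",
    "read_regions_tsv",
    "write_regions_tsv",
]

# Standard 20 amino acids in alphabetical one-letter order.
CANONICAL_RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS: tuple[str, ...] = (PAD, UNK, CLS, SEP, MASK)

REGION_NAMES: tuple[str, ...] = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


@dataclass(frozen=True)
class ResidueAlphabet:
    """Token vocabulary: 5 special tokens followed by the 20 canonical residues.

    [PAD] always has id 0; ids are contiguous.
    """

    special_tokens: tuple[str, ...] = SPECIAL_TOKENS
    canonical_residues: tuple[str, ...] = CANONICAL_RESIDUES

    def __post_init__(self) -> None:
        if len(self.tokens) != len(set(self.tokens)):
            raise ValueError("alphabet tokens must be unique")
        if self.special_tokens[0] != PAD:
            raise ValueError("[PAD] must be the first token (id 0)")

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.special_tokens + self.canonical_residues

    @property
    def size(self) -> int:
        return len(self.tokens)

    def id_of(self, token: str) -> int:
        try:
            return self._index()[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in alphabet") from None

    def token_of(self, token_id: int) -> str:
        if not 0 <= token_id < self.size:
            raise KeyError(f"token id {token_id} out of range [0, {self.size})")
        return self.tokens[token_id]

    def _index(self) -> dict[str, int]:
        # built lazily; frozen dataclass so stash on the object dict
        idx = self.__dict__.get("_idx")
        if idx is None:
            idx = {t: i for i, t in enumerate(self.tokens)}
            self.__dict__["_idx"] = idx
        return idx

    @property
    def pad_id(self) -> int:
        return self.id_of(PAD)

    @property
    def unk_id(self) -> int:
        return self.id_of(UNK)

    @property
    def cls_id(self) -> int:
        return self.id_of(CLS)

    @property
    def sep_id(self) -> int:
        return self.id_of(SEP)

    @property
    def mask_id(self) -> int:
        return self.id_of(MASK)

    @property
    def residue_ids(self) -> tuple[int, ...]:
        return tuple(self.id_of(r) for r in self.canonical_residues)

    def to_dict(self) -> dict:
        return {
            "special_tokens": list(self.special_tokens),
            "canonical_residues": list(self.canonical_residues),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResidueAlphabet":
        return cls(tuple(d["special_tokens"]), tuple(d["canonical_residues"]))


#: Module-level default used throughout unless a caller supplies its own.
DEFAULT_ALPHABET = ResidueAlphabet()


@dataclass(frozen=True)
class RegionAnnotation:
    """Seven half-open residue intervals FR1,CDR1,FR2,CDR2,FR3,CDR3,FR4."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(REGION_NAMES):
            raise ValueError(f"expected {len(REGION_NAMES)} intervals, got {len(self.intervals)}")

    def __getitem__(self, region: str) -> tuple[int, int]:
        try:
            i = REGION_NAMES.index(region)
        except ValueError:
            raise KeyError(f"unknown region name {region!r}") from None
        return self.intervals[i]

    @property
    def length(self) -> int:
        return self.intervals[-1][1]

    def items(self) -> Iterator[tuple[str, tuple[int, int]]]:
        return iter(zip(REGION_NAMES, self.intervals))

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "RegionAnnotation":
        bounds, pos = [], 0
        for n in lengths:
            bounds.append((pos, pos + n))
            pos += n
        return cls(tuple(bounds))

    def region_of(self, residue_pos: int) -> str:
        for name, (a, b) in self.items():
            if a <= residue_pos < b:
                return name
        raise IndexError(f"residue position {residue_pos} outside [0, {self.length})")


@dataclass(frozen=True)
class AnnotatedChain:
    id: str
    chain_type: str  # "heavy" | "light"
    sequence: str
    regions: RegionAnnotation | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.chain_type not in ("heavy", "light"):
            raise ValueError(f"chain_type must be 'heavy' or 'light', got {self.chain_type!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TokenizedSequence:
    """[CLS] + residues + [SEP]; region label per token ('special' at ends)."""

    token_ids: tuple[int, ...]
    region_labels: tuple[str, ...]
    residue_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.token_ids) != len(self.region_labels):
            raise ValueError("token_ids and region_labels length mismatch")

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def n_residues(self) -> int:
        return len(self.token_ids) - 2

    @property
    def residue_indices(self) -> range:
        return range(self.residue_offset, self.residue_offset + self.n_residues)


def tokenize(
    chain: AnnotatedChain,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
    *,
    allow_unknown: bool = False,
) -> TokenizedSequence:
    """Frame ``chain.sequence`` as [CLS] residues [SEP].

    Non-canonical characters are rejected with the offending 0-based residue
    position; ``allow_unknown=True`` substitutes [UNK] instead (intended for
    inference-time inputs only, never training data).
    """
    seq = chain.sequence
    if not seq:
        raise ValueError(f"chain {chain.id!r}: empty sequence")
    canonical = set(alphabet.canonical_residues)
    ids = [alphabet.cls_id]
    for pos, ch in enumerate(seq):
        if ch in canonical:
            ids.append(alphabet.id_of(ch))
        elif allow_unknown:
            ids.append(alphabet.unk_id)
        else:
            raise ValueError(
                f"chain {chain.id!r}: non-canonical residue {ch!r} at position {pos}"
            )
    ids.append(alphabet.sep_id)

    if chain.regions is not None:
        if chain.regions.length != len(seq):
            raise ValueError(
                f"chain {chain.id!r}: annotation covers [0, {chain.regions.length}) "
                f"but sequence has length {len(seq)}"
            )
        labels = ["special"] + [chain.regions.region_of(p) for p in range(len(seq))] + ["special"]
    else:
        labels = ["special"] + ["unannotated"] * len(seq) + ["special"]
    return TokenizedSequence(tuple(ids), tuple(labels))


def detokenize(tok: TokenizedSequence, alphabet: ResidueAlphabet = DEFAULT_ALPHABET) -> str:
    """Recover the residue string (inverse of :func:`tokenize`)."""
    if tok.token_ids[0] != alphabet.cls_id or tok.token_ids[-1] != alphabet.sep_id:
        raise ValueError("token sequence is not framed by [CLS]...[SEP]")
    return "".join(alphabet.token_of(i) for i in tok.token_ids[1:-1])


def region_token_indices(tok: TokenizedSequence, region: str) -> tuple[int, ...]:
    """Token-coordinate indices (residue coordinate + 1) of ``region``.

    Never includes special tokens.
    """
    if region not in REGION_NAMES:
        raise KeyError(f"unknown region name {region!r}")
    return tuple(i for i, lab in enumerate(tok.region_labels) if lab == region)


def validate_annotation(chain: AnnotatedChain) -> list[str]:
    """Report violations of the region-annotation invariants (never raises)."""
    violations: list[str] = []
    seq = chain.sequence
    non_canonical = [
        (i, c) for i, c in enumerate(seq) if c not in CANONICAL_RESIDUES
    ]
    for i, c in non_canonical[:5]:
        violations.append(f"non-canonical residue {c!r} at position {i}")
    reg = chain.regions
    if reg is None:
        return violations
    pos = 0
    for name, (a, b) in reg.items():
        if a != pos:
            kind = "gap" if a > pos else "overlap"
            violations.append(f"{kind} before {name}: expected start {pos}, got {a}")
        if b < a:
            violations.append(f"{name} has negative length [{a}, {b})")
        pos = max(b, a)
        if chain.chain_type == "heavy" and name.startswith("CDR") and b <= a:
            violations.append(f"{name} is empty on a heavy chain")
    if pos != len(seq):
        violations.append(f"annotation covers [0, {pos}) but sequence length is {len(seq)}")
    return violations


# ---------------------------------------------------------------------------
# I/O: FASTA with "chain=H|L" / "family=<id>" key=value tags, regions TSV
# ---------------------------------------------------------------------------

_CHAIN_TAG = {"H": "heavy", "L": "light"}
_TAG_CHAIN = {v: k for k, v in _CHAIN_TAG.items()}


def read_fasta(path, default_chain_type: str = "heavy") -> list[AnnotatedChain]:
    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chain_type = default_chain_type
        family = None
        for tag in rec.description.split()[1:]:
            if tag.startswith("chain="):
                chain_type = _CHAIN_TAG[tag.split("=", 1)[1]]
            elif tag.startswith("family="):
                family = tag.split("=", 1)[1]
        chains.append(AnnotatedChain(rec.id, chain_type, str(rec.seq).upper(), family=family))
    return chains


def write_fasta(path, chains: Sequence[AnnotatedChain]) -> None:
    records = []
    for c in chains:
        desc = f"chain={_TAG_CHAIN[c.chain_type]}"
        if c.family is not None:
            desc += f" family={c.family}"
        records.append(SeqRecord(Seq(c.sequence), id=c.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


_TSV_COLUMNS = [f"{r.lower()}_{end}" for r in REGION_NAMES for end in ("start", "end")]


def read_regions_tsv(path) -> dict[str, RegionAnnotation]:
    import csv

    out: dict[str, RegionAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {"id", *_TSV_COLUMNS} - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"regions TSV missing columns: {sorted(missing)}")
        for row in reader:
            intervals = tuple(
                (int(row[f"{r.lower()}_start"]), int(row[f"{r.lower()}_end"]))
                for r in REGION_NAMES
            )
            out[row["id"]] = RegionAnnotation(intervals)
    return out


def write_regions_tsv(path, annotations: dict[str, RegionAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["id"] + _TSV_COLUMNS) + "\n")
        for cid, reg in annotations.items():
            cells = [cid] + [str(x) for a_b in reg.intervals for x in a_b]
            fh.write("\t".join(cells) + "\n")


def attach_regions(
    chains: Sequence[AnnotatedChain], annotations: dict[str, RegionAnnotation]
) -> list[AnnotatedChain]:
    """Return chains with their annotation attached where one exists."""
    return [
        replace(c, regions=annotations[c.id]) if c.id in annotations else c
        for c in chains
    ]
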