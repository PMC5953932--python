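"""Reading, validating and simulating DNA sequences, and the per-base position partition.

The whole method starts from the observation that a DNA sequence can be split
into four subsequences — the positions occupied by A, C, G and T respectively.
Everything downstream (spiral embedding, masses, moments) operates on these
four position sets, so this module is the single entry point for sequence data:
FASTA parsing with explicit ambiguity policies, the base partition, and a
seeded substitution-model generator for test sets with controlled divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_ALPHABET_SET = frozenset(ALPHABET)

#: FASTA validation policies.
POLICIES = ("strict", "skip-ambiguous", "uppercase-coerce")


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence over the {A, C, G, T} alphabet.

    Parameters
    ----------
    id : str
        Free-text label; labels key distance matrices downstream, so they must
        be unique within a set.
    residues : str
        The ordered residue string, uppercase A/C/G/T only.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = next(
            ((i, c) for i, c in enumerate(self.residues, 1) if c not in _ALPHABET_SET),
            None,
        )
        if bad is not None:
            raise ValueError(
                f"sequence {self.id!r}: invalid residue {bad[1]!r} at position {bad[0]}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class BasePartition:
    """1-based positions of each base in the parent sequence.

    The four lists are disjoint, strictly increasing, and their union is
    {1, ..., N} where N is the parent length — the per-base subsequence
    lengths always sum to the sequence length.
    """

    positions_A: tuple[int, ...]
    positions_C: tuple[int, ...]
    positions_G: tuple[int, ...]
    positions_T: tuple[int, ...]

    def by_base(self) -> dict[str, tuple[int, ...]]:
        return {
            "A": self.positions_A,
            "C": self.positions_C,
            "G": self.positions_G,
            "T": self.positions_T,
        }

    @property
    def total(self) -> int:
        return sum(len(p) for p in self.by_base().values())


def partition_by_base(seq: NucleotideSequence) -> BasePartition:
    """Split a sequence into the four per-base position sets.

    Positions are 1-based indices into the original sequence, so the global
    ordering information survives the split.
    """
    pos: dict[str, list[int]] = {b: [] for b in ALPHABET}
    for i, residue in enumerate(seq.residues, 1):
        pos[residue].append(i)
    return BasePartition(*(tuple(pos[b]) for b in ALPHABET))


def _clean_record(record: SeqRecord, policy: str) -> str:
    raw = str(record.seq)
    if policy in ("uppercase-coerce", "skip-ambiguous"):
        raw = raw.upper()
    if policy == "skip-ambiguous":
        kept = [c for c in raw if c in _ALPHABET_SET]
        n_removed = len(raw) - len(kept)
        if n_removed:
            logger.warning(
                "record %r: removed %d ambiguous residue(s); positions renumbered",
                record.id,
                n_removed,
            )
        return "".join(kept)
    return raw


def read_fasta(path: str | Path, policy: str = "strict") -> list[NucleotideSequence]:
    """Read a (multi-record) FASTA file into validated sequences.

    Parameters
    ----------
    path : path-like
        FASTA file, wrapped or unwrapped lines.
    policy : {"strict", "skip-ambiguous", "uppercase-coerce"}
        ``strict`` rejects any residue outside A/C/G/T; ``uppercase-coerce``
        case-folds first, then applies strict validation; ``skip-ambiguous``
        case-folds and silently drops non-ACGT residues with a logged count.
        Dropping residues renumbers positions, which changes the embedding —
        hence strict is the default.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing/empty file, invalid residues under strict policies, a record
        left with zero valid residues, or duplicate record ids.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[NucleotideSequence] = []
    seen: set[str] = set()
    for record in records:
        if record.id in seen:
            raise ValueError(f"{path}: duplicate record id {record.id!r}")
        seen.add(record.id)
        residues = _clean_record(record, policy)
        if not residues:
            raise ValueError(f"{path}: record {record.id!r} has no valid residues")
        out.append(NucleotideSequence(id=record.id, residues=residues))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences to FASTA (one unwrapped line per record)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(Path(path)), "fasta-2line")


def _mutate(residues: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution: each site mutates with probability `rate` to one
    of the three other bases, chosen uniformly."""
    out = residues.copy()
    hit = rng.random(out.size) < rate
    # offset 1..3 from the current base, mod 4: uniform over the other three
    offsets = rng.integers(1, 4, size=out.size)
    out[hit] = (out[hit] + offsets[hit]) % 4
    return out


def generate_synthetic_set(
    n_clades: int,
    per_clade: int,
    length: int,
    divergence_within: float,
    divergence_between: float,
    seed: int,
) -> list[NucleotideSequence]:
    """Simulate a clade-structured sequence set under a uniform substitution model.

    One uniform-random ancestor is drawn; each clade ancestor is derived from
    it by per-site substitution at rate ``divergence_between``, and each leaf
    from its clade ancestor at rate ``divergence_within``. No indels, so
    lengths are exactly ``length``. Labels encode clade membership as
    ``clade{c}_seq{k}``. Output is bitwise reproducible for a fixed seed.
    """
    if not (0 <= divergence_within < divergence_between <= 1):
        raise ValueError(
            "require 0 <= divergence_within < divergence_between <= 1, got "
            f"{divergence_within}/{divergence_between}"
        )
    if length < 4:
        raise ValueError("length must be >= 4")
    if n_clades < 1 or per_clade < 1:
        raise ValueError("n_clades and per_clade must be >= 1")
    rng = np.random.default_rng(seed)
    base_codes = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    ancestor = rng.integers(0, 4, size=length)
    seqs: list[NucleotideSequence] = []
    for c in range(n_clades):
        clade_anc = _mutate(ancestor, divergence_between, rng)
        for k in range(per_clade):
            leaf = _mutate(clade_anc, divergence_within, rng)
            residues = base_codes[leaf].tobytes().decode()
            seqs.append(NucleotideSequence(id=f"clade{c}_seq{k}", residues=residues))
    return seqs


def hamming_distance(a: NucleotideSequence, b: NucleotideSequence) -> int:
    """Number of mismatching sites between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a.residues, b.residues))


def as_sequences(X: Sequence) -> list[NucleotideSequence]:
    """Coerce an iterable of strings / NucleotideSequence into validated sequences.

    Bare strings get positional ids ``seq0, seq1, ...``.
    """
    out = []
    for i, item in enumerate(X):
        if isinstance(item, NucleotideSequence):
            out.append(item)
        else:
            out.append(NucleotideSequence(id=f"seq{i}", residues=str(item).upper()))
    return out
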