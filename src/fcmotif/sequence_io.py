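"""FASTA input, sequence containers and k-mer iteration.

Test and control inputs are ordinary multi-FASTA files of extracted peak
(resp. flanking-background) segments.  Sequences are held uppercase over the
four-letter DNA alphabet; IUPAC ambiguity codes are resolved at load time by
a seeded uniform draw over the letters they denote, so that downstream word
counting can assume {A,C,G,T}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("fcmotif")

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Ambiguity code -> concrete letters it may stand for.
IUPAC_AMBIGUITY = {
    "N": "ACGT", "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "U": "T",
}


class Role(str, Enum):
    TEST = "test"
    CONTROL = "control"


@dataclass
class SequenceSet:
    """An ordered collection of uppercase DNA sequences with a role tag."""

    sequences: list[str]
    role: Role
    name: str = ""
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"SequenceSet {self.name!r} is empty")
        for i, s in enumerate(self.sequences):
            if not s:
                raise ValueError(f"sequence {i} in {self.name!r} is empty")
            if set(s) - set(ALPHABET):
                bad = sorted(set(s) - set(ALPHABET))
                raise ValueError(
                    f"sequence {i} in {self.name!r} contains non-ACGT letters {bad}"
                )
        if self.ids is not None and len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def n_windows(self, l: int, both_strands: bool = False) -> int:
        """Total number of length-l windows scanned over the set."""
        n = sum(max(0, len(s) - l + 1) for s in self.sequences)
        return 2 * n if both_strands else n

    def seq_id(self, i: int) -> str:
        if self.ids is not None:
            return self.ids[i]
        return f"seq_{i}"


def revcomp(s: str) -> str:
    """Reverse complement of a DNA word."""
    return s.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(s: str, rng: np.random.Generator) -> str:
    """Uppercase a raw record and resolve IUPAC ambiguity codes.

    Each ambiguity letter is replaced by a letter drawn uniformly from the
    set it denotes, using the supplied generator.  Letters outside the IUPAC
    nucleotide alphabet raise ValueError.
    """
    s = s.upper()
    if not set(s) - set(ALPHABET):
        return s
    out = []
    for ch in s:
        if ch in BASE_INDEX:
            out.append(ch)
        elif ch in IUPAC_AMBIGUITY:
            choices = IUPAC_AMBIGUITY[ch]
            out.append(choices[int(rng.integers(len(choices)))])
        else:
            raise ValueError(f"non-nucleotide letter {ch!r}")
    return "".join(out)


def read_fasta(path, role: Role, *, sanitize_seed: int = 0) -> SequenceSet:
    """Read a multi-FASTA file into a :class:`SequenceSet`.

    Records are uppercased and ambiguity codes resolved by a seeded uniform
    draw (``sanitize_seed``); record order is preserved.  An empty file or a
    record with letters outside the IUPAC nucleotide codes is an error.
    """
    rng = np.random.default_rng(sanitize_seed)
    sequences: list[str] = []
    ids: list[str] = []
    n_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        try:
            clean = sanitize_sequence(raw, rng)
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r} in {path}: {exc}") from exc
        n_ambiguous += sum(1 for a, b in zip(raw.upper(), clean) if a != b)
        sequences.append(clean)
        ids.append(rec.id)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    if n_ambiguous:
        logger.info(
            "replaced %d ambiguity letters in %s with seeded uniform draws",
            n_ambiguous, path,
        )
    return SequenceSet(sequences=sequences, role=role, name=str(path), ids=ids)


def iter_kmers(
    s: str, l: int, both_strands: bool = False
) -> Iterator[tuple[int, str, str]]:
    """Yield ``(offset, word, strand)`` for every length-l window of ``s``.

    Coordinates are 0-based half-open on the forward strand.  With
    ``both_strands`` each window additionally yields its reverse complement
    with strand '-'; the offset still refers to the forward-strand window.
    ``l > len(s)`` yields nothing.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    for i in range(len(s) - l + 1):
        w = s[i : i + l]
        yield i, w, "+"
        if both_strands:
            yield i, revcomp(w), "-"


_ENC = np.full(128, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENC[ord(_b)] = _i


def encode(s: str) -> np.ndarray:
    """Encode a DNA string as an int8 array with A,C,G,T -> 0..3."""
    a = _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (a < 0).any():
        raise ValueError("non-ACGT letter in sequence")
    return a
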