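"""Seeded synthetic sequence sets with planted (l,d) motifs.

The generator emulates the discovery setting: a test set of short
peak-centered segments carrying mutated instances of a planted consensus
under an OOPS / ZOOPS / TCM occupancy model, and a control set of plain
background segments.  Each planted instance mutates at exactly i positions
with binomial probability C(d,i)·p_con^i·(1−p_con)^(d−i), at uniformly
chosen positions and uniformly chosen alternative letters — the same
mutation process the mining thresholds assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emerging import OccupancyModel, p_mutation
from .output import PredictedSite
from .sequence_io import ALPHABET, Role, SequenceSet


def make_background(
    n_seqs: int,
    seq_len: int,
    *,
    markov_order: int = 0,
    seed: int = 0,
    probs: np.ndarray | None = None,
    transition: np.ndarray | None = None,
    role: Role = Role.CONTROL,
    name: str = "synthetic-background",
) -> SequenceSet:
    """Generate background sequences, i.i.d. or from a Markov chain.

    Order 0 draws letters i.i.d. from ``probs`` (uniform by default).  For
    order k >= 1 supply ``transition`` of shape (4,)*k + (4,); the first k
    letters are drawn from ``probs``.
    """
    if n_seqs <= 0 or seq_len <= 0:
        raise ValueError("n_seqs and seq_len must be positive")
    rng = np.random.default_rng(seed)
    if probs is None:
        probs = np.full(4, 0.25)
    probs = np.asarray(probs, dtype=float)
    seqs: list[str] = []
    if markov_order == 0 or transition is None:
        if markov_order > 0:
            raise ValueError("markov_order >= 1 requires a transition table")
        draws = rng.choice(4, size=(n_seqs, seq_len), p=probs)
        for row in draws:
            seqs.append("".join(ALPHABET[k] for k in row))
    else:
        k = markov_order
        if transition.shape != (4,) * (k + 1):
            raise ValueError("transition shape must be (4,)*order + (4,)")
        for _ in range(n_seqs):
            s = list(rng.choice(4, size=k, p=probs))
            for _ in range(seq_len - k):
                ctx = tuple(s[-k:])
                s.append(int(rng.choice(4, p=transition[ctx])))
            seqs.append("".join(ALPHABET[b] for b in s[:seq_len]))
    return SequenceSet(sequences=seqs, role=role, name=name)


def _mutate(word: str, d: int, p_con: float, rng: np.random.Generator) -> str:
    """Mutate exactly i ~ Binomial(d, p_con) positions of ``word``."""
    weights = np.array([p_mutation(i, d, p_con) for i in range(d + 1)])
    i = int(rng.choice(d + 1, p=weights))
    if i == 0:
        return word
    positions = rng.choice(len(word), size=i, replace=False)
    w = list(word)
    for p in positions:
        alternatives = [b for b in ALPHABET if b != w[p]]
        w[p] = alternatives[int(rng.integers(3))]
    return "".join(w)


def plant_motif(
    bg: SequenceSet,
    consensus: str,
    d: int,
    p_con: float,
    model: OccupancyModel = OccupancyModel.ZOOPS,
    occupancy: float = 0.8,
    seed: int = 0,
    *,
    max_tries: int = 200,
) -> tuple[SequenceSet, list[PredictedSite]]:
    """Implant mutated instances of ``consensus`` into copies of ``bg``.

    Per sequence the instance count is 1 (OOPS), Bernoulli(occupancy)
    (ZOOPS), or Poisson(occupancy) capped by what fits without overlap
    (TCM).  Implant positions are uniform without overlap.  Returns the test
    set and the ground-truth site list.
    """
    model = OccupancyModel(model)
    l = len(consensus)
    if any(len(s) < l for s in bg.sequences):
        raise ValueError("consensus longer than a background sequence")
    rng = np.random.default_rng(seed)
    out_seqs: list[str] = []
    truth: list[PredictedSite] = []
    for si, s in enumerate(bg.sequences):
        if model is OccupancyModel.OOPS:
            n_inst = 1
        elif model is OccupancyModel.ZOOPS:
            n_inst = int(rng.random() < occupancy)
        else:
            capacity = len(s) // l
            n_inst = min(int(rng.poisson(occupancy)), capacity)
        placed: list[int] = []
        chars = list(s)
        for _ in range(n_inst):
            for _try in range(max_tries):
                start = int(rng.integers(len(s) - l + 1))
                if all(abs(start - q) >= l for q in placed):
                    break
            else:
                raise ValueError(
                    f"cannot place {n_inst} non-overlapping instances in a "
                    f"length-{len(s)} sequence"
                )
            placed.append(start)
            word = _mutate(consensus, d, p_con, rng)
            chars[start : start + l] = word
            truth.append(PredictedSite(si, start, "+", word, 0.0))
        out_seqs.append("".join(chars))
    truth.sort(key=lambda t: (t.seq_index, t.offset))
    test = SequenceSet(
        sequences=out_seqs, role=Role.TEST, name=bg.name + "+planted"
    )
    return test, truth


def write_truth_bed(truth: list[PredictedSite], test: SequenceSet, path) -> None:
    """Ground-truth implant sites as BED6."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(
                f"{test.seq_id(t.seq_index)}\t{t.offset}\t"
                f"{t.offset + len(t.word)}\t{t.word}\t0\t{t.strand}\n"
            )


def write_fasta(sset: SequenceSet, path) -> None:
    """Plain multi-FASTA writer (one line per sequence)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sset.sequences):
            fh.write(f">{sset.seq_id(i)}\n{s}\n")
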