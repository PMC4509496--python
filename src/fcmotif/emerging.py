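"""Emerging-substring mining: discriminative l-mer enumeration.

A word u of length l is an *emerging substring* if its frequency in the test
set reaches the model-dependent threshold λ_f and its test/control frequency
ratio (growth rate g) reaches λ_g.  λ_f is derived from the probability that
a random (l,d)-mutated instance of a planted consensus lands on a given word:

    P_d(i)  = C(d,i) · p_con^i · (1 − p_con)^(d−i)
    P_occ   = Σ_{i=1..d} P_d(i) / (C(l,i) · 3^i)

with λ_f = 0.8·P_occ (OOPS), 0.6·P_occ (ZOOPS) or 1.2·P_occ (TCM).  The
i = 0 term of P_occ is excluded by default: the exact consensus is not a
*mutated* instance, and only the i ≥ 1 form is consistent with the worked
threshold λ_f = 0.6 · 0.8/18 = 0.02667 for (l,d) = (6,1), p_con = 0.8 under
ZOOPS; the full 0..d sum is available via ``include_exact_term``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from math import comb, inf

import pandas as pd

from .sequence_io import SequenceSet, iter_kmers

logger = logging.getLogger("fcmotif")

#: The (l, d) pairs scanned by default, keyed by word length.
DEFAULT_LD_GRID: dict[int, int] = {6: 1, 7: 1, 8: 1, 9: 2, 10: 2, 11: 2, 12: 3}


class OccupancyModel(str, Enum):
    """Per-sequence motif occurrence model."""

    OOPS = "oops"    # exactly one occurrence per sequence
    ZOOPS = "zoops"  # zero or one occurrence per sequence
    TCM = "tcm"      # two-component mixture: any number of occurrences


#: λ_f multiplier applied to P_occ under each occupancy model.
LAMBDA_F_FACTOR = {
    OccupancyModel.OOPS: 0.8,
    OccupancyModel.ZOOPS: 0.6,
    OccupancyModel.TCM: 1.2,
}


@dataclass
class MiningParams:
    """Parameters of one (l, d) mining pass."""

    l: int
    d: int
    model: OccupancyModel = OccupancyModel.ZOOPS
    p_con: float = 0.8
    lambda_g: float = 2.0
    include_exact_term: bool = False  # include i=0 in P_occ (see module doc)
    freq_mode: str = "occurrences"    # or "presence": sequences containing u

    def __post_init__(self) -> None:
        self.model = OccupancyModel(self.model)
        if not 0 < self.l:
            raise ValueError("l must be positive")
        if not 0 <= self.d < self.l:
            raise ValueError("require 0 <= d < l")
        if not 0.0 <= self.p_con <= 1.0:
            raise ValueError("p_con must be a probability")
        if self.lambda_g <= 1.0:
            raise ValueError("lambda_g must exceed 1")
        if self.freq_mode not in ("occurrences", "presence"):
            raise ValueError("freq_mode must be 'occurrences' or 'presence'")


@dataclass
class EmergingSubstring:
    """A candidate word with its counts, frequencies and growth rate."""

    word: str
    count_t: int
    count_c: int
    f_t: float
    f_c: float
    g: float
    passes: bool


def p_mutation(i: int, d: int, p_con: float) -> float:
    """Probability that a random (l,d) instance mutates at exactly i positions.

    Binomial: C(d,i) · p_con^i · (1−p_con)^(d−i).
    """
    if not 0 <= i <= d:
        raise ValueError(f"require 0 <= i <= d, got i={i}, d={d}")
    return comb(d, i) * p_con**i * (1.0 - p_con) ** (d - i)


def p_occ(l: int, d: int, p_con: float, include_exact_term: bool = False) -> float:
    """Probability that a random (l,d) instance equals one specific mutated word.

    Each i-mutation class spreads its probability mass over the C(l,i)·3^i
    words at Hamming distance i from the consensus.
    """
    if not d < l:
        raise ValueError("require d < l")
    lo = 0 if include_exact_term else 1
    return sum(
        p_mutation(i, d, p_con) / (comb(l, i) * 3**i) for i in range(lo, d + 1)
    )


def lambda_f(model: OccupancyModel, p_occ_value: float, n_seqs: int) -> float:
    """Model-dependent frequency threshold λ_f, clamped to [1/n_seqs, 1]."""
    if not 0.0 < p_occ_value <= 1.0:
        raise ValueError("p_occ must lie in (0, 1]")
    model = OccupancyModel(model)
    raw = LAMBDA_F_FACTOR[model] * p_occ_value
    lo = 1.0 / n_seqs
    clamped = min(1.0, max(lo, raw))
    if clamped != raw:
        logger.warning(
            "lambda_f %.6g outside valid range [%.6g, 1]; clamped to %.6g",
            raw, lo, clamped,
        )
    return clamped


def count_words(
    sset: SequenceSet, l: int, both_strands: bool = False
) -> Counter[str]:
    """Occurrence counts of every observed l-mer in the set.

    Overlapping windows all count; with ``both_strands`` the reverse
    complement of each window counts too.  Absent words have implicit count 0.
    """
    counts: Counter[str] = Counter()
    for s in sset.sequences:
        for _, w, _ in iter_kmers(s, l, both_strands):
            counts[w] += 1
    return counts


def count_presence(
    sset: SequenceSet, l: int, both_strands: bool = False
) -> Counter[str]:
    """Number of sequences containing each observed l-mer at least once."""
    counts: Counter[str] = Counter()
    for s in sset.sequences:
        seen = {w for _, w, _ in iter_kmers(s, l, both_strands)}
        counts.update(seen)
    return counts


def growth_rate(f_t: float, f_c: float) -> float:
    """g = f_t / f_c; an absent control word gives +inf (passes any λ_g)."""
    if f_c == 0.0:
        return inf if f_t > 0.0 else 0.0
    return f_t / f_c


def find_emerging(
    counts_t: Counter[str],
    counts_c: Counter[str],
    params: MiningParams,
    n_t: int,
    n_c: int,
    *,
    keep_failing: bool = False,
) -> list[EmergingSubstring]:
    """Emerging substrings among the words observed in the test set.

    Frequencies are occurrence counts divided by the number of sequences in
    the respective set; a word passes iff f_t ≥ λ_f and g ≥ λ_g.  With
    ``keep_failing`` the full diagnostic row of every test-set word is
    returned (for Table-style dumps).
    """
    po = p_occ(params.l, params.d, params.p_con, params.include_exact_term)
    lam_f = lambda_f(params.model, po, n_t)
    out: list[EmergingSubstring] = []
    for word, ct in counts_t.items():
        cc = counts_c.get(word, 0)
        f_t = ct / n_t
        f_c = cc / n_c
        g = growth_rate(f_t, f_c)
        passes = f_t >= lam_f and g >= params.lambda_g
        if passes or keep_failing:
            out.append(EmergingSubstring(word, ct, cc, f_t, f_c, g, passes))
    out.sort(key=lambda e: (-e.count_t, e.word))
    return out


def diagnostic_table(rows: list[EmergingSubstring]) -> pd.DataFrame:
    """Diagnostic DataFrame (word, counts, f, g, passes) mirroring the
    emerging-substring report; suitable for a TSV dump."""
    return pd.DataFrame(
        [
            {
                "word": e.word,
                "count_t": e.count_t,
                "count_c": e.count_c,
                "f_t": e.f_t,
                "f_c": e.f_c,
                "g": e.g,
                "passes": e.passes,
            }
            for e in rows
        ]
    )
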