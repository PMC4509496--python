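"""PWM construction around emerging-substring seeds.

Each emerging substring is treated as a reference word.  Its Hamming-d
neighborhood is enumerated, every neighbor is scored with a two-proportion
z statistic comparing its test-set and control-set rates, qualified
neighbors are collected, and two position count matrices are formed: M1
from test-set counts and M2 from control-set counts rescaled by N1/N2.
The motif PWM Θ normalizes M = max(M1 − M2, 0) with 5% per-column
pseudocounts; the adjacent-pair dependency tables Φ are estimated the same
way from dinucleotide counts of the same weighted instances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb, sqrt

import numpy as np

from .sequence_io import ALPHABET, SequenceSet, encode

logger = logging.getLogger("fcmotif")

Z_THRESHOLD_DEFAULT = 1.643
PSEUDOCOUNT_FRAC_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------

@dataclass
class BackgroundModel:
    """Third-order Markov background with lower-order start fallbacks.

    ``cond[k]`` holds the order-k conditional table of shape (4,)*k + (4,),
    estimated with add-one pseudocounts.  ``theta0`` is the mononucleotide
    marginal and ``phi0`` the dinucleotide joint, both pseudocounted.
    """

    theta0: np.ndarray
    phi0: np.ndarray
    cond: list[np.ndarray]  # orders 0..3
    log_cond: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.log_cond = [np.log(c) for c in self.cond]

    def logp0(self, word: str) -> float:
        """log p0 of a window: order-0..2 at the first three positions,
        order-3 thereafter (context taken within the window)."""
        s = encode(word)
        total = 0.0
        for j in range(len(s)):
            k = min(j, 3)
            ctx = tuple(s[j - k : j])
            total += float(self.log_cond[k][ctx + (s[j],)])
        return total

    def p0(self, word: str) -> float:
        return float(np.exp(self.logp0(word)))


def fit_background(control: SequenceSet, *, min_length: int = 1000) -> BackgroundModel:
    """Fit the Markov background of orders 0..3 on the control set.

    Conditionals are maximum-likelihood with add-one pseudocounts.  A control
    set shorter than ``min_length`` total bases is refused: third-order
    estimation needs at least hundreds of observations per context.
    """
    total_len = control.total_length()
    if total_len < min_length:
        raise ValueError(
            f"control set has only {total_len} bases; supply at least "
            f"{min_length} for background estimation"
        )
    cond = []
    encoded = [encode(s) for s in control.sequences]
    for k in range(4):
        counts = np.ones((4,) * (k + 1), dtype=float)  # add-one pseudocounts
        for a in encoded:
            if len(a) < k + 1:
                continue
            # all (k+1)-grams
            idx = tuple(a[j : len(a) - k + j] for j in range(k + 1))
            np.add.at(counts, idx, 1.0)
        cond.append(counts / counts.sum(axis=-1, keepdims=True))
    theta0 = cond[0].copy()
    # dinucleotide joint with pseudocounts
    pair = np.ones((4, 4), dtype=float)
    for a in encoded:
        if len(a) >= 2:
            np.add.at(pair, (a[:-1], a[1:]), 1.0)
    phi0 = pair / pair.sum()
    return BackgroundModel(theta0=theta0, phi0=phi0, cond=cond)


# ---------------------------------------------------------------------------
# neighborhood enumeration and the z statistic
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodInstance:
    """A word within Hamming distance d of a reference, with its counts."""

    word: str
    hamming: int
    positions: tuple[int, ...] = ()
    count_t: int = 0
    count_c_raw: int = 0
    count_c_adj: float = 0.0
    z: float = 0.0


def neighborhood_size(l: int, d: int) -> int:
    """E = Σ_{i=1..d} C(l,i)·3^i, the number of distinct mutated words."""
    return sum(comb(l, i) * 3**i for i in range(1, d + 1))


def neighborhood(ref: str, d: int) -> list[NeighborhoodInstance]:
    """All words at Hamming distance 1..d from ``ref``.

    Exactly ``neighborhood_size(len(ref), d)`` stubs are returned; the
    reference itself is excluded (callers keep it on the parent record).
    """
    l = len(ref)
    if not d < l:
        raise ValueError("require d < l")
    out: list[NeighborhoodInstance] = []
    for i in range(1, d + 1):
        for positions in itertools.combinations(range(l), i):
            alternatives = [
                [b for b in ALPHABET if b != ref[p]] for p in positions
            ]
            for letters in itertools.product(*alternatives):
                w = list(ref)
                for p, b in zip(positions, letters):
                    w[p] = b
                out.append(
                    NeighborhoodInstance(
                        word="".join(w), hamming=i, positions=positions
                    )
                )
    return out


def z_score(C1: float, C2: float, N1: int, N2: int) -> float:
    """Two-proportion z statistic for counts C1/N1 vs C2/N2.

    Degenerate pooled rates (q = 0 or q = 1) return 0 rather than NaN.
    """
    if N1 <= 0 or N2 <= 0:
        raise ValueError("N1 and N2 must be positive")
    q1 = C1 / N1
    q2 = C2 / N2
    q = (C1 + C2) / (N1 + N2)
    if q <= 0.0 or q >= 1.0:
        return 0.0
    return (q1 - q2) / sqrt(q * (1.0 - q) * (N1 + N2) / (N1 * N2))


def qualify(
    instances: list[NeighborhoodInstance],
    reference: NeighborhoodInstance,
    z_thresh: float = Z_THRESHOLD_DEFAULT,
) -> list[NeighborhoodInstance]:
    """Select the neighborhood instances that enter the count matrices.

    Keeps every instance with z > ``z_thresh``.  Instances are grouped by
    their mutated positions (a single position at d = 1); a group with no
    instance above threshold contributes its maximum-positive-z instance
    instead, if any.  The reference word is always included.
    """
    kept: list[NeighborhoodInstance] = [reference]
    groups: dict[tuple[int, ...], list[NeighborhoodInstance]] = {}
    for inst in instances:
        groups.setdefault(inst.positions, []).append(inst)
    for positions in sorted(groups):
        members = groups[positions]
        above = [m for m in members if m.z > z_thresh]
        if above:
            kept.extend(above)
        else:
            best = max(members, key=lambda m: m.z)
            if best.z > 0.0:
                kept.append(best)
    return kept


# ---------------------------------------------------------------------------
# count matrices and the motif model
# ---------------------------------------------------------------------------

def build_pcms(
    qualified: list[NeighborhoodInstance], N1: int, N2: int, l: int
) -> tuple[np.ndarray, np.ndarray]:
    """Position count matrices M1 (test) and M2 (control, rescaled by N1/N2).

    Instances are weighted by their occurrence counts: each instance adds its
    count to the cell (letter, position) for every position of its word.
    """
    if not qualified:
        raise ValueError("qualified instance list is empty")
    M1 = np.zeros((4, l), dtype=float)
    M2 = np.zeros((4, l), dtype=float)
    scale = N1 / N2
    for inst in qualified:
        idx = encode(inst.word)
        cols = np.arange(l)
        M1[idx, cols] += inst.count_t
        M2[idx, cols] += inst.count_c_raw * scale
    return M1, M2


def build_pair_pcms(
    qualified: list[NeighborhoodInstance], N1: int, N2: int, l: int
) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent-pair count tensors of shape (l−1, 4, 4), weighted like
    :func:`build_pcms`."""
    P1 = np.zeros((l - 1, 4, 4), dtype=float)
    P2 = np.zeros((l - 1, 4, 4), dtype=float)
    scale = N1 / N2
    for inst in qualified:
        idx = encode(inst.word)
        rows = np.arange(l - 1)
        P1[rows, idx[:-1], idx[1:]] += inst.count_t
        P2[rows, idx[:-1], idx[1:]] += inst.count_c_raw * scale
    return P1, P2


def _normalize_with_pseudocounts(
    counts: np.ndarray, frac: float, axis_cells: int
) -> np.ndarray:
    """Normalize a non-negative count block; pseudocount mass = frac × block
    total, split evenly over its cells.  An all-zero block becomes uniform."""
    total = counts.sum()
    if total <= 0.0:
        return np.full_like(counts, 1.0 / axis_cells)
    pc = frac * total / axis_cells
    out = counts + pc
    return out / out.sum()


def pwm_from_pcms(
    M1: np.ndarray,
    M2: np.ndarray,
    pseudocount_frac: float = PSEUDOCOUNT_FRAC_DEFAULT,
    *,
    pseudocount_mode: str = "column_frac",
) -> np.ndarray:
    """PWM Θ from M = max(M1 − M2, 0) with 5% per-column pseudocounts.

    ``column_frac`` adds 5% of each column's post-subtraction total, split
    evenly over the four letters; ``flat`` adds ``pseudocount_frac`` to every
    cell instead.  A column of M that is entirely zero yields the uniform
    column (logged).
    """
    if M1.shape != M2.shape:
        raise ValueError("M1 and M2 must have the same shape")
    M = np.maximum(M1 - M2, 0.0)
    l = M.shape[1]
    theta = np.empty_like(M)
    for i in range(l):
        col = M[:, i]
        if col.sum() <= 0.0:
            logger.info("PWM column %d has no net counts; using uniform", i)
            theta[:, i] = 0.25
        elif pseudocount_mode == "column_frac":
            theta[:, i] = _normalize_with_pseudocounts(col, pseudocount_frac, 4)
        elif pseudocount_mode == "flat":
            c = col + pseudocount_frac
            theta[:, i] = c / c.sum()
        else:
            raise ValueError(f"unknown pseudocount_mode {pseudocount_mode!r}")
    return theta


def phi_from_pair_pcms(
    P1: np.ndarray,
    P2: np.ndarray,
    pseudocount_frac: float = PSEUDOCOUNT_FRAC_DEFAULT,
) -> np.ndarray:
    """Dependency tables Φ from the pair counts, with the same subtraction
    and pseudocount rule applied per 4×4 table."""
    P = np.maximum(P1 - P2, 0.0)
    phi = np.empty_like(P)
    for i in range(P.shape[0]):
        phi[i] = _normalize_with_pseudocounts(P[i], pseudocount_frac, 16)
    return phi


@dataclass
class MotifModel:
    """A motif: PWM Θ, adjacent-pair tables Φ, and its supporting evidence.

    ``counts`` and ``pair_counts`` retain the background-subtracted count
    matrices (M and the pair analogue) so that clustering can merge motifs
    at the count level rather than by averaging probabilities.
    """

    length: int
    theta: np.ndarray              # (4, l), columns sum to 1
    phi: np.ndarray                # (l-1, 4, 4), tables sum to 1
    seed: str
    ic: float = 0.0
    instances: list[NeighborhoodInstance] = field(default_factory=list)
    counts: np.ndarray | None = None       # (4, l)
    pair_counts: np.ndarray | None = None  # (l-1, 4, 4)
    n_support: float = 0.0

    def __post_init__(self) -> None:
        if self.theta.shape != (4, self.length):
            raise ValueError("theta must be 4 x length")
        if self.phi.shape != (self.length - 1, 4, 4):
            raise ValueError("phi must be (length-1) x 4 x 4")


def build_motif(
    seed_word: str,
    qualified: list[NeighborhoodInstance],
    N1: int,
    N2: int,
    pseudocount_frac: float = PSEUDOCOUNT_FRAC_DEFAULT,
) -> MotifModel:
    """Assemble a MotifModel from a seed word and its qualified instances."""
    l = len(seed_word)
    M1, M2 = build_pcms(qualified, N1, N2, l)
    P1, P2 = build_pair_pcms(qualified, N1, N2, l)
    theta = pwm_from_pcms(M1, M2, pseudocount_frac)
    phi = phi_from_pair_pcms(P1, P2, pseudocount_frac)
    return MotifModel(
        length=l,
        theta=theta,
        phi=phi,
        seed=seed_word,
        instances=qualified,
        counts=np.maximum(M1 - M2, 0.0),
        pair_counts=np.maximum(P1 - P2, 0.0),
        n_support=float(sum(i.count_t for i in qualified)),
    )
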