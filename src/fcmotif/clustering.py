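"""Cross-length motif clustering and merging.

Redundant PWMs — many seeds differing by a few letters, and shifted variants
of the same site — are collapsed by greedy agglomeration.  Similarity is the
Harbison score: the maximum over admissible overlap alignments of
1 − D(a', b'), with D the per-column Euclidean PWM distance

    D(a, b) = sqrt( (1/2l) Σ_i Σ_k (a_ik − b_ik)² )  ∈ [0, 1].

The minimum overlap is 7 columns, or two fewer than the shorter motif when
the motifs are shorter than that.  Clusters merge at the count level: the
background-subtracted count matrices are aligned at the best shift and
summed over the union of covered columns, then renormalized with the usual
pseudocount rule, so a cluster of shifted motifs yields a longer motif.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .pwm import MotifModel, PSEUDOCOUNT_FRAC_DEFAULT

MIN_OVERLAP_DEFAULT = 7
SIM_THRESHOLD_DEFAULT = 0.75

_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G


def pwm_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Per-column Euclidean distance between equal-length PWMs, in [0, 1]."""
    if a.shape != b.shape:
        raise ValueError("PWMs must have equal length")
    l = a.shape[1]
    return float(np.sqrt(((a - b) ** 2).sum() / (2 * l)))


def _admissible_shifts(la: int, lb: int, min_overlap: int) -> list[int]:
    """Shifts of b relative to a with sufficient overlap, ordered so that the
    first maximal-similarity shift found is the tie-break winner
    (smallest |shift|, negative before positive).

    The minimum overlap is ``min_overlap`` columns, relaxed by two (and
    capped at the shorter motif) only when a motif is shorter than that.
    """
    shorter = min(la, lb)
    eff = min_overlap if shorter >= min_overlap else min(min_overlap - 2, shorter)
    if eff < 1:
        raise ValueError("motifs too short for any admissible overlap")
    shifts = [
        t for t in range(-(lb - eff), la - eff + 1)
        if min(la, t + lb) - max(0, t) >= eff
    ]
    shifts.sort(key=lambda t: (abs(t), t > 0))
    return shifts


def harbison_similarity(
    a: np.ndarray, b: np.ndarray, min_overlap: int = MIN_OVERLAP_DEFAULT
) -> tuple[float, int]:
    """Best 1 − D over all admissible overlap alignments of PWMs a and b.

    Returns (similarity, shift) where ``shift`` is the offset of b's first
    column relative to a's; ties prefer the smallest |shift|, negative
    before positive.
    """
    la, lb = a.shape[1], b.shape[1]
    if la < 4 or lb < 4:
        raise ValueError("PWMs must have length >= 4")
    best_sim, best_shift = -np.inf, 0
    for t in _admissible_shifts(la, lb, min_overlap):
        lo, hi = max(0, t), min(la, t + lb)
        sim = 1.0 - pwm_distance(a[:, lo:hi], b[:, lo - t : hi - t])
        if sim > best_sim:
            best_sim, best_shift = sim, t
    return best_sim, best_shift


def revcomp_motif(m: MotifModel) -> MotifModel:
    """The reverse-complement motif: columns reversed, letters complemented,
    pair tables reversed with arguments swapped and complemented."""
    theta = m.theta[_COMP][:, ::-1].copy()
    phi = m.phi[::-1][:, _COMP][:, :, _COMP].transpose(0, 2, 1).copy()
    counts = None if m.counts is None else m.counts[_COMP][:, ::-1].copy()
    pair_counts = None
    if m.pair_counts is not None:
        pair_counts = (
            m.pair_counts[::-1][:, _COMP][:, :, _COMP].transpose(0, 2, 1).copy()
        )
    return replace(
        m, theta=theta, phi=phi, counts=counts, pair_counts=pair_counts
    )


def _merge_counts(
    rep: MotifModel, other: MotifModel, shift: int,
    pseudocount_frac: float,
) -> MotifModel:
    """Merge ``other`` into ``rep`` at the given shift, summing the
    background-subtracted counts over the union of covered columns."""
    lo = min(0, shift)
    hi = max(rep.length, shift + other.length)
    L = hi - lo
    counts = np.zeros((4, L))
    counts[:, -lo : -lo + rep.length] += rep.counts
    counts[:, shift - lo : shift - lo + other.length] += other.counts
    pair = np.zeros((L - 1, 4, 4))
    pair[-lo : -lo + rep.length - 1] += rep.pair_counts
    pair[shift - lo : shift - lo + other.length - 1] += other.pair_counts
    # Pseudocount mass is tied to the best-covered column, not each column's
    # own total: columns contributed by a single thin member would otherwise
    # come out spuriously confident after per-column normalization.
    top_col = counts.sum(axis=0).max()
    if top_col <= 0:
        theta = np.full((4, L), 0.25)
        phi = np.full((L - 1, 4, 4), 1.0 / 16)
    else:
        col_pc = pseudocount_frac * top_col / 4
        theta = (counts + col_pc) / (counts.sum(axis=0) + 4 * col_pc)
        pair_totals = pair.sum(axis=(1, 2))
        pair_pc = pseudocount_frac * pair_totals.max() / 16
        phi = (pair + pair_pc) / (pair_totals[:, None, None] + 16 * pair_pc)
    return MotifModel(
        length=L,
        theta=theta,
        phi=phi,
        seed=rep.seed,
        ic=0.0,
        instances=rep.instances + other.instances,
        counts=counts,
        pair_counts=pair,
        n_support=rep.n_support + other.n_support,
    )


def cluster_motifs(
    models: list[MotifModel],
    sim_thresh: float = SIM_THRESHOLD_DEFAULT,
    *,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    both_strands: bool = False,
    pseudocount_frac: float = PSEUDOCOUNT_FRAC_DEFAULT,
) -> list[MotifModel]:
    """Greedy agglomeration of motifs across lengths.

    Models are visited in descending-IC order (ties: larger support, then
    seed).  Each model joins the first cluster whose *founding* model (its
    highest-IC member) reaches ``sim_thresh``; otherwise it seeds a new
    cluster.  Judging membership against the founder rather than the growing
    merge keeps every member within ±(l − min_overlap) columns of the seed —
    a drifting representative would otherwise accrete shifted fragments
    without bound.  With ``both_strands`` the reverse-complement orientation
    is also tried and the better of the two similarities used.  IC of merged
    motifs must be recomputed by the caller (it needs a background model).
    """
    ordered = sorted(models, key=lambda m: (-m.ic, -m.n_support, m.seed))
    founders: list[MotifModel] = []   # membership is judged against these
    merged: list[MotifModel] = []     # running count-level merges
    offsets: list[int] = []           # founder's column offset inside merged
    for m in ordered:
        placed = False
        for ci, founder in enumerate(founders):
            sim, shift = harbison_similarity(
                founder.theta, m.theta, min_overlap
            )
            cand = m
            if both_strands:
                rc = revcomp_motif(m)
                sim_rc, shift_rc = harbison_similarity(
                    founder.theta, rc.theta, min_overlap
                )
                if sim_rc > sim:
                    sim, shift, cand = sim_rc, shift_rc, rc
            if sim >= sim_thresh:
                # shift is relative to the founder; rebase onto the merged
                # motif, whose left edge may extend past the founder's
                new = _merge_counts(
                    merged[ci], cand, shift + offsets[ci], pseudocount_frac
                )
                offsets[ci] += max(0, -(shift + offsets[ci]))
                merged[ci] = new
                placed = True
                break
        if not placed:
            founders.append(m)
            merged.append(m)
            offsets.append(0)
    return merged
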