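"""Dependency-aware log-likelihood-ratio scoring and information content.

A window s of motif length scores

    LLR(s) = log( U(s) · V(s) / p0(s) )

where U is the product of per-position PWM probabilities, V the product of
adjacent-pair dependency probabilities, and p0 the third-order Markov
background (lower orders at the first three window positions).  U and V are
both included as printed in the ranking statistic even though together they
count mononucleotide preference twice; the redundancy is deliberate and
documented rather than corrected.  All logs are natural (scores in nats).

Information content is the KL divergence of the motif distribution from the
mononucleotide background.  The motif joint is the first-order chain
p(s) = θ_1(s_1) · Π_i Φ_{i−1,i}(s_{i−1}, s_i) / m_{i−1}(s_{i−1}) with m the
row marginal of Φ; the KL sum over all 4^l words is evaluated exactly by
dynamic programming over the chain, with a literal-enumeration mode kept
for small l as a cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np

from .pwm import BackgroundModel, MotifModel
from .sequence_io import SequenceSet, encode

# ---------------------------------------------------------------------------
# elementary log-likelihood terms
# ---------------------------------------------------------------------------

def letter_loglik(
    theta: np.ndarray, theta0: np.ndarray, i: int, k: int
) -> float:
    """log(θ_ik / θ_0k): per-letter motif-vs-background log-likelihood."""
    return float(np.log(theta[k, i]) - np.log(theta0[k]))


def pair_loglik(
    phi: np.ndarray, phi0: np.ndarray, i: int, k1: int, k2: int
) -> float:
    """log(Φ_{i,i+1}(k1,k2) / Φ_0(k1,k2)) for adjacent positions i, i+1."""
    return float(np.log(phi[i, k1, k2]) - np.log(phi0[k1, k2]))


def llr(s: str, motif: MotifModel, bg: BackgroundModel) -> float:
    """LLR of one window, evaluated in log space."""
    if len(s) != motif.length:
        raise ValueError(
            f"window length {len(s)} != motif length {motif.length}"
        )
    idx = encode(s)
    log_u = float(np.log(motif.theta[idx, np.arange(motif.length)]).sum())
    log_v = float(
        np.log(motif.phi[np.arange(motif.length - 1), idx[:-1], idx[1:]]).sum()
    )
    return log_u + log_v - bg.logp0(s)


# ---------------------------------------------------------------------------
# vectorized window scanning
# ---------------------------------------------------------------------------

def window_matrix(sset: SequenceSet, l: int) -> tuple[np.ndarray, np.ndarray]:
    """All length-l windows of a set as an (n_windows, l) int matrix.

    Returns (windows, seq_starts) where seq_starts[i] is the row index of
    sequence i's first window; sequences shorter than l contribute none.
    """
    blocks = []
    starts = np.zeros(len(sset.sequences) + 1, dtype=np.int64)
    for i, s in enumerate(sset.sequences):
        if len(s) >= l:
            a = encode(s)
            w = np.lib.stride_tricks.sliding_window_view(a, l)
            blocks.append(w)
            starts[i + 1] = starts[i] + w.shape[0]
        else:
            starts[i + 1] = starts[i]
    if blocks:
        W = np.ascontiguousarray(np.concatenate(blocks, axis=0))
    else:
        W = np.empty((0, l), dtype=np.int8)
    return W, starts


def background_window_logp0(W: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """log p0 of every window row of W under the Markov background."""
    n, l = W.shape
    out = np.zeros(n, dtype=float)
    for j in range(l):
        k = min(j, 3)
        ctx = tuple(W[:, j - k + m] for m in range(k))
        out += bg.log_cond[k][ctx + (W[:, j],)]
    return out


def llr_windows(
    W: np.ndarray, motif: MotifModel, logp0: np.ndarray
) -> np.ndarray:
    """Vectorized LLR of every window row of W (logp0 precomputed)."""
    l = motif.length
    if W.shape[0] == 0:
        return np.zeros(0)
    lt = np.log(motif.theta)
    lp = np.log(motif.phi)
    scores = lt[W, np.arange(l)].sum(axis=1)
    for i in range(l - 1):
        scores += lp[i, W[:, i], W[:, i + 1]]
    return scores - logp0


# ---------------------------------------------------------------------------
# information content
# ---------------------------------------------------------------------------

def _chain_distribution(motif: MotifModel):
    """Initial distribution and transition matrices of the motif chain."""
    init = motif.theta[:, 0]
    transitions = []
    for i in range(motif.length - 1):
        table = motif.phi[i]
        marg = table.sum(axis=1, keepdims=True)
        transitions.append(table / marg)
    return init, transitions


def motif_word_prob(motif: MotifModel, word: str) -> float:
    """p(word | Θ, Φ) under the chain factorization of the motif model."""
    idx = encode(word)
    init, transitions = _chain_distribution(motif)
    p = float(init[idx[0]])
    for i in range(1, len(idx)):
        p *= float(transitions[i - 1][idx[i - 1], idx[i]])
    return p


def information_content(
    motif: MotifModel, bg: BackgroundModel, *, method: str = "chain"
) -> float:
    """IC = KL( p(·|Θ,Φ) || Π θ_0 ), in nats.

    ``chain`` evaluates the sum over Σ^l exactly by propagating the chain's
    position marginals; ``enumerate`` sums over all 4^l words literally
    (cross-check, l ≤ 10 only).
    """
    log_theta0 = np.log(bg.theta0)
    init, transitions = _chain_distribution(motif)
    if method == "enumerate":
        if motif.length > 10:
            raise ValueError("enumerate mode is limited to l <= 10")
        total = 0.0
        for word in itertools.product(range(4), repeat=motif.length):
            p = float(init[word[0]])
            for i in range(1, motif.length):
                p *= float(transitions[i - 1][word[i - 1], word[i]])
            if p > 0.0:
                q = float(np.exp(log_theta0[list(word)].sum()))
                total += p * np.log(p / q)
        return total
    if method != "chain":
        raise ValueError(f"unknown method {method!r}")
    # E_p[log p(s) - log q(s)] accumulated term by term along the chain.
    cur = init.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(cur > 0, cur * (np.log(cur) - log_theta0), 0.0)
    total = float(term.sum())
    for T in transitions:
        pair = cur[:, None] * T  # joint of (s_{i-1}, s_i)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(
                pair > 0, pair * (np.log(T) - log_theta0[None, :]), 0.0
            )
        total += float(contrib.sum())
        cur = pair.sum(axis=0)
    return total
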