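"""FDR-controlled site prediction, motif ranking and report writers.

For each motif the test and control sets are scanned at the motif's length;
the false discovery rate at an integer LLR threshold μ is

    FDR(μ) = (I2 · N1/N2) / I1

with I1 (I2) the number of test (control) windows scoring above μ and
N1, N2 the total window counts.  The selected μ is the smallest integer with
FDR(μ) below the limit (maximizing sensitivity among valid thresholds);
windows of the test set scoring above μ are the predicted sites.  Motifs are
ranked by information content.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pwm import BackgroundModel, MotifModel
from .scoring import (
    background_window_logp0,
    information_content,
    llr_windows,
    window_matrix,
)
from .sequence_io import ALPHABET, SequenceSet, revcomp

logger = logging.getLogger("fcmotif")

FDR_LIMIT_DEFAULT = 0.2
TOP_K_DEFAULT = 50


@dataclass
class PredictedSite:
    """One predicted motif occurrence, on forward-strand coordinates."""

    seq_index: int
    offset: int
    strand: str
    word: str
    llr: float


@dataclass
class RankedMotif:
    """A motif together with its FDR threshold and predicted sites."""

    motif: MotifModel
    mu: int
    fdr: float
    sites: list[PredictedSite]
    consensus: str


@dataclass
class _ScanCache:
    """Window matrices and background log-probabilities, cached per length."""

    test: SequenceSet
    bg: BackgroundModel
    control: SequenceSet | None = None
    _test_data: dict = field(default_factory=dict)
    _control_data: dict = field(default_factory=dict)

    def get_test(self, l: int):
        if l not in self._test_data:
            Wt, starts = window_matrix(self.test, l)
            self._test_data[l] = (
                Wt, starts, background_window_logp0(Wt, self.bg)
            )
        return self._test_data[l]

    def get_control(self, l: int):
        if self.control is None:
            raise ValueError("cache has no control set")
        if l not in self._control_data:
            Wc, _ = window_matrix(self.control, l)
            self._control_data[l] = (Wc, background_window_logp0(Wc, self.bg))
        return self._control_data[l]


def fdr_curve(
    motif: MotifModel,
    bg: BackgroundModel,
    test: SequenceSet,
    control: SequenceSet,
    *,
    cache: _ScanCache | None = None,
) -> dict[int, float]:
    """FDR(μ) for every integer μ in [0, ceil(max LLR over the test set)]."""
    if cache is None:
        cache = _ScanCache(test, bg, control)
    Wt, _, logp0_t = cache.get_test(motif.length)
    Wc, logp0_c = cache.get_control(motif.length)
    llr_t = llr_windows(Wt, motif, logp0_t)
    llr_c = llr_windows(Wc, motif, logp0_c)
    N1, N2 = Wt.shape[0], Wc.shape[0]
    max_mu = max(0, math.ceil(llr_t.max())) if llr_t.size else 0
    curve: dict[int, float] = {}
    for mu in range(max_mu + 1):
        I1 = int((llr_t > mu).sum())
        I2 = int((llr_c > mu).sum())
        if I1 == 0:
            curve[mu] = 0.0 if I2 == 0 else math.inf
        else:
            curve[mu] = (I2 * N1 / N2) / I1
    return curve


def select_mu(curve: dict[int, float], fdr_limit: float = FDR_LIMIT_DEFAULT) -> int:
    """Smallest integer μ with FDR(μ) < limit, else the FDR-minimizing μ."""
    if not curve:
        raise ValueError("empty FDR curve")
    for mu in sorted(curve):
        if curve[mu] < fdr_limit:
            return mu
    best = min(sorted(curve), key=lambda m: curve[m])
    logger.warning(
        "no integer threshold achieves FDR < %.3g; falling back to mu=%d "
        "(FDR %.3g)", fdr_limit, best, curve[best],
    )
    return best


def predict_sites(
    motif: MotifModel,
    bg: BackgroundModel,
    test: SequenceSet,
    mu: int,
    *,
    both_strands: bool = False,
    cache: _ScanCache | None = None,
) -> list[PredictedSite]:
    """Test-set windows with LLR above μ, as forward-coordinate sites."""
    if cache is None:
        cache = _ScanCache(test, bg)
    Wt, starts, logp0_t = cache.get_test(motif.length)
    sites: list[PredictedSite] = []
    scores = llr_windows(Wt, motif, logp0_t)
    hits = np.flatnonzero(scores > mu)
    seq_of = np.searchsorted(starts, hits, side="right") - 1
    for h, si in zip(hits, seq_of):
        off = int(h - starts[si])
        word = test.sequences[si][off : off + motif.length]
        sites.append(PredictedSite(int(si), off, "+", word, float(scores[h])))
    if both_strands:
        rc = _revcomp_scan(motif, bg, test, mu, cache)
        sites.extend(rc)
        sites.sort(key=lambda s: (s.seq_index, s.offset, s.strand))
    return sites


def _revcomp_scan(motif, bg, test, mu, cache) -> list[PredictedSite]:
    from .clustering import revcomp_motif

    rc = revcomp_motif(motif)
    Wt, starts, logp0_t = cache.get_test(motif.length)
    scores = llr_windows(Wt, rc, logp0_t)
    hits = np.flatnonzero(scores > mu)
    seq_of = np.searchsorted(starts, hits, side="right") - 1
    out = []
    for h, si in zip(hits, seq_of):
        off = int(h - starts[si])
        word = revcomp(test.sequences[si][off : off + motif.length])
        out.append(PredictedSite(int(si), off, "-", word, float(scores[h])))
    return out


def consensus_string(theta: np.ndarray) -> str:
    """Argmax letter per column; lowercase where max probability < 0.5."""
    out = []
    for i in range(theta.shape[1]):
        k = int(theta[:, i].argmax())
        ch = ALPHABET[k]
        out.append(ch if theta[k, i] >= 0.5 else ch.lower())
    return "".join(out)


def rank_and_emit(
    models: list[MotifModel],
    bg: BackgroundModel,
    test: SequenceSet,
    control: SequenceSet,
    *,
    top_k: int = TOP_K_DEFAULT,
    fdr_limit: float = FDR_LIMIT_DEFAULT,
    both_strands: bool = False,
) -> list[RankedMotif]:
    """Rank motifs by IC, apply the FDR constraint, and predict sites.

    Motifs whose best achievable FDR never drops below the limit are dropped.
    Ties in IC break toward larger supporting count, then lexicographic seed.
    The scan over candidates stops once ``top_k`` motifs have passed.
    """
    cache = _ScanCache(test, bg, control)
    for m in models:
        if m.ic == 0.0:
            m.ic = information_content(m, bg)
    ordered = sorted(models, key=lambda m: (-m.ic, -m.n_support, m.seed))
    out: list[RankedMotif] = []
    for m in ordered:
        if len(out) >= top_k:
            break
        curve = fdr_curve(m, bg, test, control, cache=cache)
        if not curve:
            continue
        feasible = {mu: f for mu, f in curve.items() if f < fdr_limit}
        if not feasible:
            continue
        mu = select_mu(curve, fdr_limit)
        sites = predict_sites(
            m, bg, test, mu, both_strands=both_strands, cache=cache
        )
        if not sites:
            # a motif with no predicted instance in the test set is vacuous
            continue
        out.append(
            RankedMotif(
                motif=m,
                mu=mu,
                fdr=curve[mu],
                sites=sites,
                consensus=consensus_string(m.theta),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_meme(ranked: list[RankedMotif], bg: BackgroundModel, path) -> None:
    """Write motifs as MEME minimal motif format (letter-probability blocks)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*bg.theta0)
        )
        for rank, rm in enumerate(ranked, start=1):
            m = rm.motif
            fh.write(f"MOTIF motif_{rank} {rm.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= {len(rm.sites)} E= 0\n"
            )
            for i in range(m.length):
                fh.write(
                    " "
                    + " ".join(f"{m.theta[k, i]:.6f}" for k in range(4))
                    + "\n"
                )
            fh.write("\n")


def write_bed(
    ranked: list[RankedMotif], test: SequenceSet, path
) -> None:
    """Write predicted sites as BED6 (0-based half-open; score is the LLR
    scaled linearly onto 0–1000 per motif)."""
    with open(path, "w") as fh:
        for rank, rm in enumerate(ranked, start=1):
            if not rm.sites:
                continue
            top = max(s.llr for s in rm.sites)
            for s in rm.sites:
                score = 0 if top <= 0 else int(round(1000 * max(s.llr, 0) / top))
                fh.write(
                    f"{test.seq_id(s.seq_index)}\t{s.offset}\t"
                    f"{s.offset + rm.motif.length}\tmotif_{rank}:{s.word}\t"
                    f"{score}\t{s.strand}\n"
                )


def report_table(ranked: list[RankedMotif]) -> pd.DataFrame:
    """Summary DataFrame: one row per emitted motif."""
    return pd.DataFrame(
        [
            {
                "motif_id": f"motif_{i}",
                "seed": rm.motif.seed,
                "consensus": rm.consensus,
                "length": rm.motif.length,
                "ic": rm.motif.ic,
                "mu": rm.mu,
                "fdr": rm.fdr,
                "n_sites": len(rm.sites),
                "n_support": rm.motif.n_support,
            }
            for i, rm in enumerate(ranked, start=1)
        ]
    )


def write_report(ranked: list[RankedMotif], path) -> None:
    report_table(ranked).to_csv(path, sep="\t", index=False, float_format="%.6g")
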