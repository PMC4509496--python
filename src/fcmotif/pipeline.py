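"""End-to-end motif discovery: mining → PWM construction → clustering → output.

For each word length l in the configured (l,d) grid, emerging substrings are
mined from the test-vs-control word counts, each seed's Hamming-d
neighborhood is scored and qualified, and a motif model is built.  Models
from all lengths are then clustered, ranked by information content, and
FDR-thresholded sites are predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .clustering import (
    MIN_OVERLAP_DEFAULT,
    SIM_THRESHOLD_DEFAULT,
    cluster_motifs,
)
from .emerging import (
    DEFAULT_LD_GRID,
    MiningParams,
    OccupancyModel,
    count_presence,
    count_words,
    find_emerging,
)
from .output import (
    FDR_LIMIT_DEFAULT,
    RankedMotif,
    TOP_K_DEFAULT,
    rank_and_emit,
)
from .pwm import (
    BackgroundModel,
    MotifModel,
    PSEUDOCOUNT_FRAC_DEFAULT,
    Z_THRESHOLD_DEFAULT,
    build_motif,
    fit_background,
    neighborhood,
    qualify,
    NeighborhoodInstance,
)
from .scoring import information_content
from .sequence_io import SequenceSet

logger = logging.getLogger("fcmotif")


@dataclass
class DiscoveryConfig:
    """All tunable parameters of a discovery run."""

    lmin: int = 6
    lmax: int = 12
    ld_grid: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_LD_GRID))
    model: OccupancyModel = OccupancyModel.ZOOPS
    p_con: float = 0.8
    lambda_g: float = 2.0
    z_thresh: float = Z_THRESHOLD_DEFAULT
    fdr_limit: float = FDR_LIMIT_DEFAULT
    top_k: int = TOP_K_DEFAULT
    both_strands: bool = False
    sim_thresh: float = SIM_THRESHOLD_DEFAULT
    min_overlap: int = MIN_OVERLAP_DEFAULT
    pseudocount_frac: float = PSEUDOCOUNT_FRAC_DEFAULT
    include_exact_term: bool = False
    freq_mode: str = "occurrences"
    max_seeds_per_length: int | None = 1000


@dataclass
class DiscoveryResult:
    ranked: list[RankedMotif]
    background: BackgroundModel
    n_seeds: dict[int, int]          # emerging substrings used per length
    n_models: int                    # motif models before clustering
    n_clusters: int


def mine_motifs_for_length(
    test: SequenceSet,
    control: SequenceSet,
    l: int,
    d: int,
    config: DiscoveryConfig,
) -> list[MotifModel]:
    """Emerging-substring mining and PWM construction at one word length."""
    counter = count_presence if config.freq_mode == "presence" else count_words
    counts_t = counter(test, l, config.both_strands)
    counts_c = counter(control, l, config.both_strands)
    params = MiningParams(
        l=l,
        d=d,
        model=config.model,
        p_con=config.p_con,
        lambda_g=config.lambda_g,
        include_exact_term=config.include_exact_term,
        freq_mode=config.freq_mode,
    )
    seeds = find_emerging(counts_t, counts_c, params, len(test), len(control))
    if (
        config.max_seeds_per_length is not None
        and len(seeds) > config.max_seeds_per_length
    ):
        logger.info(
            "l=%d: %d emerging substrings, capping at %d by test count",
            l, len(seeds), config.max_seeds_per_length,
        )
        seeds = seeds[: config.max_seeds_per_length]
    N1 = test.n_windows(l, config.both_strands)
    N2 = control.n_windows(l, config.both_strands)
    scale = N1 / N2
    models: list[MotifModel] = []
    from .pwm import z_score

    for es in seeds:
        instances = neighborhood(es.word, d)
        for inst in instances:
            inst.count_t = counts_t.get(inst.word, 0)
            inst.count_c_raw = counts_c.get(inst.word, 0)
            inst.count_c_adj = inst.count_c_raw * scale
            inst.z = z_score(inst.count_t, inst.count_c_raw, N1, N2)
        ref = NeighborhoodInstance(
            word=es.word,
            hamming=0,
            positions=(),
            count_t=es.count_t,
            count_c_raw=es.count_c,
            count_c_adj=es.count_c * scale,
            z=z_score(es.count_t, es.count_c, N1, N2),
        )
        qualified = qualify(instances, ref, config.z_thresh)
        models.append(
            build_motif(es.word, qualified, N1, N2, config.pseudocount_frac)
        )
    logger.info("l=%d d=%d: %d seeds -> %d motif models", l, d, len(seeds),
                len(models))
    return models


def discover(
    test: SequenceSet,
    control: SequenceSet,
    config: DiscoveryConfig | None = None,
) -> DiscoveryResult:
    """Run the full discovery pipeline on a test/control pair."""
    config = config or DiscoveryConfig()
    bg = fit_background(control)
    all_models: list[MotifModel] = []
    n_seeds: dict[int, int] = {}
    for l in range(config.lmin, config.lmax + 1):
        if l not in config.ld_grid:
            logger.info("l=%d not in (l,d) grid; skipping", l)
            continue
        d = config.ld_grid[l]
        models = mine_motifs_for_length(test, control, l, d, config)
        n_seeds[l] = len(models)
        all_models.extend(models)
    for m in all_models:
        m.ic = information_content(m, bg)
    clusters = cluster_motifs(
        all_models,
        config.sim_thresh,
        min_overlap=config.min_overlap,
        both_strands=config.both_strands,
        pseudocount_frac=config.pseudocount_frac,
    )
    for m in clusters:
        m.ic = information_content(m, bg)
    ranked = rank_and_emit(
        clusters,
        bg,
        test,
        control,
        top_k=config.top_k,
        fdr_limit=config.fdr_limit,
        both_strands=config.both_strands,
    )
    return DiscoveryResult(
        ranked=ranked,
        background=bg,
        n_seeds=n_seeds,
        n_models=len(all_models),
        n_clusters=len(clusters),
    )
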