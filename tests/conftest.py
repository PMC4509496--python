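import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fcmotif as fm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# The published worked example of neighborhood qualification: reference
# 8-mer ACCACGTG with its 24 single-mutation neighbors, their z-scores and
# test/control counts.  The z values are fixture inputs (the totals N1, N2
# behind them are not published), used to exercise the qualification logic.
REFERENCE_8MER = ("ACCACGTG", 19.36, 119, 9)
NEIGHBOR_TABLE = [
    # (position 1-based, instance, z, C1, C2)
    (1, "CCCACGTG", 21.78, 146, 11),
    (1, "GCCACGTG", 26.14, 177, 7),
    (1, "TCCACGTG", 15.93, 91, 9),
    (2, "AACACGTG", 11.83, 51, 5),
    (2, "AGCACGTG", 22.66, 149, 9),
    (2, "ATCACGTG", 3.28, 16, 6),
    (3, "ACAACGTG", 2.38, 9, 4),
    (3, "ACGACGTG", 1.82, 7, 3),
    (3, "ACTACGTG", 1.31, 5, 3),
    (4, "ACCCCGTG", 2.88, 15, 6),
    (4, "ACCGCGTG", 8.23, 25, 3),
    (4, "ACCTCGTG", 6.16, 23, 5),
    (5, "ACCAAGTG", -0.73, 7, 9),
    (5, "ACCAGGTG", -0.12, 14, 14),
    (5, "ACCATGTG", 2.88, 48, 30),
    (6, "ACCACATG", 0.14, 27, 26),
    (6, "ACCACCTG", -0.30, 17, 18),
    (6, "ACCACTTG", -2.08, 2, 8),
    (7, "ACCACGAG", 5.92, 24, 5),
    (7, "ACCACGCG", 8.63, 30, 4),
    (7, "ACCACGGG", 3.53, 14, 5),
    (8, "ACCACGTA", -0.07, 3, 3),
    (8, "ACCACGTC", 1.03, 7, 5),
    (8, "ACCACGTT", -0.05, 4, 4),
]


@pytest.fixture
def neighbor_instances():
    """NeighborhoodInstance list built from the printed worked example."""
    out = []
    for pos, word, z, c1, c2 in NEIGHBOR_TABLE:
        out.append(
            fm.NeighborhoodInstance(
                word=word, hamming=1, positions=(pos - 1,),
                count_t=c1, count_c_raw=c2, count_c_adj=float(c2), z=z,
            )
        )
    return out


@pytest.fixture
def reference_instance():
    word, z, c1, c2 = REFERENCE_8MER
    return fm.NeighborhoodInstance(
        word=word, hamming=0, positions=(), count_t=c1,
        count_c_raw=c2, count_c_adj=float(c2), z=z,
    )


@pytest.fixture(scope="session")
def uniform_bg():
    """Background fitted on a large i.i.d.-uniform control set: all
    conditionals close to 1/4."""
    control = fm.make_background(40, 10_000, seed=9, role=fm.Role.CONTROL)
    return fm.fit_background(control)


@pytest.fixture
def random_motif():
    """A MotifModel with random (but valid) Θ and Φ built from random
    counts, for scoring oracles."""
    def _make(l: int, seed: int = 0) -> fm.MotifModel:
        rng = np.random.default_rng(seed)
        qualified = []
        for _ in range(6):
            word = "".join(rng.choice(list("ACGT"), size=l))
            qualified.append(
                fm.NeighborhoodInstance(
                    word=word, hamming=0,
                    count_t=int(rng.integers(1, 30)),
                    count_c_raw=int(rng.integers(0, 10)),
                )
            )
        return fm.build_motif(qualified[0].word, qualified, 1000, 1000)
    return _make
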