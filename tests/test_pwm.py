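import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fcmotif as fm


def brute_force_neighbors(ref, d):
    """All words within Hamming distance 1..d of ref, by full enumeration."""
    out = set()
    for word in itertools.product("ACGT", repeat=len(ref)):
        w = "".join(word)
        h = sum(a != b for a, b in zip(w, ref))
        if 1 <= h <= d:
            out.add(w)
    return out


class TestNeighborhood:
    @pytest.mark.parametrize(
        "l,d,expected", [(8, 1, 24), (12, 3, 6570), (6, 1, 18)]
    )
    def test_size_formula(self, l, d, expected):
        assert fm.neighborhood_size(l, d) == expected
        words = fm.neighborhood("A" * l, d)
        assert len(words) == expected
        assert len({w.word for w in words}) == expected

    @pytest.mark.parametrize("ref,d", [("ACGTAC", 1), ("ACGTACG", 2),
                                       ("ACGTACGT", 1)])
    def test_matches_bruteforce_enumeration(self, ref, d):
        got = {w.word for w in fm.neighborhood(ref, d)}
        assert got == brute_force_neighbors(ref, d)

    def test_excludes_reference_and_tracks_distance(self):
        words = fm.neighborhood("ACCACGTG", 1)
        assert "ACCACGTG" not in {w.word for w in words}
        assert all(w.hamming == 1 and len(w.positions) == 1 for w in words)


class TestZScore:
    def test_equal_rates_give_zero(self):
        assert fm.z_score(5, 5, 100, 100) == 0.0

    def test_matches_scalar_formula(self):
        C1, C2, N1, N2 = 119, 9, 10_000, 10_000
        q1, q2 = C1 / N1, C2 / N2
        q = (C1 + C2) / (N1 + N2)
        expected = (q1 - q2) / math.sqrt(
            q * (1 - q) * (N1 + N2) / (N1 * N2)
        )
        assert fm.z_score(C1, C2, N1, N2) == pytest.approx(expected)

    @given(st.integers(0, 50), st.integers(0, 50),
           st.integers(100, 1000), st.integers(100, 1000))
    def test_antisymmetric_under_swap(self, c1, c2, n1, n2):
        z = fm.z_score(c1, c2, n1, n2)
        assert fm.z_score(c2, c1, n2, n1) == pytest.approx(-z)

    def test_degenerate_pooled_rate_returns_zero(self):
        assert fm.z_score(0, 0, 100, 100) == 0.0
        assert fm.z_score(100, 100, 100, 100) == 0.0


class TestQualify:
    def test_no_positive_z_yields_no_fallback(self):
        insts = [
            fm.NeighborhoodInstance("AAAC", 1, (3,), z=-0.5),
            fm.NeighborhoodInstance("AAAG", 1, (3,), z=-2.0),
        ]
        ref = fm.NeighborhoodInstance("AAAA", 0, (), z=5.0)
        kept = fm.qualify(insts, ref)
        assert [k.word for k in kept] == ["AAAA"]

    def test_worked_example_fallbacks(
        self, neighbor_instances, reference_instance
    ):
        kept = fm.qualify(neighbor_instances, reference_instance,
                          z_thresh=1.643)
        words = {k.word for k in kept}
        n_above = sum(1 for k in kept if k.z > 1.643 and k.hamming == 1)
        assert n_above == 15
        # positions 6 and 8 have no neighbor above threshold; their
        # best positive-z instances are kept instead
        assert "ACCACATG" in words and "ACCACGTC" in words
        assert "ACCACCTG" not in words and "ACCACGTA" not in words
        assert reference_instance.word in words
        assert len(kept) == 1 + 15 + 2

    def test_threshold_is_strict(self):
        insts = [fm.NeighborhoodInstance("AAAC", 1, (3,), z=1.643)]
        ref = fm.NeighborhoodInstance("AAAA", 0, (), z=9.0)
        kept = fm.qualify(insts, ref, z_thresh=1.643)
        # 1.643 is not > 1.643, but it is the position's max positive z
        assert {k.word for k in kept} == {"AAAA", "AAAC"}


class TestPcms:
    def test_single_instance_columns(self):
        inst = fm.NeighborhoodInstance("AC", 0, (), count_t=5)
        M1, M2 = fm.build_pcms([inst], 100, 100, 2)
        assert M1[0, 0] == 5 and M1[1, 1] == 5
        assert M1.sum() == 10 and M2.sum() == 0

    def test_split_column(self):
        a = fm.NeighborhoodInstance("AC", 0, (), count_t=5)
        b = fm.NeighborhoodInstance("AG", 0, (), count_t=5)
        M1, _ = fm.build_pcms([a, b], 100, 100, 2)
        assert M1[0, 0] == 10
        assert M1[1, 1] == 5 and M1[2, 1] == 5

    def test_column_sums_conserved_on_worked_example(
        self, neighbor_instances, reference_instance
    ):
        kept = fm.qualify(neighbor_instances, reference_instance)
        M1, M2 = fm.build_pcms(kept, 1000, 1000, 8)
        total = sum(k.count_t for k in kept)
        assert np.allclose(M1.sum(axis=0), total)

    def test_control_rescaled_by_window_ratio(self):
        inst = fm.NeighborhoodInstance("AC", 0, (), count_t=0, count_c_raw=6)
        _, M2 = fm.build_pcms([inst], 100, 300, 2)
        assert M2[0, 0] == pytest.approx(2.0)


class TestPwmFromPcms:
    def test_equal_matrices_give_uniform(self):
        M = np.arange(8, dtype=float).reshape(4, 2) + 1
        theta = fm.pwm_from_pcms(M, M)
        assert np.allclose(theta, 0.25)

    def test_pseudocount_arithmetic(self):
        # single count-10 "A" column: 5% of 10 split over 4 letters
        M1 = np.array([[10.0], [0.0], [0.0], [0.0]])
        theta = fm.pwm_from_pcms(M1, np.zeros_like(M1))
        assert theta[:, 0] == pytest.approx(
            np.array([10.125, 0.125, 0.125, 0.125]) / 10.5
        )

    def test_negative_differences_clipped(self):
        M1 = np.array([[1.0], [0.0], [0.0], [0.0]])
        M2 = np.array([[0.0], [5.0], [0.0], [0.0]])
        theta = fm.pwm_from_pcms(M1, M2)
        # only the A count survives the subtraction
        assert theta[0, 0] == theta.max()
        assert theta[1, 0] == theta[2, 0] == theta[3, 0]

    def test_columns_sum_to_one_and_positive(self, random_motif):
        m = random_motif(8, seed=3)
        assert np.allclose(m.theta.sum(axis=0), 1.0, atol=1e-9)
        assert (m.theta > 0).all()
        assert np.allclose(m.phi.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert (m.phi > 0).all()

    def test_phi_marginals_consistent_with_theta(self):
        # with no control subtraction the pair-table marginals must agree
        # with the single-letter columns
        insts = [
            fm.NeighborhoodInstance("ACGT", 0, (), count_t=7),
            fm.NeighborhoodInstance("AGGT", 0, (), count_t=3),
        ]
        m = fm.build_motif("ACGT", insts, 100, 100)
        for i in range(3):
            row = m.phi[i].sum(axis=1)
            col = m.phi[i].sum(axis=0)
            assert np.allclose(row, m.theta[:, i], atol=1e-6)
            assert np.allclose(col, m.theta[:, i + 1], atol=1e-6)


class TestBackground:
    def test_all_a_control_is_nearly_deterministic(self):
        control = fm.SequenceSet(["A" * 500] * 4, fm.Role.CONTROL)
        bg = fm.fit_background(control)
        assert bg.cond[3][0, 0, 0, 0] > 0.99

    def test_uniform_control_converges_to_quarter(self, uniform_bg):
        for k in range(4):
            assert np.allclose(uniform_bg.cond[k], 0.25, atol=0.02)
        assert np.allclose(uniform_bg.theta0, 0.25, atol=0.02)
        assert np.allclose(uniform_bg.phi0, 0.0625, atol=0.01)

    def test_word_probability_is_product_of_conditionals(self, uniform_bg):
        bg = uniform_bg
        word = "ACGT"
        expected = (
            bg.cond[0][0]
            * bg.cond[1][0, 1]
            * bg.cond[2][0, 1, 2]
            * bg.cond[3][0, 1, 2, 3]
        )
        assert bg.p0(word) == pytest.approx(float(expected))

    def test_short_control_is_rejected(self):
        control = fm.SequenceSet(["ACGT" * 10], fm.Role.CONTROL)
        with pytest.raises(ValueError, match="control"):
            fm.fit_background(control)

    def test_conditionals_normalized(self, uniform_bg):
        for k in range(4):
            sums = uniform_bg.cond[k].sum(axis=-1)
            assert np.allclose(sums, 1.0)
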