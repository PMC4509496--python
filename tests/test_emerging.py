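import math
from collections import Counter

import pytest
from hypothesis import given, strategies as st

import fcmotif as fm
from fcmotif.emerging import OccupancyModel, growth_rate


class TestPMutation:
    @pytest.mark.parametrize(
        "i,d,p,expected",
        [
            (1, 1, 0.8, 0.8),
            (0, 1, 0.8, 0.2),
            (2, 3, 0.2, 0.096),  # C(3,2) * 0.04 * 0.8
        ],
    )
    def test_values(self, i, d, p, expected):
        assert fm.p_mutation(i, d, p) == pytest.approx(expected)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fm.p_mutation(2, 1, 0.5)

    @given(
        st.integers(min_value=0, max_value=5),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_sums_to_one(self, d, p):
        total = sum(fm.p_mutation(i, d, p) for i in range(d + 1))
        assert total == pytest.approx(1.0)


class TestPOcc:
    def test_worked_zoops_setting(self):
        # (6,1) at p_con 0.8: single term 0.8 / (6*3)
        assert fm.p_occ(6, 1, 0.8) == pytest.approx(0.0444444, abs=1e-6)

    def test_zero_mutation_probability(self):
        assert fm.p_occ(8, 2, 0.0) == 0.0

    def test_single_term(self):
        assert fm.p_occ(8, 1, 0.5) == pytest.approx(0.5 / 24)

    def test_exact_term_variant_adds_consensus_mass(self):
        base = fm.p_occ(6, 1, 0.8)
        full = fm.p_occ(6, 1, 0.8, include_exact_term=True)
        assert full == pytest.approx(base + 0.2)


class TestLambdaF:
    def test_published_zoops_threshold(self):
        lam = fm.lambda_f(OccupancyModel.ZOOPS, fm.p_occ(6, 1, 0.8), 600)
        assert round(lam, 5) == 0.02667

    @pytest.mark.parametrize(
        "model,expected",
        [(OccupancyModel.OOPS, 0.04), (OccupancyModel.ZOOPS, 0.03),
         (OccupancyModel.TCM, 0.06)],
    )
    def test_model_multipliers(self, model, expected):
        assert fm.lambda_f(model, 0.05, 100) == pytest.approx(expected)

    def test_model_ordering(self):
        po = 0.02
        assert (
            fm.lambda_f(OccupancyModel.ZOOPS, po, 1000)
            < fm.lambda_f(OccupancyModel.OOPS, po, 1000)
            < fm.lambda_f(OccupancyModel.TCM, po, 1000)
        )

    def test_clamped_to_validity_range(self, caplog):
        # 0.6 * 0.001 falls below 1/100
        lam = fm.lambda_f(OccupancyModel.ZOOPS, 0.001, 100)
        assert lam == pytest.approx(0.01)

    def test_unknown_model_errors(self):
        with pytest.raises(ValueError):
            fm.lambda_f("mixture", 0.05, 100)


class TestCountWords:
    def test_overlapping_windows(self):
        ss = fm.SequenceSet(["AAAA"], fm.Role.TEST)
        assert fm.count_words(ss, 2) == Counter({"AA": 3})

    def test_duplicate_sequences(self):
        ss = fm.SequenceSet(["ACGT", "ACGT"], fm.Role.TEST)
        assert fm.count_words(ss, 4) == Counter({"ACGT": 2})

    @given(
        st.lists(st.text(alphabet="ACGT", min_size=3, max_size=20),
                 min_size=1, max_size=10),
        st.integers(1, 3),
    )
    def test_matches_bruteforce_dictionary(self, seqs, l):
        ss = fm.SequenceSet(seqs, fm.Role.TEST)
        brute = Counter()
        for s in seqs:
            for i in range(len(s) - l + 1):
                brute[s[i : i + l]] += 1
        assert fm.count_words(ss, l) == brute

    def test_both_strands_doubles_totals(self):
        ss = fm.SequenceSet(["ACGTACGT"], fm.Role.TEST)
        fwd = fm.count_words(ss, 3)
        both = fm.count_words(ss, 3, both_strands=True)
        assert sum(both.values()) == 2 * sum(fwd.values())


class TestFindEmerging:
    # published worked rows: counts over 600/600 sequences at the
    # lambda_f = 0.02667 / lambda_g = 2 setting
    TABLE_ROWS = [
        ("AACTGC", 5, 16, 0.0083, 0.3125, False),
        ("AAGTGG", 8, 6, 0.0133, 1.3333, False),
        ("CAGCGA", 19, 3, 0.0317, 6.3333, True),
        ("TGACTT", 15, 7, 0.0250, 2.1429, False),
        ("GCTTCA", 2, 5, 0.0033, 0.4, False),
    ]

    @pytest.fixture
    def params(self):
        return fm.MiningParams(l=6, d=1, model=OccupancyModel.ZOOPS, p_con=0.8)

    def test_published_rows(self, params):
        counts_t = Counter({w: ct for w, ct, _, _, _, _ in self.TABLE_ROWS})
        counts_c = Counter({w: cc for w, _, cc, _, _, _ in self.TABLE_ROWS})
        rows = fm.find_emerging(counts_t, counts_c, params, 600, 600,
                                keep_failing=True)
        by_word = {r.word: r for r in rows}
        for word, ct, cc, f_t, g, passes in self.TABLE_ROWS:
            r = by_word[word]
            assert round(r.f_t, 4) == pytest.approx(f_t, abs=5e-5)
            assert r.g == pytest.approx(g, abs=5e-5)
            assert r.passes is passes

    def test_absent_control_word_gives_infinite_growth(self, params):
        rows = fm.find_emerging(
            Counter({"CAGCGA": 30}), Counter(), params, 600, 600
        )
        assert rows[0].g == math.inf and rows[0].passes

    def test_passing_only_by_default(self, params):
        counts_t = Counter({"CAGCGA": 19, "GCTTCA": 2})
        counts_c = Counter({"CAGCGA": 3, "GCTTCA": 5})
        rows = fm.find_emerging(counts_t, counts_c, params, 600, 600)
        assert [r.word for r in rows] == ["CAGCGA"]

    @given(st.integers(0, 40), st.integers(0, 40))
    def test_pass_decision_matches_definition(self, ct, cc):
        params = fm.MiningParams(l=6, d=1, model=OccupancyModel.ZOOPS,
                                 p_con=0.8)
        n = 600
        rows = fm.find_emerging(
            Counter({"ACGTAC": ct}) if ct else Counter(),
            Counter({"ACGTAC": cc}), params, n, n, keep_failing=True,
        )
        lam_f = fm.lambda_f(params.model, fm.p_occ(6, 1, 0.8), n)
        if ct == 0:
            assert rows == []
        else:
            expected = (ct / n >= lam_f) and (
                growth_rate(ct / n, cc / n) >= 2.0
            )
            assert rows[0].passes == expected


class TestDiagnosticTable:
    def test_columns_and_roundtrip(self, tmp_path):
        rows = [
            fm.EmergingSubstring("CAGCGA", 19, 3, 19 / 600, 3 / 600,
                                 19 / 3, True)
        ]
        from fcmotif.emerging import diagnostic_table

        df = diagnostic_table(rows)
        assert list(df.columns) == [
            "word", "count_t", "count_c", "f_t", "f_c", "g", "passes"
        ]
        assert df.iloc[0]["word"] == "CAGCGA"
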