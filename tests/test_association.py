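"""Association statistics: contingency construction with the exclusion
rule, Cramér's V, Fisher's exact test (including the published 2x2),
subgenome marker frequencies, Evanno ΔK, and pollination-assay scoring."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from polysloc.association import (ContingencyTable, build_contingency,
                                  cramers_v, delta_k, fisher_exact,
                                  marker_frequencies, score_cross)


def table(counts, rows=None, cols=None):
    counts = np.asarray(counts)
    r, c = counts.shape
    return ContingencyTable(rows or [f"r{i}" for i in range(r)],
                            cols or [f"c{j}" for j in range(c)], counts)


def panel_from(records):
    return pd.DataFrame([{"accession": f"a{i}", "cluster": cl, "markers": ms}
                         for i, (cl, ms) in enumerate(records)])


class TestBuildContingency:
    def test_counts_by_marker_and_cluster(self):
        panel = panel_from([("c1", ["A", "D"]), ("c1", ["A", "D"]),
                            ("c2", ["B", "D"])])
        t = build_contingency(panel, ["A", "B"])
        assert t.to_frame().loc["A", "c1"] == 2
        assert t.to_frame().loc["B", "c2"] == 1
        assert t.excluded == 0

    def test_heterozygote_and_noncarrier_excluded(self):
        panel = panel_from([("c1", ["A", "D"]), ("c1", ["A", "B", "D"]),
                            ("c2", ["D"])])
        t = build_contingency(panel, ["A", "B"])
        assert t.n == 1 and t.excluded == 2

    def test_semicolon_string_markers_accepted(self):
        panel = panel_from([("c1", "A;D"), ("c2", "B;D")])
        t = build_contingency(panel, ["A", "B"])
        assert t.n == 2

    def test_empty_after_exclusion_errors(self):
        panel = panel_from([("c1", ["D"])])
        with pytest.raises(ValueError, match="empty"):
            build_contingency(panel, ["A", "B"])

    def test_separate_cluster_mapping(self):
        panel = panel_from([("ignored", ["A"]), ("ignored", ["B"])])
        t = build_contingency(panel, ["A", "B"],
                              clusters={"a0": "x", "a1": "y"})
        assert t.col_labels == ["x", "y"]


class TestCramersV:
    def test_perfect_association(self):
        assert cramers_v(table([[10, 0], [0, 10]])).V == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        res = cramers_v(table([[8, 2], [2, 8]]))
        assert res.chi2 == pytest.approx(7.2)
        assert res.V == pytest.approx(0.6)

    def test_independence(self):
        assert cramers_v(table([[5, 5], [5, 5]])).V == pytest.approx(0.0)

    def test_permutation_and_transpose_invariance(self):
        counts = np.array([[7, 1, 2], [0, 5, 3]])
        base = cramers_v(table(counts)).V
        assert cramers_v(table(counts[:, [2, 0, 1]])).V == pytest.approx(base)
        assert cramers_v(table(counts[[1, 0], :])).V == pytest.approx(base)
        assert cramers_v(table(counts.T)).V == pytest.approx(base)

    def test_v_is_one_iff_rows_partition_columns(self):
        assert cramers_v(table([[4, 0, 0], [0, 3, 0], [0, 0, 2]])).V \
            == pytest.approx(1.0)
        assert cramers_v(table([[4, 1, 0], [0, 3, 0], [0, 0, 2]])).V < 1.0

    def test_empty_row_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res = cramers_v(table([[5, 0], [0, 5], [0, 0]]))
        assert res.V == pytest.approx(1.0)


class TestFisherExact:
    def test_published_wild_vs_cultivated_table(self):
        one, two = fisher_exact(table([[4, 0], [1, 5]]))
        assert round(one, 4) == 0.0238
        assert round(two, 4) == 0.0476

    def test_uniform_2x2(self):
        one, two = fisher_exact(table([[1, 1], [1, 1]]))
        assert two == pytest.approx(1.0)

    def test_matches_scipy_on_2x2(self):
        for counts in ([[4, 0], [1, 5]], [[8, 2], [2, 8]], [[3, 7], [6, 1]]):
            _, two = fisher_exact(table(counts))
            assert two == pytest.approx(
                scipy.stats.fisher_exact(counts)[1], rel=1e-9)

    def test_two_tailed_at_least_one_tailed(self):
        for counts in ([[4, 0], [1, 5]], [[9, 1], [3, 6]], [[2, 2], [2, 2]]):
            one, two = fisher_exact(table(counts))
            assert 0 < one <= two <= 1

    def test_table_probabilities_sum_to_one(self):
        """Hypergeometric probabilities over all 2x2 tables with the
        observed margins are a distribution."""
        from polysloc.association import _log_factorials, _table_log_prob
        counts = np.array([[4, 0], [1, 5]])
        n = counts.sum()
        lf = _log_factorials(n)
        r1, c1 = counts[0].sum(), counts[:, 0].sum()
        total = 0.0
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            t = np.array([[x, r1 - x], [c1 - x, n - r1 - c1 + x]])
            total += math.exp(_table_log_prob(t, lf))
        assert total == pytest.approx(1.0)

    def test_rxc_enumeration_matches_scipy_chi2_direction(self):
        """3x2 exact test by total enumeration: p in (0,1] and smaller for
        a strongly structured table than for a flat one."""
        _, structured = fisher_exact(table([[6, 0], [0, 6], [3, 3]]))
        _, flat = fisher_exact(table([[3, 3], [3, 3], [3, 3]]))
        assert 0 < structured < flat <= 1

    def test_monte_carlo_requires_flag(self):
        big = table(np.full((4, 4), 40))
        with pytest.raises(ValueError, match="monte_carlo"):
            fisher_exact(big)

    def test_monte_carlo_close_to_exact_on_small_table(self):
        t = table([[6, 0], [0, 6], [3, 3]])
        _, exact = fisher_exact(t)
        _, mc = fisher_exact(t, monte_carlo=True, n_resamples=20000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)


class TestMarkerFrequencies:
    SUB = {"A": "sub1", "B": "sub1", "C": "sub1", "D": "sub2", "E": "sub2"}

    def test_published_style_arithmetic(self):
        """49 accessions: 23 homozygous A, 20 homozygous B, 2 homozygous C,
        one B/C heterozygote, 3 others -> 46/98 = 46.9%, 41/98 = 41.8%,
        5/98 = 5.1% on subgenome 1."""
        records = ([("c1", ["A", "D"])] * 23 + [("c2", ["B", "D"])] * 20
                   + [("c2", ["C", "D"])] * 2 + [("c2", ["B", "C", "D"])]
                   + [("c1", ["D"])] * 3)
        panel = panel_from(records)
        freqs = marker_frequencies(panel, self.SUB).set_index("marker")
        assert len(panel) == 49
        assert freqs.loc["A", "slots"] == 46
        assert round(freqs.loc["A", "frequency"], 1) == 46.9
        assert round(freqs.loc["B", "frequency"], 1) == 41.8
        assert round(freqs.loc["C", "frequency"], 1) == 5.1

    def test_fixed_marker_is_100(self):
        panel = panel_from([("c1", ["A", "D"]), ("c2", ["B", "D"])])
        freqs = marker_frequencies(panel, self.SUB).set_index("marker")
        assert freqs.loc["D", "frequency"] == pytest.approx(100.0)

    def test_absent_marker_is_0(self):
        panel = panel_from([("c1", ["A", "D"])])
        freqs = marker_frequencies(panel, self.SUB).set_index("marker")
        assert freqs.loc["E", "frequency"] == 0.0

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            marker_frequencies(pd.DataFrame(columns=["markers"]), self.SUB)


class TestDeltaK:
    def test_linear_likelihood_gives_zero(self):
        runs = {k: [(-100.0 + 10 * k) + eps for eps in (-1, 0, 1)]
                for k in range(1, 6)}
        out = delta_k(runs).set_index("K")
        for k in range(2, 5):
            assert out.loc[k, "deltaK"] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        sd2 = 2 / math.sqrt(2)  # two runs differing by 2*sd2 have sd = 2
        runs = {1: [-100, -100], 2: [-50, -50],
                3: [-40 + sd2, -40 - sd2], 4: [-38, -38]}
        out = delta_k(runs).set_index("K")
        assert out.loc[3, "deltaK"] == pytest.approx(4.0)

    def test_zero_sd_flagged(self):
        runs = {1: [-10, -10], 2: [-5, -5], 3: [-4, -4]}
        out = delta_k(runs).set_index("K")
        assert out.loc[2, "sd_zero"] and pd.isna(out.loc[2, "deltaK"])

    def test_single_run_errors(self):
        with pytest.raises(ValueError, match="2 runs"):
            delta_k({1: [-10], 2: [-5], 3: [-4]})

    def test_nonconsecutive_k_errors(self):
        with pytest.raises(ValueError):
            delta_k({1: [-10, -9], 3: [-5, -4], 4: [-3, -2]})


class TestScoreCross:
    @pytest.mark.parametrize("tubes, expected", [
        (0, "incompatible"), (19, "incompatible"),
        (20, "compatible"), (100, "compatible"),
    ])
    def test_pollen_tube_criterion(self, tubes, expected):
        assert score_cross(pollen_tubes=tubes) == expected

    def test_stringent_criterion(self):
        assert score_cross(pollen_tubes=15, stringent=True) == "compatible"
        assert score_cross(pollen_tubes=9, stringent=True) == "incompatible"

    @pytest.mark.parametrize("mm, expected", [
        (4.9, "incompatible"), (5.0, "compatible"), (12.0, "compatible"),
    ])
    def test_silique_criterion(self, mm, expected):
        assert score_cross(silique_mm=mm) == expected

    def test_exactly_one_measurement(self):
        with pytest.raises(ValueError):
            score_cross()
        with pytest.raises(ValueError):
            score_cross(pollen_tubes=5, silique_mm=3.0)

    def test_negative_measurement(self):
        with pytest.raises(ValueError):
            score_cross(pollen_tubes=-1)
        with pytest.raises(ValueError):
            score_cross(silique_mm=-0.1)


@given(a=st.integers(1, 12), b=st.integers(0, 12),
       c=st.integers(0, 12), d=st.integers(1, 12))
@settings(deadline=None, max_examples=60)
def test_fisher_two_tailed_bounds_hold_generally(a, b, c, d):
    one, two = fisher_exact(table([[a, b], [c, d]]))
    assert 0 < one <= 1 + 1e-12
    assert one <= two + 1e-12
    assert two <= 1 + 1e-12
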