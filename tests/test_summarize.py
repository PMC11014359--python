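"""Summaries, histograms, medians, and between-sample statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racetails.summarize import (
    SummaryError,
    compare_class_fractions,
    compare_length_distributions,
    export,
    length_classes,
    median_length,
    summarize_calls,
)
from tests.test_dedup import make_call


class TestClassFractions:
    def test_fraction_arithmetic(self):
        calls = (
            [make_call(cls="A", key=f"a{i}") for i in range(50)]
            + [make_call(cls="AU", a_len=10, u_len=2, key=f"b{i}") for i in range(25)]
            + [make_call(cls="U", a_len=0, u_len=3, key=f"c{i}") for i in range(15)]
            + [make_call(cls="NONE", a_len=0, u_len=0, key=f"d{i}") for i in range(10)]
        )
        s = summarize_calls(calls, "s", "ref")
        assert s.class_fractions == {"A": 0.50, "AU": 0.25, "U": 0.15, "NONE": 0.10}
        assert s.uridylated_fraction == pytest.approx(0.40)
        assert abs(sum(s.class_fractions.values()) - 1.0) < 1e-9

    def test_all_none_gives_zero_uridylation(self):
        calls = [make_call(cls="NONE", a_len=0, u_len=0, key=str(i))
                 for i in range(5)]
        s = summarize_calls(calls, "s", "ref")
        assert s.uridylated_fraction == 0.0

    def test_other_excluded_from_four_class_denominator(self):
        calls = [make_call(cls="A", key="a"),
                 make_call(cls="OTHER", a_len=0, u_len=0, key="o")]
        s = summarize_calls(calls, "s", "ref")
        assert s.n_molecules == 1 and s.n_other == 1
        assert s.class_fractions["A"] == 1.0

    def test_empty_input_flagged(self):
        s = summarize_calls([], "s", "ref")
        assert s.n_molecules == 0
        assert "no_molecules" in s.flags
        assert s.uridylated_fraction is None

    def test_histograms_conserve_class_counts(self):
        rng = np.random.default_rng(0)
        calls = []
        for i in range(200):
            if rng.random() < 0.2:
                calls.append(make_call(cls="A", a_len=80, censored=True, key=f"a{i}"))
            else:
                calls.append(make_call(cls="A", a_len=int(rng.integers(1, 120)), key=f"a{i}"))
        s = summarize_calls(calls, "s", "ref")
        assert sum(s.a_len_hist.values()) == s.class_counts["A"] == 200


class TestLengthClasses:
    def test_boundary_placement(self):
        assert length_classes([(32, False), (33, False), (64, False),
                               (65, False)]) == (1, 2, 1)

    def test_censored_goes_to_top_class(self):
        assert length_classes([(80, True)]) == (0, 0, 1)

    def test_empty(self):
        assert length_classes([]) == (0, 0, 0)


class TestMedianLength:
    def test_odd_n(self):
        assert median_length([1, 2, 3]) == 2

    def test_even_n_mean_of_middle(self):
        assert median_length([10, 20, 30, 40]) == 25

    def test_empty_is_none(self):
        assert median_length([]) is None

    def test_sample_median_tracks_distribution_median(self):
        """Monte-Carlo: sample median of 20 000 draws from a known
        discrete distribution is within +-1 of its true median."""
        rng = np.random.default_rng(7)
        r, mean = 5.0, 45.0
        p = r / (r + mean)
        draws = rng.negative_binomial(r, p, size=20000)
        draws = draws[draws > 0]
        from scipy import stats as sps
        true_median = sps.nbinom.median(r, p)
        assert abs(median_length(list(draws)) - true_median) <= 1


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        stat, p, dof = compare_class_fractions([30, 20, 10], [30, 20, 10])
        assert stat == 0.0 and p == 1.0 and dof == 2

    def test_2x2_closed_form(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 200*8000^2/1e8 = 128
        stat, p, dof = compare_class_fractions([90, 10], [10, 90])
        assert stat == pytest.approx(128.0)
        assert dof == 1

    def test_p_value_matches_chi2_upper_tail(self):
        from scipy.stats import chi2

        stat, p, dof = compare_class_fractions([90, 10], [10, 90])
        assert p == pytest.approx(chi2.sf(128.0, 1), rel=1e-12)

    def test_zero_column_advises_pooling(self):
        with pytest.raises(SummaryError, match="pool"):
            compare_class_fractions([5, 0], [5, 0])

    @given(
        st.tuples(*[st.integers(0, 200)] * 4).filter(
            lambda t: (t[0] + t[2]) > 0 and (t[1] + t[3]) > 0
            and (t[0] + t[1]) > 0 and (t[2] + t[3]) > 0
        )
    )
    @settings(max_examples=1000, deadline=None)
    def test_agrees_with_closed_form_on_random_2x2(self, table):
        a, b, c, d = table
        stat, _, _ = compare_class_fractions([a, b], [c, d])
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert stat == pytest.approx(expected, rel=1e-10, abs=1e-10)


def _exact_mw_two_sided_p(xs, ys):
    """Enumeration oracle: two-sided p from all rank arrangements."""
    pooled = sorted(xs + ys)
    n1 = len(xs)
    u_obs = sum(1 for x in xs for y in ys if x > y) + 0.5 * sum(
        1 for x in xs for y in ys if x == y
    )
    mean_u = n1 * len(ys) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        group_x = [pooled[i] for i in combo]
        group_y = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for x in group_x for y in group_y if x > y) + 0.5 * sum(
            1 for x in group_x for y in group_y if x == y
        )
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        """U=0 with n=3 vs 3; full enumeration over C(6,3)=20 gives 0.1."""
        u, p = compare_length_distributions([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(_exact_mw_two_sided_p([1, 2, 3], [4, 5, 6]))

    def test_identical_multisets_give_p_one(self):
        _, p = compare_length_distributions([5, 7, 7, 9], [5, 7, 7, 9])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("xs, ys", [
        ([10, 20], [15, 25, 35]),
        ([1, 4, 7], [2, 5, 8, 11]),
        ([3, 9], [1, 2, 10, 12]),
    ])
    def test_small_tie_free_sample_p_matches_enumeration(self, xs, ys):
        """With no ties the exact null is the permutation distribution."""
        _, p = compare_length_distributions(xs, ys)
        assert p == pytest.approx(_exact_mw_two_sided_p(xs, ys), abs=1e-9)

    def test_shifted_samples_detected_with_high_power(self):
        rng = np.random.default_rng(3)
        a = rng.integers(20, 60, size=500)
        b = a + 15  # median shift of 15 nt
        _, p = compare_length_distributions(list(a), list(b))
        assert p < 1e-6

    def test_empty_sample_is_error(self):
        with pytest.raises(SummaryError):
            compare_length_distributions([], [1, 2])


class TestExport:
    def test_tables_written_and_deterministic(self, tmp_path):
        calls = (
            [make_call(cls="A", a_len=40, key=f"a{i}") for i in range(6)]
            + [make_call(cls="AU", a_len=20, u_len=3, key=f"b{i}") for i in range(3)]
            + [make_call(cls="NONE", a_len=0, u_len=0, key="n0")]
        )
        s = summarize_calls(calls, "s", "ref")
        paths1 = export([s], tmp_path / "one")
        paths2 = export([s], tmp_path / "two")
        assert set(paths1) == {
            "classes", "length_classes", "a_len_hist", "au_len_hist",
            "ten_nt_bins", "u_by_total", "medians",
        }
        for name in paths1:
            assert paths1[name].read_bytes() == paths2[name].read_bytes()

    def test_classes_table_has_four_classes_plus_other(self, tmp_path):
        import pandas as pd

        s = summarize_calls([make_call(cls="A", key="a")], "s", "ref")
        paths = export([s], tmp_path)
        df = pd.read_csv(paths["classes"], sep="\t")
        assert list(df["class"]) == ["A", "AU", "U", "NONE", "OTHER"]

    def test_histogram_rows_span_window_plus_censored_category(self, tmp_path):
        import pandas as pd

        s = summarize_calls([make_call(cls="A", key="a")], "s", "ref")
        paths = export([s], tmp_path)
        df = pd.read_csv(paths["a_len_hist"], sep="\t")
        assert len(df) == 81
        assert df["length"].iloc[-1] == ">=81"
        assert df["length"].iloc[0] == "1"
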