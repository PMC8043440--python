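"""Conservative Poisson decrease test: estimator, CDF, p-values, table."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracsurv.incidence import (
    YearlyStratumCounts,
    decrease_test,
    format_p,
    increase_test,
    lambda_hat,
    lambda_low,
    poisson_cdf,
    stratum_counts,
    surveillance_table,
)
from fracsurv.synth import generate_corpus, paper_like_config


def brute_force_poisson_cdf(k: int, rate: float) -> float:
    """Independent oracle: stable iterative pmf summation."""
    if k < 0:
        return 0.0
    pmf = math.exp(-rate)
    total = pmf
    for i in range(1, k + 1):
        pmf *= rate / i
        total += pmf
    return min(total, 1.0)


class TestEstimators:
    def test_lambda_hat_is_arithmetic_mean(self):
        assert lambda_hat([10, 20, 30]) == 20.0
        assert lambda_hat([0, 0, 0, 0, 0]) == 0.0
        assert lambda_hat([295, 301, 288, 290, 300]) == pytest.approx(294.8)

    def test_lambda_hat_empty_is_error(self):
        with pytest.raises(ValueError):
            lambda_hat([])

    def test_lambda_low_reference_value(self):
        # 294.8 - 1.959964*sqrt(294.8/5) by direct arithmetic
        assert lambda_low(294.8, 5) == pytest.approx(279.7496, abs=1e-3)

    def test_lambda_low_floors_at_zero(self):
        assert lambda_low(0.0, 5) == 0.0
        assert lambda_low(0.5, 2) == 0.0  # 0.5 - 1.96*0.5 < 0

    def test_lambda_low_consistency_as_n_grows(self):
        lh = 100.0
        values = [lambda_low(lh, n) for n in (5, 50, 5000, 500000)]
        assert values == sorted(values)
        assert values[-1] == pytest.approx(lh, abs=0.03)


class TestPoissonCdf:
    def test_small_case_against_closed_form(self):
        # P(X<=2 | rate=1) = e^-1 * (1 + 1 + 1/2)
        assert poisson_cdf(2, 1.0) == pytest.approx(2.5 * math.exp(-1), abs=1e-14)

    def test_k_zero_closed_form(self):
        for rate in (0.1, 3.0, 17.5):
            assert poisson_cdf(0, rate) == pytest.approx(math.exp(-rate), abs=1e-14)

    def test_negative_k_and_normalization(self):
        assert poisson_cdf(-1, 5.0) == 0.0
        assert poisson_cdf(10_000, 50.0) == pytest.approx(1.0, abs=1e-12)

    @given(
        k=st.integers(min_value=0, max_value=200),
        rate=st.floats(min_value=1e-6, max_value=50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, k, rate):
        assert poisson_cdf(k, rate) == pytest.approx(
            brute_force_poisson_cdf(k, rate), abs=1e-12
        )


class TestDecreaseTest:
    def ysc(self, baseline, observed, measure="fractures", scope="total"):
        return YearlyStratumCounts(measure, scope, tuple(baseline), observed)

    def test_reference_total_fractures_row(self):
        # baseline mean 294.8 over n=5, observed 233 -> p formats to 0.002
        res = decrease_test(self.ysc([295, 301, 288, 290, 300], 233))
        assert res.lambda_hat == pytest.approx(294.8)
        assert format_p(res.p_value) == "0.002"

    def test_reference_examinations_row_below_point_001(self):
        res = decrease_test(self.ysc([949, 950, 948, 950, 949], 651, "examinations"))
        assert res.p_value < 0.001
        assert format_p(res.p_value) == "< 0.001"

    def test_p_at_the_conservative_mean_is_near_half(self):
        # Poisson CDF at floor(rate) lies in (0.4, 0.6) for rate > 9
        baseline = [100] * 5
        low = lambda_low(100.0, 5)
        res = decrease_test(self.ysc(baseline, round(low)))
        assert 0.4 < res.p_value < 0.6

    def test_direction_note_for_increases(self):
        res = decrease_test(self.ysc([74] * 5, 82))
        assert "observed exceeds" in res.direction_note
        assert res.p_value > 0.9  # lower-tail p is large for an increase

    def test_zero_baseline_convention(self):
        res = decrease_test(self.ysc([0, 0, 0, 0, 0], 0))
        assert res.p_value == 1.0
        assert "lambda_low = 0" in res.direction_note

    def test_monotone_in_observed_and_rate(self):
        baseline = [150] * 5
        ps = [decrease_test(self.ysc(baseline, k)).p_value for k in range(100, 160, 10)]
        assert ps == sorted(ps)
        # p decreases as the conservative rate rises
        p_small = decrease_test(self.ysc([100] * 5, 90)).p_value
        p_large = decrease_test(self.ysc([140] * 5, 90)).p_value
        assert p_large < p_small

    def test_exploratory_increase_test_flags_growth(self):
        res = increase_test(self.ysc([50] * 5, 90))
        assert res.p_value < 0.001
        assert "upper-tail" in res.direction_note


class TestFormatP:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (1.6e-4, "< 0.001"),
            (0.0466, "0.047"),
            (0.5, "0.500"),
            (0.0005, "0.001"),
            (1.0, "1.000"),
        ],
    )
    def test_reporting_convention(self, p, expected):
        assert format_p(p) == expected


@pytest.fixture(scope="module")
def labeled_corpus():
    reports, gold = generate_corpus(paper_like_config(seed=123))
    return reports, gold


class TestSurveillanceTable:
    def test_rows_cover_all_strata(self, labeled_corpus):
        reports, gold = labeled_corpus
        table = surveillance_table(reports, gold, list(range(2015, 2020)), 2020)
        assert len(table) == 2 * (1 + 3 + 6)
        assert set(table.measure) == {"examinations", "fractures"}

    def test_lambda_hat_equals_hand_mean_per_row(self, labeled_corpus):
        reports, gold = labeled_corpus
        years = list(range(2015, 2020))
        table = surveillance_table(reports, gold, years, 2020)
        counts = {
            (c.measure, c.scope): c for c in stratum_counts(reports, gold, years, 2020)
        }
        for _, row in table.iterrows():
            c = counts[(row["measure"], row["scope"])]
            assert row["mean_baseline"] == pytest.approx(
                sum(c.baseline_counts) / len(c.baseline_counts)
            )

    def test_empty_test_year_gives_zero_observed(self, labeled_corpus):
        reports, gold = labeled_corpus
        pre_2020 = [r for r in reports if r.exam_date.year != 2020]
        ids = {r.report_id for r in pre_2020}
        labels = [g for g in gold if g.report_id in ids]
        table = surveillance_table(pre_2020, labels, list(range(2015, 2020)), 2020)
        assert (table.observed == 0).all()
        fr = table.set_index(["measure", "scope"])
        row = fr.loc[("fractures", "total")]
        assert row["p_value"] == pytest.approx(
            poisson_cdf(0, row["lambda_low"]), abs=1e-12
        )

    def test_counts_invariant_fractures_bounded_by_examinations(self, labeled_corpus):
        reports, gold = labeled_corpus
        for c in stratum_counts(reports, gold, list(range(2015, 2020)), 2020):
            assert min(c.baseline_counts) >= 0 and c.observed >= 0
        tab = surveillance_table(reports, gold, list(range(2015, 2020)), 2020)
        piv = tab.set_index(["measure", "scope"])
        for scope in piv.loc["fractures"].index:
            assert (
                piv.loc[("fractures", scope), "observed"]
                <= piv.loc[("examinations", scope), "observed"]
            )


class TestYearlyStratumCounts:
    def test_validation(self):
        with pytest.raises(ValueError):
            YearlyStratumCounts("fractures", "total", (5,), 3)  # n < 2
        with pytest.raises(ValueError):
            YearlyStratumCounts("fractures", "total", (5, -1), 3)
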