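"""Conservative Poisson surveillance test for yearly event counts.

Model: the event count of one stratum (examinations or affirmed fractures
in the fixed yearly window) is Poisson with unknown rate λ. From the n
baseline years the rate is estimated by maximum likelihood,
``λ̂ = mean(baseline counts)``. To make the decrease test conservative, the
test rate is not λ̂ itself but the lower bound of the asymptotic
(1 − α) confidence interval,

    λ̂_low = λ̂ − z_{1−α/2} · sqrt(λ̂ / n),   floored at 0,

and the one-sided p-value is the exact Poisson probability of observing as
many or fewer events as in the test year, ``P(X ≤ observed | λ̂_low)``.
Because λ̂_low < λ under the null, the achieved size is strictly below the
nominal level. The CDF is computed exactly via the regularized
incomplete-gamma identity, never a normal approximation.

No multiple-testing correction is applied across strata; each row of the
surveillance table is a separate test, as in routine monitoring practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .corpus import (
    AgeGroup,
    AnatomicalRegion,
    Label,
    LabelRecord,
    Report,
    filter_population,
    filter_study_window,
)
from .evaluation import labels_to_dict

__all__ = [
    "YearlyStratumCounts",
    "PoissonTestResult",
    "lambda_hat",
    "lambda_low",
    "poisson_cdf",
    "decrease_test",
    "increase_test",
    "format_p",
    "stratum_counts",
    "surveillance_table",
]

Measure = Literal["examinations", "fractures"]


@dataclass(frozen=True, slots=True)
class YearlyStratumCounts:
    """Per-year event counts for one stratum: the input to the test."""

    measure: Measure
    scope: str  # "total", an AgeGroup value, or an AnatomicalRegion value
    baseline_counts: tuple[int, ...]
    observed: int

    def __post_init__(self) -> None:
        if len(self.baseline_counts) < 2:
            raise ValueError("need at least 2 baseline years")
        if min(self.baseline_counts) < 0 or self.observed < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True, slots=True)
class PoissonTestResult:
    measure: Measure
    scope: str
    lambda_hat: float
    lambda_low: float
    n_years: int
    observed: int
    p_value: float
    alpha: float
    direction_note: str = ""


def lambda_hat(baseline_counts: Sequence[int]) -> float:
    """Maximum-likelihood Poisson rate: the mean of the baseline counts."""
    if len(baseline_counts) == 0:
        raise ValueError("baseline_counts must be non-empty")
    return float(np.mean(baseline_counts))


def lambda_low(lh: float, n_years: int, alpha: float = 0.05) -> float:
    """Lower bound of the asymptotic (1−α) CI for the rate, floored at 0.

    Uses the exact normal quantile (Φ⁻¹(0.975) ≈ 1.959964), not 1.96.
    """
    if lh < 0:
        raise ValueError("rate must be non-negative")
    if n_years < 1:
        raise ValueError("need n_years >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    return max(0.0, lh - z * np.sqrt(lh / n_years))


def poisson_cdf(k: int, rate: float) -> float:
    """Exact P(X ≤ k) for X ~ Poisson(rate), via the regularized
    upper-incomplete-gamma identity P(X ≤ k) = Q(k+1, rate).

    Negative k returns 0 by convention; rate 0 gives 1 for any k ≥ 0.
    """
    if k < 0:
        return 0.0
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return 1.0
    return float(special.pdtr(k, rate))


def format_p(p: float) -> str:
    """Reporting convention: below 0.0005 print "< 0.001", else 3 decimals
    rounded half-up."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 0.0005:
        return "< 0.001"
    return str(Decimal(repr(p)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def decrease_test(ysc: YearlyStratumCounts, alpha: float = 0.05) -> PoissonTestResult:
    """One-sided conservative test for a decrease in the test-year count.

    p = P(X ≤ observed | λ̂_low). When the observed count exceeds λ̂ the
    lower-tail construction is still returned, with a direction note (the
    test is defined for decreases only). λ̂_low = 0 yields p = 1, flagged.
    """
    lh = lambda_hat(ysc.baseline_counts)
    low = lambda_low(lh, len(ysc.baseline_counts), alpha)
    note = ""
    if low == 0.0:
        p = 1.0
        note = "degenerate: lambda_low = 0, p = 1 by convention"
    else:
        p = poisson_cdf(ysc.observed, low)
    if ysc.observed > lh:
        note = (note + "; " if note else "") + (
            "observed exceeds baseline mean: lower-tail p is not informative "
            "for an increase"
        )
    return PoissonTestResult(
        measure=ysc.measure,
        scope=ysc.scope,
        lambda_hat=lh,
        lambda_low=low,
        n_years=len(ysc.baseline_counts),
        observed=ysc.observed,
        p_value=p,
        alpha=alpha,
        direction_note=note,
    )


def increase_test(ysc: YearlyStratumCounts, alpha: float = 0.05) -> PoissonTestResult:
    """Exploratory upper-tail analogue: P(X ≥ observed | λ̂ + z·sqrt(λ̂/n)).

    Symmetric counterpart to :func:`decrease_test` for strata where the
    test-year count rose; conservative in the same spirit. This mode is an
    extension of this package, not part of the published construction.
    """
    lh = lambda_hat(ysc.baseline_counts)
    n = len(ysc.baseline_counts)
    z = stats.norm.ppf(1 - alpha / 2)
    high = lh + z * np.sqrt(lh / n)
    p = 1.0 - poisson_cdf(ysc.observed - 1, high) if high > 0 else 1.0
    return PoissonTestResult(
        measure=ysc.measure,
        scope=ysc.scope,
        lambda_hat=lh,
        lambda_low=high,
        n_years=n,
        observed=ysc.observed,
        p_value=p,
        alpha=alpha,
        direction_note="exploratory upper-tail test at lambda_high",
    )


# ---------------------------------------------------------------------------
# Building stratified count tables from a labeled corpus


def _scope_of(report: Report) -> tuple[str, str]:
    return report.age_group.value, report.anatomical_region.value


def stratum_counts(
    reports: Sequence[Report],
    labels: Sequence[LabelRecord] | Mapping[str, Label],
    baseline_years: Sequence[int],
    test_year: int,
) -> list[YearlyStratumCounts]:
    """Per-stratum yearly counts from a labeled corpus.

    Reports are filtered to the study population and windowed per year;
    examinations = report count, fractures = affirmed-labeled count.
    Scopes: total, the three age groups, the six regions.
    """
    label_map = labels_to_dict(labels)
    pop = filter_population(reports)
    years = list(baseline_years) + [test_year]
    scopes = (
        ["total"]
        + [g.value for g in AgeGroup]
        + [r.value for r in AnatomicalRegion]
    )
    counts: dict[tuple[str, str, int], int] = {}
    for year in years:
        for r in filter_study_window(pop, year):
            affirmed = label_map.get(r.report_id) is Label.affirmed
            age_scope, region_scope = _scope_of(r)
            for scope in ("total", age_scope, region_scope):
                counts[("examinations", scope, year)] = (
                    counts.get(("examinations", scope, year), 0) + 1
                )
                if affirmed:
                    counts[("fractures", scope, year)] = (
                        counts.get(("fractures", scope, year), 0) + 1
                    )
    out: list[YearlyStratumCounts] = []
    for measure in ("examinations", "fractures"):
        for scope in scopes:
            baseline = tuple(
                counts.get((measure, scope, y), 0) for y in baseline_years
            )
            observed = counts.get((measure, scope, test_year), 0)
            out.append(YearlyStratumCounts(measure, scope, baseline, observed))
    return out


def surveillance_table(
    reports: Sequence[Report],
    labels: Sequence[LabelRecord] | Mapping[str, Label],
    baseline_years: Sequence[int],
    test_year: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the conservative decrease test over all strata of a labeled corpus.

    Returns one row per (measure, scope) with λ̂, λ̂_low, the observed
    test-year count, the numeric p-value and its formatted text. Strata with
    an all-zero baseline are flagged and not tested.
    """
    rows = []
    for ysc in stratum_counts(reports, labels, baseline_years, test_year):
        if sum(ysc.baseline_counts) == 0:
            rows.append(
                {
                    "measure": ysc.measure,
                    "scope": ysc.scope,
                    "mean_baseline": 0.0,
                    "lambda_low": 0.0,
                    "observed": ysc.observed,
                    "p_value": np.nan,
                    "p_value_text": "",
                    "note": "empty baseline: no test",
                }
            )
            continue
        res = decrease_test(ysc, alpha)
        rows.append(
            {
                "measure": res.measure,
                "scope": res.scope,
                "mean_baseline": res.lambda_hat,
                "lambda_low": res.lambda_low,
                "observed": res.observed,
                "p_value": res.p_value,
                "p_value_text": format_p(res.p_value),
                "note": res.direction_note,
            }
        )
    return pd.DataFrame(rows)
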