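"""Per-period demographic and genetic monitoring summaries.

Assembles the per-survey-period report rows — minimum count, sex ratio,
rabbits per active burrow, density over potential habitat, CB-ancestry and
diversity summaries, Ne — and the year-over-year statistical comparisons
(Welch two-sample t, two-sided Fisher exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PeriodSummary:
    period_id: str
    minimum_count: int
    males: int
    females: int
    n_active_burrows: int | None = None
    habitat_ha: float | None = None
    mean_cb_pct: float = math.nan
    pct_containing_cb: float = math.nan
    pct_wild_born_containing_cb: float = math.nan
    ho: float = math.nan
    he: float = math.nan
    ar: float = math.nan
    ne: float = math.nan
    ne_ci: tuple[float, float] = (math.nan, math.nan)

    def __post_init__(self) -> None:
        if self.males + self.females > self.minimum_count:
            raise ValueError(
                "males + females exceed the minimum count"
            )

    @property
    def sex_ratio(self) -> float:
        if self.females == 0:
            return math.inf if self.males else math.nan
        return self.males / self.females

    @property
    def rabbits_per_burrow(self) -> float:
        if not self.n_active_burrows:
            return math.nan
        return self.minimum_count / self.n_active_burrows

    @property
    def density(self) -> float:
        if not self.habitat_ha or self.habitat_ha <= 0:
            raise ValueError("habitat_ha must be > 0")
        return self.minimum_count / self.habitat_ha


def density(minimum_count: int, habitat_ha: float) -> float:
    """Rabbits per hectare of potential habitat."""
    if habitat_ha <= 0:
        raise ValueError("habitat_ha must be > 0")
    return minimum_count / habitat_ha


def present_density(value: float) -> str:
    """Presentation rounding of a density: two decimals, three when the
    value is below 0.01 (so 0.004 prints as 0.004, not 0.00).  Rounding
    lives only at the presentation layer; computations keep full
    precision."""
    if math.isnan(value):
        return "NA"
    if 0 < value < 0.01:
        return f"{value:.3f}"
    return f"{value:.2f}"


def present_ratio(value: float) -> str:
    if math.isnan(value):
        return "NA"
    return f"{value:.2f}"


def summarize_period(
    period_id: str,
    minimum_count: int,
    males: int,
    females: int,
    habitat_ha: float,
    n_active_burrows: int | None = None,
    genetic: dict | None = None,
) -> PeriodSummary:
    """Assemble one report row; genetic entries (ho/he/ar/ne/cb...) are
    passed through from the diversity and ancestry stages."""
    genetic = genetic or {}
    return PeriodSummary(
        period_id=period_id,
        minimum_count=minimum_count,
        males=males,
        females=females,
        n_active_burrows=n_active_burrows,
        habitat_ha=habitat_ha,
        mean_cb_pct=genetic.get("mean_cb_pct", math.nan),
        pct_containing_cb=genetic.get("pct_containing_cb", math.nan),
        pct_wild_born_containing_cb=genetic.get(
            "pct_wild_born_containing_cb", math.nan
        ),
        ho=genetic.get("ho", math.nan),
        he=genetic.get("he", math.nan),
        ar=genetic.get("ar", math.nan),
        ne=genetic.get("ne", math.nan),
        ne_ci=genetic.get("ne_ci", (math.nan, math.nan)),
    )


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t-test; degenerate inputs return NaN with the
    convention that identical samples give t=0, p=1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return math.nan, math.nan
    if np.array_equal(a, b) and np.var(a) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (point-probability summation), used for
    year-over-year sex-ratio comparisons on raw male/female counts."""
    arr = np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def compare_sex_ratios(
    males_a: int, females_a: int, males_b: int, females_b: int
) -> float:
    return fisher_exact_2x2([[males_a, females_a], [males_b, females_b]])


def apparent_survival_table(cohorts: pd.DataFrame) -> pd.DataFrame:
    """Apparent-survival rates from release/detection counts.

    ``cohorts`` needs columns ``cohort``, ``n_at_risk``, ``n_detected``;
    the returned frame adds the percentage rate.  Apparent survival is
    detection of a released (or previously detected) individual in a later
    survey, so it confounds true survival with emigration and
    non-detection.
    """
    required = {"cohort", "n_at_risk", "n_detected"}
    missing = required - set(cohorts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (cohorts["n_detected"] > cohorts["n_at_risk"]).any():
        raise ValueError("detected exceeds at-risk for a cohort")
    out = cohorts.copy()
    out["rate_pct"] = np.where(
        out["n_at_risk"] > 0,
        100.0 * out["n_detected"] / out["n_at_risk"],
        0.0,
    )
    return out


def survival_rate_pct(n_detected: int, n_at_risk: int) -> float:
    if n_at_risk == 0:
        return 0.0
    return 100.0 * n_detected / n_at_risk


def summary_table(summaries: list[PeriodSummary]) -> pd.DataFrame:
    """Flatten period summaries into the report layout (full precision;
    use the ``present_*`` helpers for display)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "period_id": s.period_id,
                "minimum_count": s.minimum_count,
                "males": s.males,
                "females": s.females,
                "sex_ratio": s.sex_ratio,
                "rabbits_per_burrow": s.rabbits_per_burrow,
                "density": s.density,
                "mean_cb_pct": s.mean_cb_pct,
                "pct_containing_cb": s.pct_containing_cb,
                "pct_wild_born_containing_cb": s.pct_wild_born_containing_cb,
                "ho": s.ho,
                "he": s.he,
                "ar": s.ar,
                "ne": s.ne,
                "ne_ci_low": s.ne_ci[0],
                "ne_ci_high": s.ne_ci[1],
            }
        )
    return pd.DataFrame(rows)
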