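"""Group summaries comparing low-risk vs high-risk respondents.

Conventions: categorical rows as n (%) with one-decimal percentages
rounded half away from zero; age as median (IQR); chi-square without
continuity correction by default; Fisher's exact test for sparse
categorical variables; Mann-Whitney for ordinal/continuous ones.
No multiplicity adjustment is applied.
"""

from __future__ import annotations

import math
import warnings
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import stats

from pcrt.questionnaire import Ethnicity, PatientResponse, Sex, TriState
from pcrt.triage import TriageOutcome

__all__ = [
    "ComparisonTest",
    "GroupComparison",
    "SummaryRow",
    "SummaryTable",
    "format_percent",
    "group_compare",
    "summarize",
]


def format_percent(numerator: int, denominator: int) -> str:
    """One-decimal percent string, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class ComparisonTest(str, Enum):
    chi_square = "chi_square"
    fisher_exact = "fisher_exact"
    mann_whitney = "mann_whitney"


class GroupComparison(BaseModel):
    model_config = ConfigDict(frozen=True)

    variable: str
    test: ComparisonTest
    statistic: Optional[float] = None
    p_value: float


def _contingency(a: Sequence, b: Sequence) -> np.ndarray:
    """Categories x 2-groups count table over the union of observed levels."""
    levels = sorted(set(a) | set(b), key=str)
    table = np.array(
        [[sum(1 for x in a if x == lv) for lv in levels],
         [sum(1 for x in b if x == lv) for lv in levels]]
    ).T
    return table[table.sum(axis=1) > 0]


def _fisher_exact_rxc(table: np.ndarray, max_tables: int = 2_000_000) -> float:
    """Freeman-Halton exact test by enumeration of tables with fixed margins.

    Falls back to a seeded Monte Carlo estimate when the enumeration
    would exceed ``max_tables``.
    """
    table = np.asarray(table, dtype=int)
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    n = table.sum()

    lgam = math.lgamma
    const = sum(lgam(m + 1) for m in row_m) + sum(lgam(m + 1) for m in col_m) - lgam(n + 1)

    def log_prob(cells: np.ndarray) -> float:
        return const - sum(lgam(c + 1) for c in cells.ravel())

    lp_obs = log_prob(table)
    r, c = table.shape

    # rough bound on enumeration size: product over free cells of (margin+1)
    bound = 1
    for i in range(r - 1):
        for j in range(c - 1):
            bound *= min(row_m[i], col_m[j]) + 1
            if bound > max_tables:
                break
        if bound > max_tables:
            break
    if bound > max_tables:
        rng = np.random.default_rng(0)
        draws = stats.random_table(row_m, col_m).rvs(100_000, random_state=rng)
        lps = np.array([log_prob(d) for d in draws])
        return float(np.mean(lps <= lp_obs + 1e-9))

    p_total = 0.0
    cells = np.zeros((r, c), dtype=int)

    def recurse(i: int, j: int, lp_partial: float) -> None:
        nonlocal p_total
        if i == r - 1:
            # last row forced by column margins
            last = col_m - cells[:-1].sum(axis=0)
            if (last >= 0).all() and last.sum() == row_m[-1]:
                lp = lp_partial - sum(lgam(x + 1) for x in last)
                if lp <= lp_obs + 1e-9:
                    p_total += math.exp(lp)
            return
        if j == c - 1:
            x = row_m[i] - cells[i, :-1].sum()
            if x < 0 or cells[:i + 1, j].sum() - cells[i, j] + x > col_m[j]:
                return
            cells[i, j] = x
            recurse(i + 1, 0, lp_partial - lgam(x + 1))
            cells[i, j] = 0
            return
        used_row = cells[i, :j].sum()
        used_col = cells[:i, j].sum()
        hi = min(row_m[i] - used_row, col_m[j] - used_col)
        for x in range(hi + 1):
            cells[i, j] = x
            recurse(i, j + 1, lp_partial - lgam(x + 1))
        cells[i, j] = 0

    recurse(0, 0, const)
    return min(p_total, 1.0)


def group_compare(
    variable: str,
    group_a: Sequence,
    group_b: Sequence,
    test: ComparisonTest | str,
    yates_correction: bool = False,
) -> GroupComparison:
    """Two-sided comparison of one variable between two groups.

    ``chi_square`` and ``fisher_exact`` expect categorical (or binary)
    values and build the contingency table internally; ``mann_whitney``
    expects numeric values.  Low expected counts are surfaced as a
    warning, never as an error.
    """
    test = ComparisonTest(test)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError(f"{variable}: both groups must be non-empty")

    if test == ComparisonTest.mann_whitney:
        method = "asymptotic" if min(len(group_a), len(group_b)) > 20 else "auto"
        u, p = stats.mannwhitneyu(group_a, group_b, alternative="two-sided", method=method)
        return GroupComparison(variable=variable, test=test, statistic=float(u), p_value=float(p))

    table = _contingency(group_a, group_b)
    if table.shape[0] < 2:  # one observed level: no association testable
        return GroupComparison(variable=variable, test=test, statistic=None, p_value=1.0)

    if test == ComparisonTest.chi_square:
        res = stats.chi2_contingency(table, correction=yates_correction)
        if (res.expected_freq < 5).any():
            warnings.warn(
                f"{variable}: expected count below 5; consider fisher_exact",
                stacklevel=2,
            )
        return GroupComparison(
            variable=variable, test=test, statistic=float(res.statistic),
            p_value=float(res.pvalue),
        )

    if table.shape == (2, 2):
        stat, p = stats.fisher_exact(table)
        return GroupComparison(variable=variable, test=test, statistic=float(stat),
                               p_value=float(p))
    return GroupComparison(variable=variable, test=test, statistic=None,
                           p_value=_fisher_exact_rxc(table))


class SummaryRow(BaseModel):
    model_config = ConfigDict(frozen=True)

    variable: str
    group_low: str
    group_high: str
    test: Optional[ComparisonTest] = None
    p_value: Optional[float] = None


class SummaryTable(BaseModel):
    """Demographics-style summary split at the referral threshold."""

    model_config = ConfigDict(frozen=True)

    n_low: int
    n_high: int
    threshold: int
    rows: tuple[SummaryRow, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    f"score < {self.threshold} (n = {self.n_low})": r.group_low,
                    f"score >= {self.threshold} (n = {self.n_high})": r.group_high,
                    "test": r.test.value if r.test else "",
                    "p_value": "" if r.p_value is None else f"{r.p_value:.3g}",
                }
                for r in self.rows
            ]
        )

    def to_markdown(self) -> str:
        return self.to_dataframe().to_markdown(index=False)


def _npct(flags: Sequence[bool], n: int) -> str:
    k = sum(bool(f) for f in flags)
    return f"{k} ({format_percent(k, n)})" if n else "0"


def _median_iqr(values: Sequence[float]) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:g} ({q1:.1f} - {q3:.1f})"


def _has_personal_cancer(r: PatientResponse) -> bool:
    p = r.self_history
    return p is not None and len(p.events) > 0


def _is_ashkenazi(r: PatientResponse) -> bool:
    return TriState.yes in (r.ashkenazi_mother, r.ashkenazi_father)


def summarize(
    cohort: Sequence[PatientResponse],
    outcomes: Sequence[TriageOutcome],
    threshold: int = 3,
) -> SummaryTable:
    """Build the two-group summary table from triaged respondents.

    Rows: sex, age (median/IQR, Mann-Whitney), ethnicity (Fisher),
    diabetes/glucose intolerance, smoking, personal cancer history and
    Ashkenazi ancestry (chi-square).  With a single-group cohort the
    comparison tests are omitted.
    """
    by_id = {o.patient_id: o for o in outcomes}
    low = [r for r in cohort if by_id[r.patient_id].score.total < threshold]
    high = [r for r in cohort if by_id[r.patient_id].score.total >= threshold]
    n_lo, n_hi = len(low), len(high)
    testable = n_lo > 0 and n_hi > 0

    def row(variable: str, fn, test: ComparisonTest, fmt) -> SummaryRow:
        a = [fn(r) for r in low]
        b = [fn(r) for r in high]
        cmp_res = group_compare(variable, a, b, test) if testable else None
        return SummaryRow(
            variable=variable,
            group_low=fmt(a, n_lo) if n_lo else "-",
            group_high=fmt(b, n_hi) if n_hi else "-",
            test=test if cmp_res else None,
            p_value=cmp_res.p_value if cmp_res else None,
        )

    def pct_fmt(values: Sequence[bool], n: int) -> str:
        return _npct(values, n)

    def med_fmt(values: Sequence[float], n: int) -> str:
        return _median_iqr(values)

    rows = [
        row("Female, n (%)", lambda r: r.sex == Sex.female, ComparisonTest.chi_square, pct_fmt),
        row("Age, median (IQR)", lambda r: r.age, ComparisonTest.mann_whitney, med_fmt),
    ]

    # ethnicity: one tested parent row, then per-category count rows
    eth_cmp = (
        group_compare("Ethnicity", [r.ethnicity for r in low], [r.ethnicity for r in high],
                      ComparisonTest.fisher_exact)
        if testable
        else None
    )
    rows.append(
        SummaryRow(
            variable="Ethnicity, n (%)", group_low="", group_high="",
            test=ComparisonTest.fisher_exact if eth_cmp else None,
            p_value=eth_cmp.p_value if eth_cmp else None,
        )
    )
    for eth in Ethnicity:
        rows.append(
            SummaryRow(
                variable=f"  {eth.value}",
                group_low=_npct([r.ethnicity == eth for r in low], n_lo) if n_lo else "-",
                group_high=_npct([r.ethnicity == eth for r in high], n_hi) if n_hi else "-",
            )
        )

    rows += [
        row("Diabetes or glucose intolerance, n (%)",
            lambda r: r.nod.diabetes_or_glucose_intolerance,
            ComparisonTest.chi_square, pct_fmt),
        row("Currently tobacco smoking, n (%)", lambda r: r.current_smoker,
            ComparisonTest.chi_square, pct_fmt),
        row("Personal history of any cancer, n (%)", _has_personal_cancer,
            ComparisonTest.chi_square, pct_fmt),
        row("Ashkenazi Jewish ancestry, n (%)", _is_ashkenazi,
            ComparisonTest.chi_square, pct_fmt),
    ]
    return SummaryTable(n_low=n_lo, n_high=n_hi, threshold=threshold, rows=tuple(rows))
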