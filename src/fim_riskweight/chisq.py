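"""Chi-square contingency weights (weight group A1).

For each risk factor ``v`` a 2x5 observed table is formed over the five
outcome (LCM) risk levels: the ``v`` row holds, per LCM level, the summed
share of ``v`` in each observation's total crude rate across all risk
factors; the complement row makes columns total the per-level observation
counts.  Pearson's chi-square statistic on this table (df = 4) measures how
unevenly the variable's rate mass distributes over outcome risk levels, and
the per-variable statistics, normalized to sum 1, form the first weight
group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import LCM

logger = logging.getLogger(__name__)

#: Degrees of freedom of a 2x5 contingency table.
DF = 4


@dataclass(frozen=True)
class ObservedTable:
    """2x5 observed table for one variable: (v, non-v) x risk levels 1..5.

    Entries are nonnegative reals; fractional entries are permitted (the
    rate-share construction produces them).
    """

    variable: str
    values: np.ndarray  # shape (2, 5)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (2, 5):
            raise ValueError(f"observed table must be 2x5, got {values.shape}")
        if (values < -1e-12).any():
            raise ValueError("observed table entries must be nonnegative")
        if values.sum() <= 0:
            raise ValueError("observed table grand total must be positive")
        object.__setattr__(self, "values", values)

    @property
    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square decomposition of a 2x5 observed table."""

    variable: str
    observed: np.ndarray
    expected: np.ndarray
    contributions: np.ndarray  # (O - E)^2 / E, zero where E = 0
    statistic: float
    pvalue: float
    df: int = DF


def build_observed(
    rates: pd.DataFrame,
    levels: pd.DataFrame,
    variable: str,
    outcome: str = LCM,
) -> ObservedTable:
    """Observed 2x5 table of rate shares for ``variable`` across outcome levels.

    For each observation, the variable's *share* is its crude rate divided by
    the observation's total crude rate over all risk factors (the outcome
    column is excluded from the total).  Row ``v`` sums shares within each
    outcome risk level; row ``non-v`` is the level's observation count minus
    that, so column totals equal the outcome level frequencies and the grand
    total equals the number of observations.  Observations with an all-zero
    rate total are dropped with a warning.
    """
    if variable not in rates.columns:
        raise KeyError(f"unknown variable: {variable!r}")
    if outcome not in levels.columns:
        raise KeyError(f"outcome column {outcome!r} not in levels")
    factors = [c for c in rates.columns if c != outcome]
    totals = rates[factors].sum(axis=1)
    ok = totals > 0
    if (~ok).any():
        logger.warning(
            "dropping %d observation(s) with all-zero rates from %s's table",
            int((~ok).sum()), variable,
        )
    share = rates.loc[ok, variable] / totals[ok]
    lcm_level = levels.loc[ok, outcome].to_numpy(dtype=int)
    values = np.zeros((2, 5))
    for ell in range(1, 6):
        in_level = lcm_level == ell
        values[0, ell - 1] = share.to_numpy()[in_level].sum()
        values[1, ell - 1] = in_level.sum() - values[0, ell - 1]
    return ObservedTable(variable=variable, values=values)


def expected_under_independence(observed: ObservedTable) -> np.ndarray:
    """Expected table under row/column independence: row_i * col_j / total.

    Zero row or column margins yield zero expected entries.
    """
    return np.outer(observed.row_totals, observed.column_totals) / observed.grand_total


def pearson_chisq(observed: ObservedTable) -> ChiSquareResult:
    """Pearson chi-square statistic, per-cell contributions and p-value (df=4).

    Cells with zero expected value contribute 0 by convention.
    """
    expected = expected_under_independence(observed)
    contributions = np.zeros_like(expected)
    nz = expected > 0
    contributions[nz] = (observed.values[nz] - expected[nz]) ** 2 / expected[nz]
    statistic = float(contributions.sum())
    return ChiSquareResult(
        variable=observed.variable,
        observed=observed.values,
        expected=expected,
        contributions=contributions,
        statistic=statistic,
        pvalue=float(stats.chi2.sf(statistic, DF)),
    )


def chisq_weights(statistics: pd.Series) -> pd.Series:
    """Normalize per-variable chi-square statistics into weight group A1."""
    stats_arr = statistics.astype(float)
    if len(stats_arr) == 0:
        raise ValueError("no chi-square statistics given")
    if (stats_arr < 0).any():
        raise ValueError("chi-square statistics must be nonnegative")
    total = stats_arr.sum()
    if total == 0:
        raise ValueError("all chi-square statistics are zero: no information")
    return stats_arr / total


def chisq_stage(
    rates: pd.DataFrame,
    levels: pd.DataFrame,
    outcome: str = LCM,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Run the full chi-square stage over every risk factor.

    Returns (statistics, p-values, weights), each indexed by variable.
    """
    factors = [c for c in rates.columns if c != outcome]
    results = {
        v: pearson_chisq(build_observed(rates, levels, v, outcome=outcome))
        for v in factors
    }
    statistics = pd.Series({v: r.statistic for v, r in results.items()}, name="chisq")
    pvalues = pd.Series({v: r.pvalue for v, r in results.items()}, name="pvalue")
    return statistics, pvalues, chisq_weights(statistics)
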