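"""Analytic Hierarchy Process priority vectors (weight group A3).

An expert (Delphi) pairwise-comparison matrix A has a(i, j) > 0 expressing
how much more important variable i is than variable j.  Three standard
prioritization methods are provided:

* ``column_norm_mean`` (default) — normalize each column to sum 1 and
  average across columns;
* ``geometric_mean`` — normalized row geometric means;
* ``eigenvector`` — principal right eigenvector by power iteration.

Reciprocity (a(i,j) * a(j,i) = 1) is *checked and reported*, not enforced:
elicited matrices in practice violate it, and the computation proceeds on
the matrix as given, with loud diagnostics.  Consistency is summarized by
Saaty's consistency index CI = (lambda_max - n)/(n - 1) and consistency
ratio CR = CI / RI(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Saaty random consistency indices RI(n), n = 1..15.
SAATY_RI = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49,
            1.51, 1.48, 1.56, 1.57, 1.59)

#: tolerance on |a(i,j)*a(j,i) - 1| before a pair is flagged; loose enough
#: to absorb 2-decimal rounding of reciprocals like 1/3 ~ 0.33.
RECIPROCITY_TOL = 0.05

METHODS = ("column_norm_mean", "geometric_mean", "eigenvector")


@dataclass(frozen=True)
class PairwiseMatrix:
    """A positive pairwise-comparison matrix with its reciprocity report."""

    values: pd.DataFrame  # square, index == columns == variable names
    reciprocity_violations: tuple[tuple[str, str, float], ...]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def variables(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class AhpResult:
    """Priority vector with consistency diagnostics."""

    weights: pd.Series      # nonnegative, sums to 1
    lambda_max: float       # principal-eigenvalue estimate mean((A w)_i / w_i)
    ci: float               # (lambda_max - n) / (n - 1)
    cr: float               # CI / RI(n)
    method: str


def _check_matrix(values: pd.DataFrame) -> PairwiseMatrix:
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"pairwise matrix must be square, got {values.shape}")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all() or (arr <= 0).any():
        raise ValueError("pairwise matrix entries must be positive and finite")
    if not np.allclose(np.diag(arr), 1.0, atol=1e-9):
        raise ValueError("pairwise matrix diagonal must be 1")
    names = list(values.index)
    violations = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            prod = arr[i, j] * arr[j, i]
            if abs(prod - 1.0) > RECIPROCITY_TOL:
                violations.append((names[i], names[j], float(prod)))
    if violations:
        logger.warning(
            "pairwise matrix violates reciprocity in %d pair(s), e.g. %s",
            len(violations), violations[0],
        )
    return PairwiseMatrix(values=values, reciprocity_violations=tuple(violations))


def read_pairwise_matrix(path) -> PairwiseMatrix:
    """Read a pairwise-comparison CSV (first column = variable names).

    The header row must repeat the variable names; entries must be positive.
    Reciprocity violations are logged and carried in the result.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column variable names differ or are misordered")
    return _check_matrix(df)


def pairwise_from_dataframe(values: pd.DataFrame) -> PairwiseMatrix:
    """Validate an in-memory square comparison table."""
    return _check_matrix(values)


def random_index(n: int) -> float:
    """Saaty random consistency index RI(n); linear extrapolation above 15."""
    if n < 1:
        raise ValueError("n must be positive")
    if n <= 15:
        return SAATY_RI[n - 1]
    slope = SAATY_RI[-1] - SAATY_RI[-2]
    logger.warning("RI table covers n <= 15; extrapolating linearly for n=%d", n)
    return SAATY_RI[-1] + slope * (n - 15)


def priority_vector(
    matrix: PairwiseMatrix, method: str = "column_norm_mean"
) -> AhpResult:
    """Derive the AHP priority vector (weight group A3) and consistency stats."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    arr = matrix.values.to_numpy(dtype=float)
    n = matrix.n
    if method == "column_norm_mean":
        w = (arr / arr.sum(axis=0, keepdims=True)).mean(axis=1)
    elif method == "geometric_mean":
        w = np.exp(np.log(arr).mean(axis=1))
        w = w / w.sum()
    else:
        w = np.full(n, 1.0 / n)
        for _ in range(10_000):
            w_new = arr @ w
            w_new = w_new / w_new.sum()
            if np.abs(w_new - w).max() < 1e-10:
                w = w_new
                break
            w = w_new
        else:
            residual = float(np.abs(arr @ w / (arr @ w).sum() - w).max())
            raise RuntimeError(
                f"power iteration did not converge (residual {residual:.3e})"
            )
    w = w / w.sum()
    lambda_max = float(np.mean((arr @ w) / w))
    ci = (lambda_max - n) / (n - 1) if n > 1 else 0.0
    cr = 0.0 if n < 3 else ci / random_index(n)
    weights = pd.Series(w, index=matrix.variables, name=f"ahp_{method}")
    return AhpResult(weights=weights, lambda_max=lambda_max, ci=ci, cr=cr,
                     method=method)


def consistency_ratio(result: AhpResult, n: int) -> float:
    """Consistency ratio CR = CI / RI(n); defined as 0 for n < 3."""
    if n < 3:
        return 0.0
    return result.ci / random_index(n)
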