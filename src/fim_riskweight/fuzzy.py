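"""Fuzzy composition and lattice-degree-of-nearness selection.

Each weight group A (chi-square, RIDIT, AHP) is composed with a fuzzy
membership matrix R (risk factors x five risk classes, rows summing to 1)
to give a composed membership vector B = A . R, normalized to sum 1.  Each
B is compared with a reference membership vector C over the same classes
through the lattice operations

* inner composition  B (x) C = max_l min(B_l, C_l)   (max-min)
* outer composition  B (.) C = min_l max(B_l, C_l)   (min-max)
* lattice degree of nearness  sigma = [ (B (x) C) + 1 - (B (.) C) ] / 2

and the weight group with maximal sigma is selected.  All internal math is
in proportions; percentages appear only at I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import LCM

logger = logging.getLogger(__name__)

#: Fixed tie-break order of the three weight-derivation methods.
METHOD_ORDER = ("chisq", "ridit", "ahp")


def _as_membership(vector, name: str = "membership vector") -> np.ndarray:
    arr = np.asarray(vector, dtype=float)
    if arr.ndim != 1 or len(arr) != 5:
        raise ValueError(f"{name} must have 5 entries, got shape {arr.shape}")
    if (arr < -1e-12).any():
        raise ValueError(f"{name} entries must be nonnegative")
    return arr


def membership_matrix(levels: pd.DataFrame, outcome: str = LCM) -> pd.DataFrame:
    """Fuzzy membership matrix R: risk factors x the five outcome risk classes.

    Entry (v, l) starts as the level-l agreement rate — the fraction of
    observations at level l of variable v whose outcome level is also l —
    and each row is renormalized to sum 1.  A variable identical to the
    outcome gives (after renormalization of perfect agreement) a uniform
    row; an uninformative variable gives an approximately uniform row, and a
    single observation gives a point mass on its class.  Empty level groups
    contribute 0 before renormalization; a row of all zeros is replaced by a
    uniform row with a warning.
    """
    if outcome not in levels.columns:
        raise KeyError(f"outcome column {outcome!r} not in levels")
    out = levels[outcome].to_numpy(dtype=int)
    factors = [c for c in levels.columns if c != outcome]
    rows = {}
    for v in factors:
        lv = levels[v].to_numpy(dtype=int)
        raw = np.zeros(5)
        for ell in range(1, 6):
            group = lv == ell
            if group.any():
                raw[ell - 1] = (out[group] == ell).mean()
        if raw.sum() == 0:
            logger.warning("variable %s never agrees with the outcome level; "
                           "using a uniform membership row", v)
            raw = np.full(5, 0.2)
        rows[v] = raw / raw.sum()
    R = pd.DataFrame.from_dict(rows, orient="index", columns=range(1, 6))
    R.index.name = "variable"
    return R


def compose(weights: pd.Series, R: pd.DataFrame) -> pd.Series:
    """Composed membership vector B = A . R, renormalized to sum 1."""
    if set(weights.index) != set(R.index):
        raise ValueError("weight index does not match membership-matrix rows")
    b = R.mul(weights.reindex(R.index), axis=0).sum(axis=0).to_numpy(dtype=float)
    total = b.sum()
    if total <= 0:
        raise ValueError("composed membership vector has zero mass")
    return pd.Series(b / total, index=R.columns, name="B")


def inner_composition(B, C) -> float:
    """Max-min composition: max over classes of min(B_l, C_l)."""
    b, c = _as_membership(B, "B"), _as_membership(C, "C")
    return float(np.minimum(b, c).max())


def outer_composition(B, C) -> float:
    """Min-max composition: min over classes of max(B_l, C_l)."""
    b, c = _as_membership(B, "B"), _as_membership(C, "C")
    return float(np.maximum(b, c).min())


def lattice_nearness(B, C) -> float:
    """Lattice degree of nearness sigma = [(B (x) C) + 1 - (B (.) C)] / 2."""
    return 0.5 * (inner_composition(B, C) + 1.0 - outer_composition(B, C))


def select_optimal(sigmas: Mapping[str, float]) -> str:
    """Method with maximal sigma; ties go to the fixed order chisq, ridit, ahp."""
    if not sigmas:
        raise ValueError("no nearness values given")
    best = max(sigmas.values())
    tied = [m for m, s in sigmas.items() if s == best]
    if len(tied) > 1:
        tied.sort(key=lambda m: (METHOD_ORDER.index(m) if m in METHOD_ORDER
                                 else len(METHOD_ORDER), m))
        logger.info("nearness tie among %s; selecting %s by fixed order",
                    tied, tied[0])
    return tied[0]


def reference_membership(
    lcm_rates: pd.Series, lcm_levels: pd.Series
) -> pd.Series:
    """Reference membership vector C from the outcome's own rate mass.

    C_l = (sum of outcome crude rates over observations at outcome level l)
    / (total outcome crude rate).  C increases across levels whenever higher
    levels hold higher rates.
    """
    rates = lcm_rates.to_numpy(dtype=float)
    lv = lcm_levels.to_numpy(dtype=int)
    total = rates.sum()
    if total <= 0:
        raise ValueError("total outcome rate is zero")
    c = np.array([rates[lv == ell].sum() for ell in range(1, 6)]) / total
    return pd.Series(c, index=range(1, 6), name="C")


def membership_from_composition_rows(inner_row, outer_row, C) -> np.ndarray:
    """Recover B from printed per-class min(B,C) and max(B,C) rows.

    For each class, min(B_l, C_l) and max(B_l, C_l) are {B_l, C_l} as a set,
    so B_l is whichever printed entry differs from C_l (both equal C_l iff
    B_l = C_l).  Used to reconstruct composed vectors from published
    nearness tables.
    """
    inner = _as_membership(inner_row, "inner row")
    outer = _as_membership(outer_row, "outer row")
    c = _as_membership(C, "C")
    b = np.where(inner != c, inner, np.where(outer != c, outer, c))
    return b


@dataclass(frozen=True)
class NearnessResult:
    """Per-method compositions, nearness values and the selected method."""

    composed: dict[str, np.ndarray]     # B per method
    inner: dict[str, float]             # B (x) C
    outer: dict[str, float]             # B (.) C
    sigma: dict[str, float]
    reference: np.ndarray               # C
    selected: str

    def to_dict(self) -> dict:
        return {
            "reference_C": list(self.reference),
            "methods": {
                m: {
                    "B": list(self.composed[m]),
                    "inner": self.inner[m],
                    "outer": self.outer[m],
                    "sigma": self.sigma[m],
                }
                for m in self.sigma
            },
            "selected": self.selected,
        }


def nearness_analysis(
    weight_groups: Mapping[str, pd.Series],
    R: pd.DataFrame,
    C: Sequence[float] | pd.Series,
) -> NearnessResult:
    """Compose each weight group with R, score against C, select the optimal.

    ``weight_groups`` maps method names (conventionally chisq/ridit/ahp) to
    weight vectors over R's rows.
    """
    c = _as_membership(C, "C")
    composed, inner, outer, sigma = {}, {}, {}, {}
    for method, weights in weight_groups.items():
        b = compose(weights, R).to_numpy()
        composed[method] = b
        inner[method] = inner_composition(b, c)
        outer[method] = outer_composition(b, c)
        sigma[method] = lattice_nearness(b, c)
    return NearnessResult(
        composed=composed, inner=inner, outer=outer, sigma=sigma,
        reference=c, selected=select_optimal(sigma),
    )
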