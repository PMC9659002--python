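"""Packaged reference fixtures from the published worked examples.

The CSVs under ``fim_riskweight/data`` transcribe the published
intermediate tables of the lung-cancer-mortality study this pipeline
reimplements: the chi-square worked example, the per-variable chi-square
statistics, the pooled outcome level frequencies, the Delphi
pairwise-comparison matrix, the lattice-nearness table and the final
method-ranking comparison.  They serve as oracles in tests and as inputs
to the fixture-anchored acceptance checks.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

from .ahp import PairwiseMatrix, pairwise_from_dataframe
from .chisq import ObservedTable
from .fuzzy import membership_from_composition_rows

_DATA = files("fim_riskweight") / "data"

_LEVEL_COLS = ["very_low", "low", "medium", "high", "very_high"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def load_chisq_example() -> ObservedTable:
    """The published 2x5 observed table for disease burden (DB)."""
    df = _read("table2_chisq_example.csv", index_col=0)
    return ObservedTable(variable="DB", values=df[_LEVEL_COLS].to_numpy(float))


def load_chisq_values() -> pd.DataFrame:
    """Published per-variable chi-square statistics and normalized weights."""
    return _read("table3_chisq_values.csv", index_col=0)


def load_level_frequencies() -> np.ndarray:
    """Published pooled outcome level frequencies (sum 1097)."""
    df = _read("table4_level_frequencies.csv")
    return df["frequency"].to_numpy(int)


def load_delphi_matrix() -> PairwiseMatrix:
    """Published 30x30 Delphi pairwise-comparison matrix (reciprocity unenforced)."""
    df = _read("table6_delphi.csv", index_col=0)
    return pairwise_from_dataframe(df)


def load_nearness_example() -> dict:
    """Published lattice-nearness table.

    Returns a dict with the reference vector ``C`` (proportions), and per
    method the printed inner (max-min) row, outer (min-max) row, the
    composed membership vector ``B`` reconstructed from them, and the
    printed nearness value ``sigma`` (proportion).
    """
    df = _read("table8_nearness.csv")
    c = df.loc[(df["method"] == "reference"), _LEVEL_COLS].to_numpy(float)[0] / 100
    out: dict = {"C": c, "methods": {}}
    for method in ("chisq", "ridit", "ahp"):
        rows = df[df["method"] == method].set_index("row")
        inner = rows.loc["inner", _LEVEL_COLS].to_numpy(float) / 100
        outer = rows.loc["outer", _LEVEL_COLS].to_numpy(float) / 100
        out["methods"][method] = {
            "inner_row": inner,
            "outer_row": outer,
            "B": membership_from_composition_rows(inner, outer, c),
            "sigma": float(rows.loc["sigma", "very_low"]) / 100,
        }
    return out


def load_method_rankings() -> pd.DataFrame:
    """Published method-comparison table: per-variable weights and ranks."""
    return _read("table9_method_rankings.csv", index_col=0)
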