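"""Ingestion of long-format mortality tables, crude rates and quintile risk levels.

A mortality table is a long-format :class:`pandas.DataFrame` with columns
``country, year, variable, deaths, population``: one row per
country, calendar year and variable, where each variable is a mortality
cause/risk-factor acronym (:data:`RISK_FACTORS`) or the outcome
(:data:`LCM`).  From it the module derives

* a *rate matrix* — observations (country or country-year) x variables,
  crude mortality rates (deaths per person);
* a *risk-level matrix* — the same shape with each variable's rates cut
  into five quintile risk levels 1 (very low) ... 5 (very high).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Acronyms of the 30 country-level risk-factor mortality variables.
RISK_FACTORS: tuple[str, ...] = (
    "DB",       # disease burden
    "TB",       # tuberculosis
    "UWS",      # unsafe water source
    "USN",      # unsafe sanitation
    "NHF",      # no access to handwashing facility
    "HAP",      # household air pollution from solid fuels
    "NEB",      # non-exclusive breastfeeding
    "DBF",      # discontinued breastfeeding
    "CW",       # child wasting
    "CS",       # child stunting
    "LBW",      # low birth weight due to short gestation
    "SHS",      # secondhand smoke
    "AU",       # alcohol use
    "DU",       # drug use
    "DLF",      # diet low in fruits
    "DLV",      # diet low in vegetables
    "USX",      # unsafe sex
    "LPA",      # low physical activity
    "HFP",      # high fasting plasma glucose
    "HBM",      # high body-mass index
    "HBP",      # high systolic blood pressure
    "IDY",      # iron deficiency
    "Smoking",
    "VAD",      # vitamin A deficiency
    "LBD",      # low bone mineral density
    "AP",       # air pollution
    "OAP",      # outdoor air pollution
    "DHS",      # diet high in sodium
    "DLG",      # diet low in whole grains
    "DLN",      # diet low in nuts and seeds
)

#: Name of the outcome variable: lung-cancer mortality.
LCM = "LCM"

#: Full display names for the acronyms (outcome included).
VARIABLE_NAMES: dict[str, str] = {
    "DB": "Disease burden",
    "TB": "Tuberculosis",
    "UWS": "Unsafe water source",
    "USN": "Unsafe sanitation",
    "NHF": "No access to handwashing facility",
    "HAP": "Household air pollution from solid fuels",
    "NEB": "Non-exclusive breastfeeding",
    "DBF": "Discontinued breastfeeding",
    "CW": "Child wasting",
    "CS": "Child stunting",
    "LBW": "Low birth weight due to short gestation",
    "SHS": "Secondhand smoke",
    "AU": "Alcohol use",
    "DU": "Drug use",
    "DLF": "Diet low in fruits",
    "DLV": "Diet low in vegetables",
    "USX": "Unsafe sex",
    "LPA": "Low physical activity",
    "HFP": "High fasting plasma glucose",
    "HBM": "High body-mass index",
    "HBP": "High systolic blood pressure",
    "IDY": "Iron deficiency",
    "Smoking": "Smoking",
    "VAD": "Vitamin A deficiency",
    "LBD": "Low bone mineral density",
    "AP": "Air pollution",
    "OAP": "Outdoor air pollution",
    "DHS": "Diet high in sodium",
    "DLG": "Diet low in whole grains",
    "DLN": "Diet low in nuts and seeds",
    LCM: "Lung cancer mortality",
}

REQUIRED_COLUMNS = ("country", "year", "variable", "deaths", "population")

#: Risk-level labels, index 1..5.
LEVEL_LABELS = ("very low", "low", "medium", "high", "very high")


class SchemaError(ValueError):
    """A required column is missing (after applying the column mapping)."""


class ValidationError(ValueError):
    """A row violates a mortality-table invariant."""


def validate_mortality_table(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Validate a long mortality table against its invariants.

    Checks that every (country, year, variable) triple is unique, deaths are
    nonnegative, populations positive, and the variable vocabulary is exactly
    ``variables`` (default: the 30 risk-factor acronyms plus ``LCM``).

    With ``strict=True`` the first violation raises :class:`ValidationError`
    naming the offending row; with ``strict=False`` offending rows are dropped
    and each dropped row is logged with its reason.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    vocab = set(RISK_FACTORS) | {LCM} if variables is None else set(variables)

    table = table.copy()
    reasons = pd.Series("", index=table.index, dtype=object)
    bad_var = ~table["variable"].isin(vocab)
    reasons[bad_var] = "variable not in configured vocabulary"
    bad_deaths = pd.to_numeric(table["deaths"], errors="coerce").fillna(-1) < 0
    reasons[bad_deaths] = "negative or non-numeric deaths"
    bad_pop = pd.to_numeric(table["population"], errors="coerce").fillna(0) <= 0
    reasons[bad_pop] = "non-positive or non-numeric population"
    dup = table.duplicated(subset=["country", "year", "variable"], keep=False)
    reasons[dup & (reasons == "")] = "duplicate (country, year, variable) triple"

    bad = reasons != ""
    if bad.any():
        first = bad.idxmax()
        if strict:
            raise ValidationError(
                f"row {first} ({table.loc[first, 'country']}, "
                f"{table.loc[first, 'year']}, {table.loc[first, 'variable']}): "
                f"{reasons[first]}"
            )
        for idx in table.index[bad]:
            logger.warning("dropping row %s: %s", idx, reasons[idx])
        table = table[~bad]
    return table.reset_index(drop=True)


def read_mortality_table(
    path,
    schema: Mapping[str, str] | None = None,
    variables: Sequence[str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Read and validate a long-format mortality CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from the canonical column names
        (``country, year, variable, deaths, population``) to the names used
        in the file, e.g. ``{"country": "location_name"}``.
    variables
        Allowed variable vocabulary; defaults to the 30 risk-factor acronyms
        plus ``LCM``.
    strict
        Raise on the first invalid row (default) instead of dropping it.
    """
    raw = pd.read_csv(path)
    if schema:
        rename = {src: canonical for canonical, src in schema.items()}
        missing = [s for s in schema.values() if s not in raw.columns]
        if missing:
            raise SchemaError(f"mapped column(s) not found in {path}: {missing}")
        raw = raw.rename(columns=rename)
    table = validate_mortality_table(raw, variables=variables, strict=strict)
    table["year"] = table["year"].astype(int)
    table["deaths"] = table["deaths"].astype(float)
    table["population"] = table["population"].astype(float)
    return table[list(REQUIRED_COLUMNS)]


def crude_rates(table: pd.DataFrame, unit: str = "country-year") -> pd.DataFrame:
    """Compute the crude-rate matrix (observations x variables).

    ``unit="country-year"`` yields one observation per country and year with
    rate = deaths / population.  ``unit="country"`` averages over years:
    rate = (mean annual deaths) / (mean annual population size).
    Observations missing any variable are dropped listwise and logged.
    """
    if unit not in ("country", "country-year"):
        raise ValueError(f"unknown observation unit: {unit!r}")
    if unit == "country-year":
        work = table.assign(rate=table["deaths"] / table["population"])
        wide = work.pivot_table(
            index=["country", "year"], columns="variable", values="rate",
            aggfunc="first",
        )
    else:
        deaths = table.pivot_table(
            index="country", columns="variable", values="deaths", aggfunc="mean"
        )
        # population is recorded per (country, year); its per-country mean is
        # the same for every variable with full records
        pop = table.pivot_table(
            index="country", columns="variable", values="population", aggfunc="mean"
        )
        wide = deaths / pop
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        for obs in wide.index[incomplete]:
            logger.warning("dropping observation %s: missing variable(s)", obs)
        wide = wide[~incomplete]
    wide.columns.name = None
    return wide


def _quintile_column(values: np.ndarray) -> np.ndarray:
    """Quintile risk levels 1..5 for one variable.

    Observations are stably sorted by value (ties keep original row order)
    and split at sorted ranks ceil(n*k/5), k = 1..4.
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    position = np.empty(n, dtype=int)
    position[order] = np.arange(n)
    cuts = np.ceil(n * np.arange(1, 5) / 5).astype(int)
    return np.searchsorted(cuts, position, side="right") + 1


def quintile_classify(rates: pd.DataFrame) -> pd.DataFrame:
    """Classify every variable's rates into five quintile risk levels.

    Returns an integer matrix with the same index/columns as ``rates`` and
    values in 1..5 (very low ... very high risk).  A constant column carries
    no ordering information and is assigned level 1 throughout, with a
    warning.

    Raises ``ValueError`` with fewer than 5 observations.
    """
    n = len(rates)
    if n < 5:
        raise ValueError(f"need at least 5 observations to form quintiles, got {n}")
    columns = {}
    for col in rates.columns:
        values = rates[col].to_numpy(dtype=float)
        if np.all(values == values[0]):
            logger.warning("variable %s is constant; all observations level 1", col)
            columns[col] = np.ones(n, dtype=int)
        else:
            columns[col] = _quintile_column(values)
    return pd.DataFrame(columns, index=rates.index)[list(rates.columns)]


def level_frequencies(levels: pd.DataFrame, variable: str) -> np.ndarray:
    """Counts of observations in risk levels 1..5 for one variable."""
    if variable not in levels.columns:
        raise KeyError(f"unknown variable: {variable!r}")
    counts = np.bincount(levels[variable].to_numpy(dtype=int), minlength=6)[1:6]
    return counts


def brute_force_quintiles(values: Iterable[float]) -> np.ndarray:
    """Reference quintile classifier: sort and cut at index ceil(n*k/5).

    Independent re-statement of the quintile convention used by
    :func:`quintile_classify`, written directly from the rank definition;
    used as a test oracle.
    """
    values = np.asarray(list(values), dtype=float)
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    levels = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        level = 5
        for k in (1, 2, 3, 4):
            if rank < math.ceil(n * k / 5):
                level = k
                break
        levels[idx] = level
    return levels
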