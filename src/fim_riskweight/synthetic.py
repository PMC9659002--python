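"""Synthetic GBD-style mortality tables with planted ground truth.

The generator emulates the structure of a Global-Burden-of-Disease result
extract: ~100 countries observed over 11 calendar years, with crude
mortality rates for 30 risk-factor variables plus the lung-cancer-mortality
outcome.  Each country carries a latent severity score ``z ~ N(0, 1)``;
variables in the *informative set* have log-rates shifted by
``effect * z``, the outcome's log-rate is shifted by ``z`` itself, and all
other variables are pure noise.  This single shared latent factor is the
simplest structure producing the monotone variable-outcome association the
quintile cross-classification downstream is designed to detect.

Ground truth (informative set, effect sizes, latent scores) is recorded so
that ranking stages can be scored for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import LCM, RISK_FACTORS

#: Default informative set: five variables planted as associated with LCM.
DEFAULT_INFORMATIVE = ("Smoking", "LPA", "CW", "LBW", "IDY")


def _per_variable(value, variables: Sequence[str], what: str) -> dict[str, float]:
    """Broadcast a scalar, or validate a mapping, over ``variables``."""
    if isinstance(value, Mapping):
        missing = [v for v in variables if v not in value]
        if missing:
            raise ValueError(f"{what} missing for variable(s): {missing}")
        return {v: float(value[v]) for v in variables}
    return {v: float(value) for v in variables}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the scale of the GBD extract the pipeline targets:
    100 countries x 11 years (2006-2016) with 3 missing country-year
    observations, i.e. 1097 observations per variable, and 5 informative
    variables at effect size 1.0.
    """

    n_countries: int = 100
    years: tuple[int, int] = (2006, 2016)  # inclusive
    variables: tuple[str, ...] = RISK_FACTORS
    informative_set: tuple[str, ...] = DEFAULT_INFORMATIVE
    #: log-rate shift per unit of latent severity, per informative variable
    #: (a scalar broadcasts).
    effect_sizes: Mapping[str, float] | float = 1.0
    #: per-variable mean of log crude rate (scalar broadcasts); default
    #: corresponds to a rate of 5e-5 deaths per person.
    baseline_log_mean: Mapping[str, float] | float = math.log(5e-5)
    #: per-variable between-country SD of log crude rate.
    baseline_log_sd: Mapping[str, float] | float = 0.6
    #: outcome baseline: mean/SD of the LCM log crude rate.
    lcm_log_mean: float = math.log(4e-4)
    lcm_log_sd: float = 0.6
    #: SD of the lognormal year-to-year noise on every log-rate.
    noise_sd: float = 0.2
    #: number of randomly deleted country-year observations.
    missing_rows: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 5:
            raise ValueError("n_countries must be at least 5")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")
        unknown = set(self.informative_set) - set(self.variables)
        if unknown:
            raise ValueError(f"informative_set not a subset of variables: {unknown}")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        effects = _per_variable(self.effect_sizes, self.informative_set, "effect size")
        if any(e < 0 for e in effects.values()):
            raise ValueError("effect sizes must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        n_units = self.n_countries * self.n_years
        if not 0 <= self.missing_rows < n_units:
            raise ValueError("missing_rows must be in [0, n_countries * n_years)")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: recoverable targets for ranking stages."""

    variables: tuple[str, ...]
    informative_set: tuple[str, ...]
    effect_sizes: dict[str, float]
    #: latent per-country severity score driving the LCM association.
    latent: dict[str, float]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            variables=tuple(raw["variables"]),
            informative_set=tuple(raw["informative_set"]),
            effect_sizes={k: float(v) for k, v in raw["effect_sizes"].items()},
            latent={k: float(v) for k, v in raw["latent"].items()},
            seed=int(raw["seed"]),
        )


def generate(config: SyntheticConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a long-format mortality table and its ground truth.

    Per country ``c``: latent severity ``z_c ~ N(0,1)``, population
    lognormal around 1e7 (constant over years).  Per variable ``v`` and
    country: baseline log-rate ``b ~ N(mu_v, sd_v)``.  Per year: log-rate =
    b + effect_v * z_c (informative variables) + N(0, noise_sd); the outcome
    uses effect 1 on z.  Deaths = round(rate * population).  The same seed
    yields an identical table.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    countries = [f"C{i:03d}" for i in range(config.n_countries)]
    years = config.year_list
    all_vars = list(config.variables) + [LCM]
    effects = _per_variable(config.effect_sizes, config.informative_set, "effect size")
    mu = _per_variable(config.baseline_log_mean, config.variables, "baseline log-mean")
    sd = _per_variable(config.baseline_log_sd, config.variables, "baseline log-sd")
    mu[LCM], sd[LCM] = config.lcm_log_mean, config.lcm_log_sd
    beta = {v: effects.get(v, 0.0) for v in config.variables}
    beta[LCM] = 1.0

    z = rng.standard_normal(config.n_countries)
    population = np.round(rng.lognormal(math.log(1e7), 0.5, config.n_countries))
    # country x variable baseline, then country x variable x year noise
    base = {
        v: mu[v] + sd[v] * rng.standard_normal(config.n_countries) for v in all_vars
    }
    records = []
    for vi, v in enumerate(all_vars):
        noise = config.noise_sd * rng.standard_normal(
            (config.n_countries, len(years))
        )
        log_rate = base[v][:, None] + beta[v] * z[:, None] + noise
        rate = np.exp(log_rate)
        deaths = np.round(rate * population[:, None])
        for ci, c in enumerate(countries):
            for yi, y in enumerate(years):
                records.append((c, y, v, deaths[ci, yi], population[ci]))
    table = pd.DataFrame(
        records, columns=["country", "year", "variable", "deaths", "population"]
    )

    if config.missing_rows:
        units = [(c, y) for c in countries for y in years]
        drop_idx = rng.choice(len(units), size=config.missing_rows, replace=False)
        dropped = {units[i] for i in drop_idx}
        keep = ~table.set_index(["country", "year"]).index.isin(dropped)
        table = table[keep].reset_index(drop=True)

    truth = GroundTruth(
        variables=tuple(config.variables),
        informative_set=tuple(config.informative_set),
        effect_sizes=effects,
        latent={c: float(z[i]) for i, c in enumerate(countries)},
        seed=config.seed,
    )
    return table, truth


def recovery_report(
    ranking: Sequence[str], truth: GroundTruth, k: int
) -> float:
    """Fraction of the planted informative set found in the top ``k`` of a ranking.

    ``ranking`` must cover exactly the generator's variable set, best first.
    """
    if set(ranking) != set(truth.variables):
        raise ValueError("ranking does not cover the generator's variable set")
    if len(ranking) != len(set(ranking)):
        raise ValueError("ranking contains duplicates")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the number of variables ({len(ranking)})")
    if not truth.informative_set:
        raise ValueError("ground truth has no informative variables to recover")
    top = set(ranking[:k])
    hits = sum(1 for v in truth.informative_set if v in top)
    return hits / len(truth.informative_set)
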