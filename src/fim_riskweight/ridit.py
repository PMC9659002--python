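"""RIDIT analysis weights (weight group A2).

RIDIT ("Relative to an Identified Distribution") scoring assigns each
ordinal risk level its mid-rank proportion under a reference distribution:
ridit(level) = (count below + half the count at the level) / total.  Ridits
lie in (0, 1) and their frequency-weighted mean is exactly 0.5.

The reference distribution here is the pooled outcome (LCM) level
frequency vector.  A risk factor's score is the frequency-weighted mean
absolute deviation from 0.5 of the mean outcome ridit within each of the
factor's own level groups — 0 when the factor is uninformative about the
outcome's level, up to 0.5 under perfect separation — and the normalized
scores form the second weight group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import LCM, level_frequencies


@dataclass(frozen=True)
class RiditLevels:
    """Mid-rank RIDIT decomposition of an ordinal frequency vector."""

    frequency: np.ndarray      # per-level counts
    average: np.ndarray        # half the frequency (the "mid" of mid-rank)
    cumulative: np.ndarray     # counts strictly below each level
    midrank: np.ndarray        # cumulative + average
    ridit: np.ndarray          # midrank / total
    total: float


def level_ridits(frequencies) -> RiditLevels:
    """Mid-rank ridits of an ordinal frequency vector.

    ridit_l = (sum of counts below level l + frequency_l / 2) / total.
    """
    freq = np.asarray(frequencies, dtype=float)
    if (freq < 0).any():
        raise ValueError("frequencies must be nonnegative")
    total = freq.sum()
    if total <= 0:
        raise ValueError("total frequency must be positive")
    average = freq / 2.0
    cumulative = np.concatenate([[0.0], np.cumsum(freq)[:-1]])
    midrank = cumulative + average
    return RiditLevels(
        frequency=freq,
        average=average,
        cumulative=cumulative,
        midrank=midrank,
        ridit=midrank / total,
        total=float(total),
    )


def variable_ridit_score(
    levels: pd.DataFrame,
    variable: str,
    reference: RiditLevels,
    outcome: str = LCM,
) -> float:
    """RIDIT discrepancy score of one risk factor against the outcome.

    Each observation receives the ridit of its outcome level under
    ``reference``.  Within each level group of ``variable`` the mean outcome
    ridit is computed; the score is sum_g (n_g / n) * |mean_g - 0.5|,
    in [0, 0.5].  Empty level groups are skipped.
    """
    if variable not in levels.columns:
        raise KeyError(f"unknown variable: {variable!r}")
    if outcome not in levels.columns:
        raise KeyError(f"outcome column {outcome!r} not in levels")
    out_level = levels[outcome].to_numpy(dtype=int)
    var_level = levels[variable].to_numpy(dtype=int)
    obs_ridit = reference.ridit[out_level - 1]
    n = len(levels)
    score = 0.0
    for g in np.unique(var_level):
        mask = var_level == g
        score += mask.sum() / n * abs(obs_ridit[mask].mean() - 0.5)
    return float(score)


def ridit_weights(scores: pd.Series) -> pd.Series:
    """Normalize per-variable RIDIT scores into weight group A2."""
    scores = scores.astype(float)
    if len(scores) == 0:
        raise ValueError("no RIDIT scores given")
    if (scores < 0).any():
        raise ValueError("RIDIT scores must be nonnegative")
    total = scores.sum()
    if total == 0:
        raise ValueError("all RIDIT scores are zero: no information")
    return scores / total


def ridit_stage(
    levels: pd.DataFrame, outcome: str = LCM
) -> tuple[RiditLevels, pd.Series, pd.Series]:
    """Run the full RIDIT stage over every risk factor.

    The reference distribution is the outcome's pooled level frequencies.
    Returns (reference ridits, raw scores, weights).
    """
    reference = level_ridits(level_frequencies(levels, outcome))
    factors = [c for c in levels.columns if c != outcome]
    scores = pd.Series(
        {v: variable_ridit_score(levels, v, reference, outcome=outcome) for v in factors},
        name="ridit_score",
    )
    return reference, scores, ridit_weights(scores)
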