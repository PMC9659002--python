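"""Random-forest comparison stage.

An ensemble of Gini-impurity decision trees classifies the outcome (LCM)
risk level 1..5 from the 30 risk factors' own quintile levels, and ranks
the variables by normalized mean-impurity-decrease importance.  Tree
constraints follow the study design: maximum depth 5, at least 10 cases in
a parent node and 5 in a child; the train/test split is stratified on the
outcome level at a 663/1097 training fraction.

The ensemble itself is scikit-learn's ``RandomForestClassifier``; this
module fixes the configuration surface and reporting around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .ingest import LCM

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RfConfig:
    """Forest and split configuration (defaults mirror the study design)."""

    max_depth: int = 5
    min_parent: int = 10       # minimum cases in a node to split
    min_child: int = 5         # minimum cases in a leaf
    n_trees: int = 100
    train_fraction: float = 663 / 1097
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.min_child > self.min_parent:
            raise ValueError("min_child must not exceed min_parent")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class RfReport:
    """Test accuracy and importance ranking of the risk factors."""

    accuracy: float
    importances: pd.Series   # nonnegative, sums to 1
    ranking: tuple[str, ...]  # variables, most important first
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "importances": {v: float(w) for v, w in self.importances.items()},
            "ranking": list(self.ranking),
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def split(
    levels: pd.DataFrame, config: RfConfig, outcome: str = LCM
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split stratified on the outcome level.

    Reproducible from ``config.seed``; warns if any outcome class is absent
    from the training part.
    """
    if len(levels) < 10:
        raise ValueError("need at least 10 observations to split")
    if outcome not in levels.columns:
        raise KeyError(f"outcome column {outcome!r} not in levels")
    train, test = train_test_split(
        levels,
        train_size=config.train_fraction,
        stratify=levels[outcome],
        random_state=config.seed,
    )
    missing = set(levels[outcome].unique()) - set(train[outcome].unique())
    if missing:
        logger.warning("outcome class(es) %s absent from training data", missing)
    return train, test


def fit_and_report(
    train: pd.DataFrame,
    test: pd.DataFrame,
    config: RfConfig,
    outcome: str = LCM,
) -> RfReport:
    """Fit the forest on the training levels and report accuracy + importances.

    Importances are mean impurity decreases normalized to sum 1; the ranking
    breaks importance ties alphabetically for determinism.
    """
    if len(train) == 0:
        raise ValueError("training data is empty")
    features = [c for c in train.columns if c != outcome]
    y_train = train[outcome]
    if y_train.nunique() < 2:
        raise ValueError("training data contains a single outcome class")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_depth=config.max_depth,
        min_samples_split=config.min_parent,
        min_samples_leaf=config.min_child,
        random_state=config.seed,
    )
    forest.fit(train[features], y_train)
    accuracy = float(forest.score(test[features], test[outcome]))
    imp = np.asarray(forest.feature_importances_, dtype=float)
    if imp.sum() == 0:  # no split ever used a feature
        imp = np.full(len(features), 1.0 / len(features))
    imp = imp / imp.sum()
    importances = pd.Series(imp, index=features, name="importance")
    # deterministic tie-break: sort by (-importance, name)
    ranking = tuple(sorted(features, key=lambda v: (-importances[v], v)))
    return RfReport(
        accuracy=accuracy,
        importances=importances,
        ranking=ranking,
        n_train=len(train),
        n_test=len(test),
    )
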