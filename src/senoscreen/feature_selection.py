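"""Descriptor ranking by tree-ensemble impurity reduction, and PCA profiling.

Feature selection reduces the descriptor set before model training: a
random forest is fitted to the labelled table and features are ranked by
their mean decrease in Gini impurity across trees.  The PCA
explained-variance profile documents why only a modest reduction is
possible on descriptor data — the variance is spread over most components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FeatureRanking",
    "VarianceProfile",
    "impurity_importance",
    "select_by_importance",
    "pca_variance_profile",
]


@dataclass
class FeatureRanking:
    """Features ordered by decreasing mean Gini-impurity reduction."""

    feature_names: list[str]     # ranking order; ties broken by name
    importances: np.ndarray      # aligned with feature_names; sums to 1
    n_trees: int
    seed: int

    def to_frame(self, selected: set[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.feature_names,
                           "importance": self.importances})
        if selected is not None:
            df["selected"] = df["feature"].isin(selected)
        return df


def impurity_importance(X, y, feature_names=None, n_trees: int = 500,
                        seed: int = 0) -> FeatureRanking:
    """Rank features by mean decrease in Gini impurity over a forest.

    Deterministic given the seed.  Requires both classes present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("impurity importance needs both classes in y")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    feature_names = list(feature_names)
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    ).fit(X, y)
    imp = forest.feature_importances_
    order = sorted(range(len(feature_names)),
                   key=lambda i: (-imp[i], feature_names[i]))
    return FeatureRanking(
        feature_names=[feature_names[i] for i in order],
        importances=imp[order],
        n_trees=n_trees,
        seed=seed,
    )


def select_by_importance(ranking: FeatureRanking, policy: str, value=None) -> list[str]:
    """Select a feature subset from a ranking.

    Policies: ``top_k`` (value = k), ``above_mean`` (features with importance
    strictly greater than, or equal to, the mean — ties at the mean are
    kept), ``above_threshold`` (value = t, importance > t).  Returns names in
    ranking order; an empty selection raises.
    """
    imp = ranking.importances
    if policy == "top_k":
        if value is None or int(value) < 1:
            raise ValueError("top_k requires a positive k")
        names = ranking.feature_names[: int(value)]
    elif policy == "above_mean":
        m = imp.mean()
        names = [n for n, v in zip(ranking.feature_names, imp) if v >= m]
    elif policy == "above_threshold":
        if value is None:
            raise ValueError("above_threshold requires a threshold")
        names = [n for n, v in zip(ranking.feature_names, imp) if v > float(value)]
    else:
        raise ValueError(f"unknown selection policy: {policy}")
    if not names:
        raise ValueError(f"selection policy {policy} selected no features")
    return names


@dataclass
class VarianceProfile:
    """Per-component explained-variance ratios of a PCA."""

    ratios: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.ratios)

    def n_components_for(self, q: float) -> int:
        """Smallest number of components whose cumulative ratio reaches q."""
        if not (0 < q <= 1):
            raise ValueError("q must be in (0, 1]")
        cum = self.cumulative
        # guard the q=1 boundary against floating-point undershoot
        idx = np.searchsorted(cum, min(q, cum[-1]) - 1e-12)
        return int(idx) + 1


def pca_variance_profile(X) -> VarianceProfile:
    """Explained-variance profile from the eigendecomposition of cov(X)."""
    X = np.asarray(X, dtype=float)
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    pca.fit(X)
    return VarianceProfile(ratios=pca.explained_variance_ratio_)
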