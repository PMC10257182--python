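"""Virtual screening: score a library, normalise scores, pick outlier hits.

A selective model produces a long-tailed score distribution over a diverse
library: the bulk of compounds sit at near-zero probability and a handful
of extreme outliers stand many standard deviations above it.  Hits are
selected by strict probability and/or z-score cutoffs, then related back to
the training chemical space with continuous Tanimoto distances and a 2-D
t-SNE embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .diversity import tanimoto_distance_matrix
from .featurisation import DescriptorTable, minmax_rescale
from .model_harness import TrainedModel

__all__ = [
    "ScoreTable",
    "HitList",
    "score_library",
    "zscore_scores",
    "select_hits",
    "embed_2d",
    "nearest_training_distances",
]


@dataclass
class ScoreTable:
    """Per-compound prediction scores with ranks and optional z-scores.

    Ranks are descending in P with ties broken by compound id, so the
    ordering is stable and a permutation of 1..n.
    """

    frame: pd.DataFrame  # columns: id, score [, z, rank]

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True)
        if "rank" not in df.columns:
            order = df.sort_values(["score", "id"], ascending=[False, True]).index
            ranks = pd.Series(index=order, data=np.arange(1, len(df) + 1))
            df["rank"] = ranks.sort_index().to_numpy()
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class HitList:
    """Selected outlier compounds and the policy that selected them."""

    frame: pd.DataFrame          # subset of the score table, P-descending
    policy: dict                 # {"p_min": ..., "z_min": ...} (set criteria only)
    library_size: int

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].tolist()

    @property
    def min_hit_z(self) -> float:
        """z-score of the lowest-scoring hit (the implied outlier cutoff)."""
        return float(self.frame["z"].min()) if len(self.frame) else float("nan")


def score_library(model: TrainedModel, dt: DescriptorTable) -> ScoreTable:
    """Score every library compound with the trained model's probability."""
    missing = [f for f in model.feature_names if f not in dt.feature_names]
    if missing:
        raise ValueError(f"library is missing model features: {missing}")
    sub = dt.subset_features(model.feature_names)
    scores = model.scores(sub.values)
    return ScoreTable(pd.DataFrame({"id": sub.ids, "score": scores}))


def zscore_scores(st: ScoreTable) -> ScoreTable:
    """Standardise prediction scores over the library (sample SD).

    With thousands of compounds the sample/population distinction is
    negligible; the sample convention (n−1 divisor) is fixed here, matching
    the descriptor z-scoring elsewhere in the package.
    """
    s = st.frame["score"].to_numpy(dtype=float)
    if len(np.unique(s)) < 2:
        raise ValueError("all scores identical; z-scores undefined (degenerate model)")
    sd = s.std(ddof=1)
    df = st.frame.copy()
    df["z"] = (s - s.mean()) / sd
    return ScoreTable(df)


def select_hits(st: ScoreTable, p_min: float | None = None,
                z_min: float | None = None) -> HitList:
    """Select compounds exceeding ALL set cutoffs (strict inequalities).

    Raising either cutoff can only remove hits (monotonicity).  An empty
    hit list is a valid outcome.
    """
    if p_min is None and z_min is None:
        raise ValueError("set at least one of p_min, z_min")
    df = st.frame
    mask = np.ones(len(df), dtype=bool)
    policy = {}
    if p_min is not None:
        mask &= df["score"].to_numpy() > p_min
        policy["p_min"] = float(p_min)
    if z_min is not None:
        if "z" not in df.columns:
            raise ValueError("score table has no z column; call zscore_scores first")
        mask &= df["z"].to_numpy() > z_min
        policy["z_min"] = float(z_min)
    hits = df[mask].sort_values(["score", "id"], ascending=[False, True])
    return HitList(frame=hits.reset_index(drop=True), policy=policy,
                   library_size=len(df))


def embed_2d(X, groups=None, perplexity: float = 50, learning_rate: float = 200,
             max_iter: int = 1200, seed: int = 0) -> pd.DataFrame:
    """2-D t-SNE embedding of combined training + screening descriptors.

    Returns a frame with columns x, y and (if given) a per-row ``group``
    tag (training / screening / hit) for overlap reporting.  Deterministic
    given the seed.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs more than 3x perplexity rows "
            f"({X.shape[0]} <= {3 * perplexity:g}); lower the perplexity"
        )
    ts = TSNE(n_components=2, perplexity=perplexity, learning_rate=learning_rate,
              max_iter=max_iter, random_state=seed, init="pca")
    coords = ts.fit_transform(X)
    df = pd.DataFrame(coords, columns=["x", "y"])
    if groups is not None:
        df["group"] = list(groups)
    return df


def nearest_training_distances(hits: DescriptorTable,
                               training: DescriptorTable) -> pd.DataFrame:
    """Continuous Tanimoto distances from each hit to every training positive.

    Both tables are min-max rescaled jointly (per feature, over the pooled
    rows) so the Tanimoto form sees non-negative coordinates.  Returns one
    row per hit with min/median distance and the fraction of training
    compounds at distance ≥ 0.99 ("maximally distant").
    """
    if len(training.ids) == 0:
        raise ValueError("empty training set")
    shared = [f for f in hits.feature_names if f in training.feature_names]
    if not shared:
        raise ValueError("hit and training tables share no features")
    H = hits.subset_features(shared).values
    T = training.subset_features(shared).values
    pooled = minmax_rescale(np.vstack([H, T]))
    Hs, Ts = pooled[: len(H)], pooled[len(H):]
    D = tanimoto_distance_matrix(Hs, Ts)
    return pd.DataFrame({
        "id": hits.ids,
        "min_distance": D.min(axis=1),
        "median_distance": np.median(D, axis=1),
        "frac_maximally_distant": (D >= 0.99).mean(axis=1),
    })
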