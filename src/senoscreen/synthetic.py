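"""Synthetic compound libraries with the statistical structure of a senolytic screen.

Real training data for senolytic discovery is severely imbalanced (tens of
positives against thousands of library negatives), the positives come from a
handful of heterogeneous literature sources with at best weak chemical
clustering, and descriptor spaces are high-dimensional with correlated
columns.  This module generates descriptor tables directly in feature space
with exactly that structure, so every downstream stage — QC, feature
selection, model training, screening — is testable end to end without any
external download.

Generative model
----------------
Negatives are drawn from a zero-mean Gaussian with block covariance
(blocks of 10 features, equicorrelated at ``feature_correlation``), which
keeps the intrinsic dimensionality high (a PCA needs most components to
explain the variance, as observed on real descriptor matrices).  Positives
share that covariance but their mean is shifted by ``effect_size`` (in
marginal-SD units, with random signs) on ``n_informative`` features, plus a
per-source offset with SD ``source_separation`` on those same features.
Screening libraries mix background compounds with a small planted-active
fraction drawn from the positive model; the plant flags are hidden truth
used only by recovery tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .featurisation import CompoundTable, DescriptorTable, LABEL_UNKNOWN

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "LabelledDescriptorTable",
    "generate_training_table",
    "generate_screening_table",
    "toy_smiles_fixture",
]

_BLOCK = 10  # features per correlated block


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic libraries.

    Defaults mirror the assembled senolytic training set: 2465 background
    negatives plus 58 positives (2.3% prevalence) from 15 literature
    sources, 200 descriptors, and a 4340-compound screening library.
    """

    n_neg: int = 2465
    n_pos: int = 58
    n_features: int = 200
    n_sources: int = 15
    n_informative: int = 40
    effect_size: float = 1.0        # standardised mean shift of positives
    source_separation: float = 0.5  # SD of between-source mean offsets
    feature_correlation: float = 0.3  # within-block correlation
    screen_size: int = 4340
    screen_active_frac: float = 0.005
    label_noise: float = 0.0        # fraction of negatives flipped to 1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_neg": self.n_neg, "n_pos": self.n_pos,
            "n_features": self.n_features, "n_sources": self.n_sources,
            "n_informative": self.n_informative, "screen_size": self.screen_size,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not (0 <= self.feature_correlation < 1):
            raise ValueError("feature_correlation must be in [0, 1)")
        for name, v in (("screen_active_frac", self.screen_active_frac),
                        ("label_noise", self.label_noise)):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_pos > 0 and self.n_sources == 0:
            raise ValueError("n_pos > 0 requires n_sources >= 1")


@dataclass
class GroundTruth:
    """Generator-side truth retained for recovery tests.

    Never serialised into descriptor CSVs; travels in a sidecar only.
    """

    informative_idx: np.ndarray
    shift: np.ndarray            # class-level mean shift, length n_features
    source_means: np.ndarray     # (n_sources, n_features) total per-source means
    planted: np.ndarray | None = None  # screening-table hidden active flags

    def to_json(self, path) -> None:
        payload = {
            "informative_idx": self.informative_idx.tolist(),
            "shift": self.shift.tolist(),
            "source_means": self.source_means.tolist(),
            "planted": None if self.planted is None else self.planted.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class LabelledDescriptorTable:
    """A descriptor table plus labels, source tags and hidden ground truth."""

    descriptors: DescriptorTable
    labels: np.ndarray           # 0/1 (or LABEL_UNKNOWN for screening rows)
    sources: list[str]
    truth: GroundTruth

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def X(self) -> np.ndarray:
        return self.descriptors.values

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        df = self.descriptors.to_frame()
        df.insert(0, "label", self.labels)
        df.insert(1, "source", self.sources)
        return df

    def to_csv(self, path) -> None:
        """Write id, label, source + descriptors. Ground truth is NOT written
        here — it goes to a sidecar via ``truth.to_json`` so no training path
        can ever see it."""
        self.to_frame().to_csv(path)


def read_labelled_csv(path):
    """Read a labelled descriptor CSV back as (DescriptorTable, labels, sources)."""
    df = pd.read_csv(path, index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: labelled table needs a 'label' column")
    labels = df.pop("label").to_numpy(dtype=int)
    sources = df.pop("source").fillna("").astype(str).tolist() if "source" in df.columns \
        else [""] * len(df)
    dt = DescriptorTable(
        ids=[str(i) for i in df.index],
        feature_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )
    return dt, labels, sources


def _feature_names(n: int) -> list[str]:
    return [f"desc_{i:03d}" for i in range(n)]


def _block_noise(rng: np.random.Generator, n: int, d: int, rho: float) -> np.ndarray:
    """Zero-mean unit-variance draws, equicorrelated at rho within blocks of 10."""
    z = rng.standard_normal((n, d))
    if rho == 0:
        return z
    out = np.empty_like(z)
    for start in range(0, d, _BLOCK):
        stop = min(start + _BLOCK, d)
        common = rng.standard_normal((n, 1))
        out[:, start:stop] = np.sqrt(rho) * common + np.sqrt(1 - rho) * z[:, start:stop]
    return out


def _positive_model(cfg: SynthConfig, rng: np.random.Generator) -> GroundTruth:
    idx = rng.choice(cfg.n_features, size=cfg.n_informative, replace=False)
    idx.sort()
    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    shift = np.zeros(cfg.n_features)
    shift[idx] = cfg.effect_size * signs
    source_means = np.tile(shift, (max(cfg.n_sources, 1), 1))
    if cfg.n_sources and cfg.source_separation > 0:
        offsets = rng.standard_normal((cfg.n_sources, cfg.n_informative))
        source_means[:, idx] += cfg.source_separation * offsets
    return GroundTruth(informative_idx=idx, shift=shift, source_means=source_means)


def _source_counts(n_pos: int, n_sources: int) -> np.ndarray:
    """Heterogeneous split of positives across sources (roughly geometric)."""
    if n_pos == 0:
        return np.zeros(n_sources, dtype=int)
    weights = np.array([0.85**i for i in range(n_sources)])
    counts = np.floor(n_pos * weights / weights.sum()).astype(int)
    counts[: n_pos - counts.sum()] += 1  # hand out the remainder, largest first
    # every source with a positive allocation keeps >= 1 compound
    while (counts == 0).any() and counts.max() > 1:
        counts[np.argmax(counts)] -= 1
        counts[np.argmin(counts)] += 1
    return counts


def generate_training_table(cfg: SynthConfig) -> LabelledDescriptorTable:
    """Generate an imbalanced labelled training library.

    Deterministic given ``cfg`` (including the seed): identical configs give
    bit-identical tables.
    """
    ss = np.random.SeedSequence([cfg.seed, 101])
    rng = np.random.default_rng(ss)
    truth = _positive_model(cfg, rng)

    X_neg = _block_noise(rng, cfg.n_neg, cfg.n_features, cfg.feature_correlation)
    counts = _source_counts(cfg.n_pos, cfg.n_sources) if cfg.n_pos else np.array([], int)
    pos_rows, pos_sources = [], []
    for s, c in enumerate(counts):
        if c == 0:
            continue
        noise = _block_noise(rng, int(c), cfg.n_features, cfg.feature_correlation)
        pos_rows.append(truth.source_means[s] + noise)
        pos_sources += [f"source_{s:02d}"] * int(c)
    X_pos = np.vstack(pos_rows) if pos_rows else np.empty((0, cfg.n_features))

    X = np.vstack([X_neg, X_pos])
    labels = np.concatenate([np.zeros(cfg.n_neg, int), np.ones(cfg.n_pos, int)])
    sources = [""] * cfg.n_neg + pos_sources

    if cfg.label_noise > 0 and cfg.n_neg > 0:
        n_flip = int(round(cfg.label_noise * cfg.n_neg))
        flip = rng.choice(cfg.n_neg, size=n_flip, replace=False)
        labels[flip] = 1

    ids = [f"train_{i:05d}" for i in range(len(labels))]
    dt = DescriptorTable(ids=ids, feature_names=_feature_names(cfg.n_features),
                         values=X, provenance="synthetic")
    return LabelledDescriptorTable(dt, labels, sources, truth)


def generate_screening_table(cfg: SynthConfig) -> LabelledDescriptorTable:
    """Generate a screening library with a hidden planted-active fraction.

    Rows are drawn from an independent random substream of the same
    generative model, so no screening compound duplicates a training row.
    Planted actives reuse the training table's positive model (same config,
    same hidden source means); the plant flag lives in ``truth.planted`` and
    table labels are all ``LABEL_UNKNOWN``.
    """
    truth = _positive_model(cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 101])))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))

    n_active = int(round(cfg.screen_size * cfg.screen_active_frac))
    if cfg.screen_active_frac > 0 and n_active == 0:
        warnings.warn("screen_active_frac too small for screen_size; 0 planted actives")
    n_bg = cfg.screen_size - n_active

    X_bg = _block_noise(rng, n_bg, cfg.n_features, cfg.feature_correlation)
    if n_active:
        src = rng.integers(0, max(cfg.n_sources, 1), size=n_active)
        noise = _block_noise(rng, n_active, cfg.n_features, cfg.feature_correlation)
        X_act = truth.source_means[src] + noise
        X = np.vstack([X_bg, X_act])
    else:
        X = X_bg
    planted = np.concatenate([np.zeros(n_bg, int), np.ones(n_active, int)])

    perm = rng.permutation(cfg.screen_size)
    X, planted = X[perm], planted[perm]

    truth.planted = planted
    ids = [f"screen_{i:05d}" for i in range(cfg.screen_size)]
    dt = DescriptorTable(ids=ids, feature_names=_feature_names(cfg.n_features),
                         values=X, provenance="synthetic")
    labels = np.full(cfg.screen_size, LABEL_UNKNOWN, dtype=int)
    return LabelledDescriptorTable(dt, labels, [""] * cfg.screen_size, truth)


_TOY_SMILES = [
    # (id, SMILES, label, source) — small, widely known structures
    ("methane", "C", 0, ""),
    ("ethanol", "CCO", 0, ""),
    ("acetic_acid", "CC(=O)O", 0, ""),
    ("benzene", "c1ccccc1", 0, ""),
    ("toluene", "Cc1ccccc1", 0, ""),
    ("phenol", "Oc1ccccc1", 0, ""),
    ("aniline", "Nc1ccccc1", 0, ""),
    ("pyridine", "c1ccncc1", 0, ""),
    ("furan", "c1ccoc1", 0, ""),
    ("thiophene", "c1ccsc1", 0, ""),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", 0, ""),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 0, ""),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 0, ""),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", 0, ""),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1", 0, ""),
    ("glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O", 0, ""),
    ("glycine", "NCC(=O)O", 0, ""),
    ("urea", "NC(N)=O", 0, ""),
    ("quercetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12", 1, "flavonoid"),
    ("fisetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)ccc12", 1, "flavonoid"),
    ("apigenin", "O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12", 1, "flavonoid"),
    ("naphthalene", "c1ccc2ccccc2c1", 0, ""),
    ("cyclohexane", "C1CCCCC1", 0, ""),
    ("dmso", "CS(C)=O", 0, ""),
]


def toy_smiles_fixture() -> CompoundTable:
    """A fixed table of small valid SMILES for featurisation tests.

    Identical on every call; every structure parses under the chemistry
    toolkit.  The three flavonols labelled positive stand in for known
    senolytics of the flavonoid family.
    """
    df = pd.DataFrame(_TOY_SMILES, columns=["id", "smiles", "label", "source"])
    return CompoundTable(df)
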