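"""Compound tables, physicochemical descriptor computation and normalisation.

Compounds enter the pipeline as SMILES strings with an optional binary
senolytic label and a free-text provenance ("source") tag.  Featurisation
maps each structure to a vector of continuous physicochemical descriptors
(molecular weight, partial charges, connectivity/shape indices, ...) through
a pluggable provider, so the rest of the pipeline never touches chemistry
directly.  Two providers ship with the package: the RDKit descriptor set,
and a "precomputed" provider that reads descriptor CSVs — the latter lets
every downstream stage run without a chemistry toolkit installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundTable",
    "DescriptorTable",
    "ZScoreParams",
    "read_compound_table",
    "write_compound_table",
    "DescriptorProvider",
    "RDKitDescriptorProvider",
    "PrecomputedDescriptorProvider",
    "compute_descriptors",
    "sanitise_descriptors",
    "zscore_fit",
    "zscore_apply",
    "zscore_inverse",
    "minmax_rescale",
]

LABEL_UNKNOWN = -1

_COMPOUND_COLUMNS = ["id", "smiles", "label", "source"]


@dataclass
class CompoundTable:
    """Identified chemical structures with labels and provenance.

    ``label`` is 1 (senolytic), 0 (assumed non-senolytic) or ``LABEL_UNKNOWN``
    for unlabelled screening compounds.  Compound ids are unique.
    """

    frame: pd.DataFrame  # columns: id, smiles, label, source

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _COMPOUND_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"compound table missing columns: {missing}")
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate compound ids: {sorted(set(dup))}")
        if (df["smiles"].astype(str).str.len() == 0).any():
            raise ValueError("empty SMILES string in compound table")
        self.frame = df[_COMPOUND_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].tolist()

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundTable):
            return NotImplemented
        return self.frame.equals(other.frame)


def read_compound_table(path) -> CompoundTable:
    """Read a compound CSV with columns id, smiles[, label][, source].

    Missing labels become ``LABEL_UNKNOWN``; a missing source column becomes
    the empty string.  Duplicate ids raise with the offending ids listed.
    """
    try:
        df = pd.read_csv(path, dtype={"id": str, "smiles": str, "source": str})
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed compound CSV {path}: {exc}") from exc
    if "id" not in df.columns or "smiles" not in df.columns:
        raise ValueError(f"{path}: compound CSV needs 'id' and 'smiles' columns")
    if "label" not in df.columns:
        df["label"] = LABEL_UNKNOWN
    df["label"] = df["label"].fillna(LABEL_UNKNOWN).astype(int)
    if "source" not in df.columns:
        df["source"] = ""
    df["source"] = df["source"].fillna("")
    return CompoundTable(df)


def write_compound_table(table: CompoundTable, path) -> None:
    table.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class ZScoreParams:
    """Per-feature mean and sample standard deviation used for z-scoring."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray  # sample SD (ddof=1); 0 marks a constant column
    constant_features: tuple[str, ...] = ()

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "constant_features": list(self.constant_features),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ZScoreParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            feature_names=tuple(payload["feature_names"]),
            mean=np.asarray(payload["mean"], dtype=float),
            sd=np.asarray(payload["sd"], dtype=float),
            constant_features=tuple(payload["constant_features"]),
        )


@dataclass
class DescriptorTable:
    """Compounds × named continuous descriptors.

    ``normalisation`` records whether values are raw or z-scored (and with
    which statistics), so screening libraries can be normalised with
    training-set parameters.  All joins downstream are by feature *name*.
    """

    ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # shape (n compounds, n features)
    normalisation: Literal["raw", "zscored"] = "raw"
    zscore_params: ZScoreParams | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.ids),
            len(self.feature_names),
        ):
            raise ValueError(
                f"descriptor matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.feature_names)} features"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.feature_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, provenance: str = "precomputed") -> "DescriptorTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            provenance=provenance,
        )

    def subset_features(self, names: Sequence[str]) -> "DescriptorTable":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return replace(self, feature_names=list(names), values=self.values[:, idx])


class DescriptorProvider:
    """Interface: a named, ordered descriptor list plus a per-SMILES vector."""

    name = "abstract"

    def descriptor_names(self) -> list[str]:
        raise NotImplementedError

    def vector(self, smiles: str) -> np.ndarray | None:
        """Descriptor vector for one SMILES, or None if it does not parse."""
        raise NotImplementedError


class RDKitDescriptorProvider(DescriptorProvider):
    """The chemistry toolkit's full physicochemical descriptor set (~200).

    Covers basic molecular properties (molecular weight, partial charges,
    valence electrons) and structural indices (Chi connectivity, E-state,
    Kappa shape).  Raises a helpful error if RDKit is not installed.
    """

    def __init__(self) -> None:
        try:
            from rdkit import Chem, RDLogger
            from rdkit.Chem import Descriptors
        except ImportError as exc:
            raise ImportError(
                "RDKit is not available; compute descriptors elsewhere and use "
                "PrecomputedDescriptorProvider / DescriptorTable.from_csv on the "
                "descriptor CSV instead"
            ) from exc
        RDLogger.DisableLog("rdApp.*")
        self._chem = Chem
        self._desc_list = list(Descriptors.descList)
        self.name = "rdkit"

    def descriptor_names(self) -> list[str]:
        return [name for name, _ in self._desc_list]

    def vector(self, smiles: str) -> np.ndarray | None:
        mol = self._chem.MolFromSmiles(smiles)
        if mol is None:
            return None
        out = np.empty(len(self._desc_list))
        for j, (_, fn) in enumerate(self._desc_list):
            try:
                out[j] = fn(mol)
            except Exception:
                out[j] = np.nan
        return out


class PrecomputedDescriptorProvider(DescriptorProvider):
    """Serve descriptor vectors from a precomputed table keyed by SMILES."""

    def __init__(self, table: pd.DataFrame):
        # index: SMILES, columns: descriptor names
        self._table = table
        self.name = "precomputed"

    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self._table.columns]

    def vector(self, smiles: str) -> np.ndarray | None:
        if smiles not in self._table.index:
            return None
        return self._table.loc[smiles].to_numpy(dtype=float)


def compute_descriptors(
    table: CompoundTable,
    provider: DescriptorProvider,
    on_excluded: Callable[[str, str], None] | None = None,
) -> DescriptorTable:
    """Featurise every compound; unparseable SMILES are excluded and reported.

    Featurisation is a pure function of the SMILES string, so duplicate
    structures receive identical rows and permuting the input permutes the
    output.  ``on_excluded(compound_id, smiles)`` is called per exclusion.
    """
    names = provider.descriptor_names()
    rows, ids, excluded = [], [], []
    for rec in table.frame.itertuples(index=False):
        vec = provider.vector(rec.smiles)
        if vec is None:
            excluded.append(rec.id)
            if on_excluded is not None:
                on_excluded(rec.id, rec.smiles)
            continue
        rows.append(vec)
        ids.append(rec.id)
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    return DescriptorTable(
        ids=ids,
        feature_names=list(names),
        values=values,
        normalisation="raw",
        provenance=provider.name,
    )


def sanitise_descriptors(
    dt: DescriptorTable,
    policy: Literal["drop_feature", "drop_compound", "impute_median"] = "drop_feature",
) -> tuple[DescriptorTable, dict]:
    """Remove or impute non-finite descriptor values.

    Policies: ``drop_feature`` removes any column containing a non-finite
    entry (default — keeps the compound set intact), ``drop_compound``
    removes the offending rows, ``impute_median`` replaces each non-finite
    entry with its column's finite median.  Returns the cleaned table and a
    report of the actions taken.
    """
    bad = ~np.isfinite(dt.values)
    report: dict = {"policy": policy, "n_nonfinite": int(bad.sum()),
                    "dropped_features": [], "dropped_compounds": [], "imputed": 0}
    if not bad.any():
        return dt, report
    if policy == "drop_feature":
        keep = ~bad.any(axis=0)
        if not keep.any():
            raise ValueError("sanitise_descriptors: every feature would be dropped")
        report["dropped_features"] = [n for n, k in zip(dt.feature_names, keep) if not k]
        out = replace(
            dt,
            feature_names=[n for n, k in zip(dt.feature_names, keep) if k],
            values=dt.values[:, keep],
        )
    elif policy == "drop_compound":
        keep = ~bad.any(axis=1)
        report["dropped_compounds"] = [i for i, k in zip(dt.ids, keep) if not k]
        out = replace(dt, ids=[i for i, k in zip(dt.ids, keep) if k],
                      values=dt.values[keep])
    elif policy == "impute_median":
        values = dt.values.copy()
        for j in range(values.shape[1]):
            col_bad = bad[:, j]
            if col_bad.any():
                finite = values[~col_bad, j]
                med = float(np.median(finite)) if finite.size else 0.0
                values[col_bad, j] = med
                report["imputed"] += int(col_bad.sum())
        out = replace(dt, values=values)
    else:
        raise ValueError(f"unknown sanitisation policy: {policy}")
    return out, report


def zscore_fit(dt: DescriptorTable) -> ZScoreParams:
    """Fit per-feature mean and sample SD (ddof=1) on a raw table.

    Constant columns (SD = 0) are flagged; they map to 0 on application.
    """
    if dt.normalisation != "raw":
        raise ValueError("zscore_fit expects a raw descriptor table")
    mean = dt.values.mean(axis=0)
    sd = dt.values.std(axis=0, ddof=1) if len(dt.ids) > 1 else np.zeros(len(dt.feature_names))
    constant = tuple(n for n, s in zip(dt.feature_names, sd) if s == 0)
    return ZScoreParams(tuple(dt.feature_names), mean, sd, constant)


def zscore_apply(dt: DescriptorTable, params: ZScoreParams) -> DescriptorTable:
    """Apply z-scoring with previously fitted statistics (by feature name)."""
    if tuple(dt.feature_names) != params.feature_names:
        raise ValueError(
            "feature names of table and z-score parameters do not match"
        )
    safe_sd = np.where(params.sd == 0, 1.0, params.sd)
    values = (dt.values - params.mean) / safe_sd
    values[:, params.sd == 0] = 0.0
    return replace(dt, values=values, normalisation="zscored", zscore_params=params)


def zscore_inverse(dt: DescriptorTable) -> DescriptorTable:
    """Undo z-scoring; constant columns return to their fitted mean."""
    if dt.normalisation != "zscored" or dt.zscore_params is None:
        raise ValueError("table is not z-scored")
    p = dt.zscore_params
    safe_sd = np.where(p.sd == 0, 1.0, p.sd)
    values = dt.values * safe_sd + p.mean
    const = np.asarray(p.sd) == 0
    values[:, const] = np.asarray(p.mean)[const]
    return replace(dt, values=values, normalisation="raw", zscore_params=None)


def minmax_rescale(X: np.ndarray) -> np.ndarray:
    """Rescale each column to [0, 1]; constant columns map to 0.

    Used before continuous Tanimoto computations, which assume non-negative
    coordinates.
    """
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    safe = np.where(rng == 0, 1.0, rng)
    out = (X - lo) / safe
    out[:, rng == 0] = 0.0
    return out
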