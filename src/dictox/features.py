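"""Feature-space construction.

Every model input is a :class:`FeatureMatrix`: a named numeric matrix
over compound match keys, tagged with the feature space it represents
(Morgan fingerprints, 2-D physicochemical descriptors, one-hot MOA /
target annotations, Cmax columns, or aggregated omics profiles).
Also provides Tanimoto similarity and the similarity-conditional v-NN
profile imputation used when a training compound lacks an omics
profile: the imputed profile is the elementwise median over all
library compounds more similar than a Tanimoto cutoff (0.70), with
held-out test compounds excluded from the neighbor pool to avoid
information leakage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .chemstd import StandardizationError

__all__ = [
    "FeatureMatrix",
    "DROPPED",
    "structural_fingerprint",
    "tanimoto",
    "physchem_descriptors",
    "physchem_matrix",
    "onehot_annotations",
    "variance_filter",
    "aggregate_profiles",
    "vnn_impute",
]

SPACE_TAGS = (
    "structure",
    "physchem",
    "moa",
    "targets",
    "cmax_total",
    "cmax_unbound",
    "omics_morphology",
    "omics_expression",
    "omics_ontology",
    "composite",
)

#: Sentinel returned by :func:`vnn_impute` when no neighbor qualifies.
DROPPED = object()

_N_BITS = 2048
_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_N_BITS)


@dataclass
class FeatureMatrix:
    """A named numeric feature matrix over compound keys."""

    space_tag: str
    data: pd.DataFrame  # index = keys, columns = feature names

    def __post_init__(self) -> None:
        if self.space_tag not in SPACE_TAGS:
            raise ValueError(f"unknown space_tag {self.space_tag!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate compound keys in feature matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature names in feature matrix")

    @property
    def keys(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV (first column `key`) + JSON sidecar."""
        path = Path(path)
        self.data.rename_axis("key").to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"space_tag": self.space_tag, "feature_names": self.feature_names},
                indent=1,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        data = pd.read_csv(path, index_col="key")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(space_tag=meta["space_tag"], data=data)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"invalid SMILES: {smiles!r}")
    return mol


def structural_fingerprint(std_smiles: str) -> np.ndarray:
    """2048-bit Morgan (ECFP4-like, radius 2) fingerprint."""
    return _FP_GEN.GetFingerprintAsNumPy(_mol(std_smiles)).astype(np.uint8)


def fingerprint_matrix(smiles_by_key: dict[str, str]) -> FeatureMatrix:
    """Structure feature space: one fingerprint row per compound."""
    rows = {k: structural_fingerprint(s) for k, s in smiles_by_key.items()}
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.columns = [f"bit_{i}" for i in range(_N_BITS)]
    return FeatureMatrix("structure", data)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary vectors.

    Defined as 0.0 when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def physchem_descriptors(std_smiles: str) -> pd.Series:
    """All RDKit 2-D physicochemical descriptors for one compound.

    Descriptors that raise are recorded as NaN; dataset-wide column
    handling (drop / clip) happens in :func:`physchem_matrix`.
    """
    mol = _mol(std_smiles)
    values = {}
    for name, fn in Descriptors.descList:
        try:
            values[name] = float(fn(mol))
        except Exception:
            values[name] = math.nan
    return pd.Series(values)


def physchem_matrix(smiles_by_key: dict[str, str]) -> FeatureMatrix:
    """Physicochemical feature space with the dataset-wide NaN policy.

    Columns that fail to compute (NaN) on any compound are dropped;
    residual infinities are clipped to the column's finite extremes,
    keeping the matrix fully finite and deterministic.
    """
    rows = {k: physchem_descriptors(s) for k, s in smiles_by_key.items()}
    data = pd.DataFrame.from_dict(rows, orient="index")
    data = data.loc[:, ~data.isna().any(axis=0)]
    for col in data.columns[np.isinf(data).any(axis=0)]:
        finite = data.loc[np.isfinite(data[col]), col]
        lo = finite.min() if len(finite) else 0.0
        hi = finite.max() if len(finite) else 0.0
        data[col] = data[col].clip(lo, hi)
    return FeatureMatrix("physchem", data)


def onehot_annotations(
    records: dict[str, set[str]], space_tag: str = "moa"
) -> FeatureMatrix:
    """One-hot encode annotation sets (MOA / known-target labels).

    One binary column per vocabulary item, columns in sorted vocabulary
    order; absence of an annotation is encoded as 0.
    """
    vocab = sorted(set().union(*records.values())) if records else []
    keys = list(records)
    arr = np.zeros((len(keys), len(vocab)), dtype=np.uint8)
    index = {term: j for j, term in enumerate(vocab)}
    for i, k in enumerate(keys):
        for term in records[k]:
            arr[i, index[term]] = 1
    return FeatureMatrix(space_tag, pd.DataFrame(arr, index=keys, columns=vocab))


def variance_filter(fm: FeatureMatrix, threshold: float = 0.001) -> FeatureMatrix:
    """Drop low-variance columns (population variance <= threshold)."""
    if fm.data.shape[0] == 0 or fm.data.shape[1] == 0:
        raise ValueError("cannot variance-filter an empty matrix")
    var = fm.data.to_numpy(dtype=float).var(axis=0, ddof=0)
    keep = fm.data.columns[var > threshold]
    return FeatureMatrix(fm.space_tag, fm.data[keep])


def aggregate_profiles(
    replicates: dict[str, list[pd.Series]], space_tag: str = "omics_morphology"
) -> FeatureMatrix:
    """Median profile per compound over its replicate profiles."""
    schema = None
    rows = {}
    for key, profiles in replicates.items():
        if not profiles:
            raise ValueError(f"no replicate profiles for {key!r}")
        for p in profiles:
            if schema is None:
                schema = list(p.index)
            elif list(p.index) != schema:
                raise ValueError(f"profile schema mismatch for {key!r}")
        rows[key] = pd.concat(profiles, axis=1).median(axis=1)
    return FeatureMatrix(space_tag, pd.DataFrame.from_dict(rows, orient="index"))


def vnn_impute(
    query_key: str,
    fingerprints: FeatureMatrix,
    profiles: FeatureMatrix,
    sim_threshold: float = 0.70,
    excluded_keys: set[str] | frozenset[str] = frozenset(),
):
    """Similarity-conditional (v-NN) profile imputation for one compound.

    If the query compound already has a profile it is returned as-is.
    Otherwise the profile is the elementwise median over all library
    compounds that have a profile, a Tanimoto similarity to the query
    strictly greater than ``sim_threshold``, and are not in
    ``excluded_keys`` (the held-out test set — excluded to prevent
    information leaking into training features).  With no qualifying
    neighbor, :data:`DROPPED` is returned and the caller discards the
    compound.
    """
    if query_key not in fingerprints.data.index:
        raise KeyError(f"no fingerprint for query compound {query_key!r}")
    if query_key in profiles.data.index:
        return profiles.data.loc[query_key]

    qfp = fingerprints.data.loc[query_key].to_numpy(dtype=bool)
    neighbors = []
    for key in profiles.data.index:
        if key == query_key or key in excluded_keys:
            continue
        if key not in fingerprints.data.index:
            continue
        sim = tanimoto(qfp, fingerprints.data.loc[key].to_numpy(dtype=bool))
        if sim > sim_threshold:
            neighbors.append(key)
    if not neighbors:
        return DROPPED
    return profiles.data.loc[neighbors].median(axis=0)
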