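"""Assemble labeled cardiotoxicity datasets.

The DICT concern categories (most / less / no / ambiguous) are
binarized for classification — most- and less-concern become label 1,
no-concern becomes 0, ambiguous compounds are excluded.  Duplicate
records sharing a match key collapse to one record, toxic if any
duplicate was toxic.  The DICTrank set can be enriched with SIDER
"cardiac disorders" compounds (DICTrank label wins on conflict), and
the two sources' agreement on shared compounds is quantified as a
concordance rate and an F1 score of SIDER against DICTrank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

__all__ = [
    "EXCLUDED",
    "binarize_concern",
    "collapse_duplicates",
    "enrich_with_sider",
    "concordance",
    "ConcordanceReport",
]

CONCERN_LEVELS = ("most", "less", "no", "ambiguous")

#: Marker returned for compounds that must be dropped before modeling.
EXCLUDED = "excluded"

_COLUMNS = ["key", "std_smiles", "concern", "label", "source"]


def binarize_concern(concern: str):
    """Map a DICT concern category to a binary toxicity label.

    most → 1, less → 1, no → 0; ambiguous compounds are not usable for
    binary classification and map to the :data:`EXCLUDED` marker.
    """
    if concern not in CONCERN_LEVELS:
        raise ValueError(
            f"unrecognized DICT concern category {concern!r}; "
            f"expected one of {CONCERN_LEVELS}"
        )
    if concern == "ambiguous":
        return EXCLUDED
    return 1 if concern in ("most", "less") else 0


def _check_dataset(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in ("key", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"{name} dataset missing columns: {missing}")
    if df["key"].isna().any() or (df["key"] == "").any():
        raise ValueError(f"{name} dataset has records with missing keys")


def collapse_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse records sharing a match key to one record per key.

    A compound is toxic if at least one duplicate record is toxic
    (label = max over duplicates).  The representative SMILES is the
    first by sorted ``std_smiles``, and the concern category is the
    most severe one observed (most > less > no > ambiguous > unknown),
    keeping concern and label consistent.
    """
    _check_dataset(records, "input")
    severity = {"most": 0, "less": 1, "no": 2, "ambiguous": 3, "unknown": 4}
    df = records.copy()
    if "concern" in df.columns:
        df["_severity"] = df["concern"].map(lambda c: severity.get(c, 99))
        df = df.sort_values(["key", "_severity"], kind="stable")
    aggregations = {"label": ("label", "max")}
    if "std_smiles" in df.columns:
        aggregations["std_smiles"] = ("std_smiles", "min")
    if "concern" in df.columns:
        aggregations["concern"] = ("concern", "first")
    if "source" in df.columns:
        aggregations["source"] = (
            "source",
            lambda s: s.iloc[0] if s.nunique() == 1 else "both",
        )
    collapsed = df.groupby("key", sort=True).agg(**aggregations).reset_index()
    cols = [c for c in _COLUMNS if c in collapsed.columns]
    return collapsed[cols]


def enrich_with_sider(
    dictrank: pd.DataFrame, sider: pd.DataFrame, mode: str = "all"
) -> pd.DataFrame:
    """Extend the DICTrank dataset with SIDER-only compounds.

    All DICTrank compounds are kept with their DICTrank labels;
    overlapping keys always retain the DICTrank label (DICTrank wins on
    conflict).  SIDER-only compounds are added according to ``mode``:
    ``toxic_only`` adds label-1 compounds, ``nontoxic_only`` label-0,
    ``all`` both.  SIDER-contributed records get concern ``unknown``
    (SIDER has no concern grades) and source ``SIDER``.
    """
    if mode not in ("toxic_only", "nontoxic_only", "all"):
        raise ValueError(f"unknown enrichment mode {mode!r}")
    _check_dataset(dictrank, "DICTrank")
    if len(sider):
        _check_dataset(sider, "SIDER")

    out = dictrank.copy()
    if "source" not in out.columns:
        out["source"] = "DICTrank"
    if len(sider) == 0:
        return out.reset_index(drop=True)

    dict_keys = set(out["key"])
    out.loc[out["key"].isin(set(sider["key"])), "source"] = "both"

    extra = sider[~sider["key"].isin(dict_keys)].copy()
    if mode == "toxic_only":
        extra = extra[extra["label"] == 1]
    elif mode == "nontoxic_only":
        extra = extra[extra["label"] == 0]
    extra["concern"] = "unknown"
    extra["source"] = "SIDER"
    cols = [c for c in _COLUMNS if c in out.columns]
    extra = extra.reindex(columns=cols)
    return pd.concat([out[cols], extra], ignore_index=True)


@dataclass
class ConcordanceReport:
    """Agreement between SIDER and DICTrank labels on shared compounds.

    ``percent_concordant`` is 100·(TP+TN)/n_overlap;
    ``f1_of_sider_vs_dictrank`` treats the SIDER label as the
    prediction and the DICTrank label as truth.
    """

    n_overlap: int
    percent_concordant: float
    f1_of_sider_vs_dictrank: float
    confusion: dict = field(default_factory=dict)


def concordance(dictrank: pd.DataFrame, sider: pd.DataFrame) -> ConcordanceReport:
    """Label concordance of the two sources on their shared compounds."""
    _check_dataset(dictrank, "DICTrank")
    _check_dataset(sider, "SIDER")
    merged = dictrank[["key", "label"]].merge(
        sider[["key", "label"]], on="key", suffixes=("_dict", "_sider")
    )
    n = len(merged)
    if n == 0:
        return ConcordanceReport(0, float("nan"), float("nan"), {})
    truth = merged["label_dict"].to_numpy(dtype=int)
    pred = merged["label_sider"].to_numpy(dtype=int)
    tp = int(np.sum((truth == 1) & (pred == 1)))
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    pct = 100.0 * (tp + tn) / n
    f1 = float(f1_score(truth, pred, zero_division=0.0))
    return ConcordanceReport(
        n_overlap=n,
        percent_concordant=pct,
        f1_of_sider_vs_dictrank=f1,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )
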