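"""Feature–label association statistics.

Ranks the features of any feature space by how strongly their
distribution differs across DICT concern categories or the binary
toxicity label.  Test selection follows the data type: categorical
(binary) features use the Pearson chi-squared test on the contingency
table; continuous features use the Kruskal–Wallis test across the
three concern groups, or the two-sided Mann–Whitney U test for
pairwise / binary contrasts, with Bonferroni correction over the
number of pairwise contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureMatrix

__all__ = [
    "AssociationResult",
    "chi_squared_assoc",
    "kruskal_wallis_assoc",
    "mann_whitney_assoc",
    "rank_features",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationResult:
    feature_name: str
    test: str  # chi_squared | kruskal_wallis | mann_whitney
    statistic: float
    p_value: float
    p_adjusted: float
    grouping: str  # three_concern | binary_label | pairwise


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def chi_squared_assoc(
    feature_values, groups, feature_name: str = "", m_comparisons: int = 1
) -> AssociationResult:
    """Pearson chi-squared test of independence, no continuity correction.

    Builds the observed r×c contingency table of feature level x group
    and tests independence with dof = (r-1)(c-1).
    """
    fv = pd.Series(feature_values).reset_index(drop=True)
    gr = pd.Series(groups).reset_index(drop=True)
    if len(fv) != len(gr):
        raise ValueError("feature and group vectors differ in length")
    mask = fv.notna() & gr.notna()
    table = pd.crosstab(fv[mask], gr[mask])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table for {feature_name!r}: "
            f"shape {table.shape} (needs >=2 levels on both margins)"
        )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError(f"empty margin in contingency table for {feature_name!r}")
    stat, p, _dof, _exp = sps.chi2_contingency(table.to_numpy(), correction=False)
    return AssociationResult(
        feature_name, "chi_squared", float(stat), float(p),
        _bonferroni(float(p), m_comparisons), "three_concern" if table.shape[1] > 2 else "binary_label",
    )


def kruskal_wallis_assoc(
    feature_values, groups, feature_name: str = "", m_comparisons: int = 1
) -> AssociationResult:
    """Kruskal–Wallis rank test across >=3 independent groups."""
    fv = np.asarray(feature_values, dtype=float)
    gr = pd.Series(groups).reset_index(drop=True)
    mask = np.isfinite(fv) & gr.notna().to_numpy()
    samples = [fv[mask][gr[mask] == g] for g in pd.unique(gr[mask])]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 3:
        raise ValueError(
            "Kruskal–Wallis needs >=3 groups; use mann_whitney_assoc for two"
        )
    if all(np.all(s == samples[0][0]) for s in samples):
        # identical constant values in every group: no evidence at all
        return AssociationResult(
            feature_name, "kruskal_wallis", 0.0, 1.0, 1.0, "three_concern"
        )
    stat, p = sps.kruskal(*samples)
    return AssociationResult(
        feature_name, "kruskal_wallis", float(stat), float(p),
        _bonferroni(float(p), m_comparisons), "three_concern",
    )


def mann_whitney_assoc(
    a, b, feature_name: str = "", m_comparisons: int = 1
) -> AssociationResult:
    """Two-sided Mann–Whitney U test with Bonferroni adjustment.

    ``m_comparisons`` is the number of pairwise contrasts performed
    (3 for the most/less/no pairs).  Exact null distribution when both
    samples have <=8 observations and no ties; mid-rank normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    try:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(min(1.0, res.pvalue))
    return AssociationResult(
        feature_name, "mann_whitney", float(res.statistic), p,
        _bonferroni(p, m_comparisons), "pairwise",
    )


def _is_categorical(col: np.ndarray) -> bool:
    finite = col[np.isfinite(col)]
    return len(np.unique(finite)) <= 2


def rank_features(
    fm: FeatureMatrix, labels: pd.DataFrame, scheme: str = "three_concern"
) -> list[AssociationResult]:
    """Rank all features of a matrix by association with the labels.

    scheme ``three_concern`` groups compounds by most/less/no concern;
    ``binary_label`` contrasts toxic vs nontoxic.  Binary feature
    columns use the chi-squared test; continuous columns use
    Kruskal–Wallis (three groups) or Mann–Whitney (binary).  Constant
    columns are skipped with a log message.  Results sorted ascending
    by p-value, ties broken by feature name.
    """
    if scheme not in ("three_concern", "binary_label"):
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    lab = labels.set_index("key") if "key" in labels.columns else labels
    shared = [k for k in fm.data.index if k in lab.index]
    if not shared:
        raise ValueError("no overlapping keys between features and labels")
    data = fm.data.loc[shared]
    if scheme == "three_concern":
        groups = lab.loc[shared, "concern"]
        keep = groups.isin(["most", "less", "no"])
    else:
        groups = lab.loc[shared, "label"]
        keep = groups.notna()
    data, groups = data[keep.to_numpy()], groups[keep.to_numpy()]

    results: list[AssociationResult] = []
    for name in data.columns:
        col = data[name].to_numpy(dtype=float)
        finite = col[np.isfinite(col)]
        if len(finite) == 0 or np.all(finite == finite[0]):
            log.info("skipping constant feature %r", name)
            continue
        try:
            if _is_categorical(col):
                res = chi_squared_assoc(col, groups, feature_name=name)
            elif scheme == "three_concern":
                res = kruskal_wallis_assoc(col, groups, feature_name=name)
            else:
                g = groups.to_numpy()
                res = mann_whitney_assoc(
                    col[g == 1], col[g == 0], feature_name=name
                )
        except ValueError as exc:
            log.info("skipping feature %r: %s", name, exc)
            continue
        results.append(res)
    return sorted(results, key=lambda r: (r.p_value, r.feature_name))


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Serialize association results to the standard tabular layout."""
    return pd.DataFrame(
        [
            (r.feature_name, r.test, r.statistic, r.p_value, r.p_adjusted, r.grouping)
            for r in results
        ],
        columns=["feature_name", "test", "statistic", "p_value", "p_adjusted", "grouping"],
    )
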