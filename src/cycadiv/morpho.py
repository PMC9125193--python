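"""Morphometric comparison of the two cycad species.

Continuous traits (leaf, leaflet, megasporophyll and seed measurements)
are compared between species with two-sided Mann-Whitney U tests at
alpha = 0.05, without multiple-testing correction (both configurable).
Significant leaflet traits feed an island-level agglomerative clustering
on standardized Euclidean distances, with the linkage method chosen by
the agglomerative coefficient.  Leaflet-margin recurvation is an ordinal
trait in classes 1-4 summarized as per-group proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

__all__ = [
    "mann_whitney",
    "TraitTestResult",
    "trait_tests",
    "trait_dendrogram",
    "recurvation_summary",
    "DEFAULT_CLUSTER_TRAITS",
    "agglomerative_coefficient",
]

#: the four significantly different leaflet traits used for clustering
DEFAULT_CLUSTER_TRAITS = ["leaflet_width", "leaflet_ratio", "basal_width", "spacing"]

LINKAGE_METHODS = {"upgma": "average", "complete": "complete",
                   "single": "single", "ward": "ward"}


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration p-value when n1 + n2 <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity
    correction.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class TraitTestResult:
    trait: str
    U: float
    p: float
    significant: bool
    n_CT: int
    mean_CT: float
    min_CT: float
    max_CT: float
    n_CR: int
    mean_CR: float
    min_CR: float
    max_CR: float


def trait_tests(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    alpha: float = 0.05,
    species_col: str = "species",
) -> pd.DataFrame:
    """Per-trait species comparison with pairwise deletion of missing
    cells; returns a table shaped like a trait-summary table
    (n / mean / min / max per species, U, p, significance flag)."""
    if traits is None:
        traits = [c for c in table.columns
                  if c not in (species_col, "region", "specimen", "recurvation_class",
                               "sclerotesta_groove", "sarcotesta_color")
                  and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for trait in traits:
        sub = table[[species_col, trait]].dropna()
        x = sub.loc[sub[species_col] == "CT", trait].to_numpy(float)
        y = sub.loc[sub[species_col] == "CR", trait].to_numpy(float)
        if x.size == 0 or y.size == 0:
            logger.warning("trait %s present in one species only; skipped", trait)
            continue
        U, p = mann_whitney(x, y)
        rows.append(TraitTestResult(
            trait=trait, U=U, p=p, significant=bool(p < alpha),
            n_CT=x.size, mean_CT=float(x.mean()), min_CT=float(x.min()), max_CT=float(x.max()),
            n_CR=y.size, mean_CR=float(y.mean()), min_CR=float(y.min()), max_CR=float(y.max()),
        ))
    return pd.DataFrame([vars(r) for r in rows]).set_index("trait")


# ---------------------------------------------------------------------------
# Agglomerative clustering of island trait means
# ---------------------------------------------------------------------------

def agglomerative_coefficient(Z: np.ndarray, n: int) -> float:
    """Mean over items of 1 - (height of the item's first merge) /
    (height of the final merge); 0 for degenerate all-identical data."""
    h_final = Z[-1, 2]
    if h_final == 0:
        return 0.0
    # first merge height per leaf: the lowest linkage step containing it
    first = np.full(n, np.nan)
    member = {i: [i] for i in range(n)}
    for step in range(Z.shape[0]):
        a, b, h, _ = Z[step]
        items = member.pop(int(a)) + member.pop(int(b))
        for it in items:
            if np.isnan(first[it]):
                first[it] = h
        member[n + step] = items
    return float(np.mean(1.0 - first / h_final))


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_h):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_h - 0.0:.6g}"
        children = ",".join(rec(c, node.dist) for c in (node.left, node.right))
        blen = parent_h - node.dist
        return f"({children}):{blen:.6g}"

    root = tree
    inner = ",".join(rec(c, root.dist) for c in (root.left, root.right))
    return f"({inner});"


def trait_dendrogram(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    group_col: str = "region",
    methods: dict[str, str] | None = None,
) -> dict:
    """Cluster group (island/region) trait means.

    Traits are averaged per group, standardized to zero mean and unit
    variance, embedded by Euclidean distance and clustered with the four
    agglomerative methods; the method with the largest agglomerative
    coefficient wins.  Constant trait columns are dropped with a warning
    before scaling.  Returns per-method coefficients, the winning method
    and its dendrogram in Newick form.
    """
    traits = traits or DEFAULT_CLUSTER_TRAITS
    methods = methods or LINKAGE_METHODS
    means = table.groupby(group_col)[traits].mean()
    if len(means) < 3:
        raise ValueError("need >= 3 groups to cluster")
    sd = means.std(ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        logger.warning("dropping constant trait columns before scaling: %s", const)
        means = means.drop(columns=const)
        sd = sd.drop(index=const)
    scaled = (means - means.mean()) / sd
    X = scaled.to_numpy(float)
    labels = list(means.index)
    coeffs = {}
    linkages = {}
    for name, scipy_name in methods.items():
        Z = hierarchy.linkage(X, method=scipy_name)
        linkages[name] = Z
        coeffs[name] = agglomerative_coefficient(Z, len(labels))
    best = max(sorted(coeffs), key=lambda m: coeffs[m])
    return {
        "coefficients": coeffs,
        "best_method": best,
        "newick": _linkage_to_newick(linkages[best], labels),
        "linkage": linkages[best],
        "labels": labels,
    }


def recurvation_summary(table: pd.DataFrame, by: str = "species") -> pd.DataFrame:
    """Per-group counts and proportions of recurvation classes 1-4."""
    if "recurvation_class" not in table.columns:
        raise ValueError("table has no recurvation_class column")
    sub = table.dropna(subset=["recurvation_class"])
    classes = [1, 2, 3, 4]
    rows = []
    for g, grp in sub.groupby(by):
        counts = grp["recurvation_class"].astype(int).value_counts()
        n = int(counts.sum())
        row = {"group": g, "n": n}
        for c in classes:
            row[f"count_{c}"] = int(counts.get(c, 0))
            row[f"prop_{c}"] = counts.get(c, 0) / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
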