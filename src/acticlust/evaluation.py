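"""Cluster-content evaluation against labelled ground truth.

Given per-window activity labels and cluster assignments this module builds
the class x cluster contingency table and derives from it

* the purity matrix — for each class, the percentage of its windows in each
  cluster (rows sum to 100), plus each cluster's share of total time;
* category capture — the percentage of a class falling inside a named group
  of clusters (e.g. the sedentary group A-E);
* average cluster purity (ACP), average event purity (AEP) and their
  combination ACEP:

      ACP  = (1/N) sum_i sum_j n_ij^2 / n_ci
      AEP  = (1/N) sum_j sum_i n_ij^2 / n_ej
      ACEP = ACP * AEP          (or sqrt(ACP * AEP) as an option)

* daily minutes per behaviour category and Bland-Altman agreement (bias and
  1.96*SD limits) of paired daily-minute measurements against a criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "contingency",
    "PurityMatrix",
    "purity_matrix",
    "CategoryMap",
    "category_capture",
    "acp",
    "aep",
    "acep",
    "daily_minutes",
    "BlandAltman",
    "bland_altman",
    "agreement_report",
    "feature_profile",
]


@dataclass
class ContingencyTable:
    """Window counts n_ij for cluster i (rows) x class j (columns)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size == 0:
            raise ValueError("empty contingency table")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def cluster_totals(self) -> pd.Series:  # n_ci
        return self.counts.sum(axis=1)

    @property
    def class_totals(self) -> pd.Series:  # n_ej
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:  # N
        return int(self.counts.to_numpy().sum())

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[0]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[1]


def contingency(labels: Sequence, clusters: Sequence) -> ContingencyTable:
    """Exact class x cluster window counts from paired per-window vectors."""
    labels = pd.Series(list(labels), name="class")
    clusters = pd.Series(list(clusters), name="cluster")
    if len(labels) != len(clusters):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(clusters)} clusters")
    if len(labels) == 0:
        raise ValueError("empty input")
    if labels.isna().any() or clusters.isna().any():
        raise ValueError("missing entries in labels or clusters")
    counts = pd.crosstab(clusters, labels)
    return ContingencyTable(counts=counts)


@dataclass
class PurityMatrix:
    """Row-percent table: classes (rows) x clusters (columns).

    ``values[c, k]`` is 100 * n_kc / n_ec — the percentage of class c's
    windows that fell in cluster k; ``cluster_share`` is each cluster's
    percentage of all windows.
    """

    values: pd.DataFrame
    cluster_share: pd.Series

    def round(self, decimals: int = 1) -> "PurityMatrix":
        """Report rendering at fixed precision (internals stay full precision)."""
        return PurityMatrix(self.values.round(decimals),
                            self.cluster_share.round(decimals))

    def to_frame(self) -> pd.DataFrame:
        """Report layout: cluster-share row on top, one row per class."""
        share = self.cluster_share.to_frame("% of total time").T
        return pd.concat([share, self.values])


def purity_matrix(ct: ContingencyTable) -> PurityMatrix:
    """Percentage of each class found within each cluster."""
    counts = ct.counts
    class_totals = ct.class_totals
    empty = class_totals[class_totals == 0].index.tolist()
    if empty:
        warnings.warn(f"classes with zero windows excluded: {empty}")
        counts = counts.drop(columns=empty)
        class_totals = class_totals.drop(empty)
    values = (100.0 * counts / class_totals).T  # classes x clusters
    share = 100.0 * ct.cluster_totals / ct.total
    return PurityMatrix(values=values, cluster_share=share)


class CategoryMap(dict):
    """Ordered mapping category name -> tuple of cluster identifiers.

    Categories must be disjoint; together they must cover the clusters they
    are checked against.
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]]):
        super().__init__({k: tuple(v) for k, v in mapping.items()})
        seen: set[str] = set()
        for cat, cl in self.items():
            dup = seen & set(cl)
            if dup:
                raise ValueError(f"cluster(s) {sorted(dup)} appear in more than "
                                 f"one category (latest: {cat})")
            seen |= set(cl)

    @property
    def clusters(self) -> set[str]:
        return {c for cl in self.values() for c in cl}

    def category_of(self, cluster: str) -> str:
        for cat, cl in self.items():
            if cluster in cl:
                return cat
        raise KeyError(f"cluster {cluster!r} not in any category")


def category_capture(pm: PurityMatrix, cm: CategoryMap) -> pd.DataFrame:
    """Percent of each class captured by each category of clusters.

    capture(class, category) = sum of the class's purity-row entries over
    the category's clusters.  Sums over a full cluster partition recover
    ~100 per class (up to rounding of the inputs).
    """
    unknown = cm.clusters - set(pm.values.columns)
    if unknown:
        raise ValueError(f"unknown cluster identifier(s): {sorted(unknown)}")
    out = {}
    for cat, cl in cm.items():
        out[cat] = pm.values[list(cl)].sum(axis=1)
    return pd.DataFrame(out)


def acp(ct: ContingencyTable) -> float:
    """Average cluster purity: 1 iff every cluster holds a single class."""
    n = ct.counts.to_numpy(dtype=float)
    n_ci = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_cluster = np.where(n_ci > 0, (n ** 2).sum(axis=1) / n_ci, 0.0)
    return float(per_cluster.sum() / ct.total)


def aep(ct: ContingencyTable) -> float:
    """Average event purity: 1 iff every class sits in a single cluster."""
    n = ct.counts.to_numpy(dtype=float)
    n_ej = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(n_ej > 0, (n ** 2).sum(axis=0) / n_ej, 0.0)
    return float(per_class.sum() / ct.total)


def acep(ct: ContingencyTable, combine: str = "product") -> float:
    """Combined cluster/event purity.

    ``combine="product"`` gives ACP*AEP (the default); ``"geometric"`` gives
    sqrt(ACP*AEP), the convention of the speaker-diarization literature the
    statistic descends from.  Both are monotone in the same inputs; the
    product is smaller whenever either purity is below 1.
    """
    prod = acp(ct) * aep(ct)
    if combine == "product":
        return prod
    if combine == "geometric":
        return float(np.sqrt(prod))
    raise ValueError(f"unknown combine {combine!r}")


def daily_minutes(clusters: Sequence[str], cm: CategoryMap,
                  window_seconds: float = 10.0) -> tuple[pd.Series, pd.Series]:
    """Minutes per category and percent of time per cluster for one recording.

    Returns ``(minutes_per_category, percent_per_cluster)``; minutes are
    window counts * window_seconds / 60.
    """
    clusters = pd.Series(list(clusters))
    counts = clusters.value_counts()
    minutes = pd.Series(
        {cat: counts.reindex(list(cl)).fillna(0).sum() * window_seconds / 60.0
         for cat, cl in cm.items()})
    percent = 100.0 * counts / len(clusters)
    return minutes, percent.sort_index()


@dataclass
class BlandAltman:
    """Agreement of paired measurements: bias and 1.96*SD limits half-width."""

    model_mean: float
    criterion_mean: float
    bias: float
    loa_half_width: float

    @property
    def limits(self) -> tuple[float, float]:
        return (self.bias - self.loa_half_width, self.bias + self.loa_half_width)


def bland_altman(model_minutes: Sequence[float],
                 criterion_minutes: Sequence[float]) -> BlandAltman:
    """Bias = mean(model - criterion); LoA half-width = 1.96 * sample SD."""
    m = np.asarray(model_minutes, dtype=float)
    c = np.asarray(criterion_minutes, dtype=float)
    if m.shape != c.shape:
        raise ValueError("paired vectors must have equal length")
    if m.size < 2:
        raise ValueError("need at least 2 paired measurements")
    diff = m - c
    return BlandAltman(
        model_mean=float(m.mean()),
        criterion_mean=float(c.mean()),
        bias=float(diff.mean()),
        loa_half_width=float(1.96 * diff.std(ddof=1)),
    )


def agreement_report(pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]]
                     ) -> pd.DataFrame:
    """Bland-Altman summary per category, one row each."""
    rows = {}
    for cat, (m, c) in pairs.items():
        ba = bland_altman(m, c)
        rows[cat] = {"model_mean": ba.model_mean,
                     "criterion_mean": ba.criterion_mean,
                     "bias": ba.bias, "loa_half_width": ba.loa_half_width}
    return pd.DataFrame(rows).T


def feature_profile(fm_raw: pd.DataFrame, assignments: Sequence,
                    feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-cluster mean of each feature on the raw (denormalized) scale.

    One row per cluster present in ``assignments``; used to compare what the
    clusters contain across independent samples.
    """
    cols = list(feature_names) if feature_names is not None else list(fm_raw.columns)
    missing = [c for c in cols if c not in fm_raw.columns]
    if missing:
        raise ValueError(f"features missing from matrix: {missing}")
    df = fm_raw[cols].copy()
    df["_cluster"] = list(assignments)
    return df.groupby("_cluster").mean().rename_axis("cluster")
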