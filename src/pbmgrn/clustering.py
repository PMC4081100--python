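"""Bi-dimensional clustering of the k-mer-by-TF specificity matrix.

The significant-word ES matrix is clustered in both dimensions to group
TFs with similar DNA specificity profiles, and per-TF core-word boxplot
("fingerprint") statistics summarize relative affinities at single-word
resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .patterns import canonical
from .pbm import CoreWord, EnrichmentTable, significant_patterns

__all__ = [
    "SpecificityMatrix",
    "ClusterAssignment",
    "FingerprintSummary",
    "build_specificity_matrix",
    "hierarchical_bicluster",
    "tf_fingerprint",
]

logger = logging.getLogger(__name__)


@dataclass
class SpecificityMatrix:
    """Significant patterns (rows) by TFs (columns) ES matrix."""

    values: pd.DataFrame

    @property
    def patterns(self) -> list[str]:
        return list(self.values.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterAssignment:
    """A flat partition plus the agglomerative tree that produced it.

    ``linkage_matrix`` is the scipy (n-1) x 4 merge table; ``labels`` maps
    each item id to its cluster label after cutting the tree.
    """

    labels: dict[str, int]
    linkage_matrix: np.ndarray
    item_order: list[str]

    def leaves(self) -> list[str]:
        return [self.item_order[i] for i in leaves_list(self.linkage_matrix)]

    def partition(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for item, lab in self.labels.items():
            out.setdefault(lab, set()).add(item)
        return out


@dataclass
class FingerprintSummary:
    """Boxplot statistics of per-core-word ES distributions for one TF.

    For each core word: median, 25th/75th percentiles, whisker ends at the
    last data point within 1.5 IQR of the box, and outliers beyond that.
    """

    tf_id: str
    groups: dict  # core text -> dict(median, q25, q75, lo, hi, outliers, n)


def build_specificity_matrix(
    table: EnrichmentTable, significant: set[str] | None = None
) -> SpecificityMatrix:
    """Restrict the ES table to the significant patterns.

    Sub-threshold cells of a kept row are retained as-is: a word enters the
    matrix if *any* TF reaches the threshold, and its scores for the other
    TFs are part of the profile.
    """
    if significant is None:
        significant = significant_patterns(table)
    if not significant:
        raise ValueError("empty significant pattern set")
    missing = significant - set(table.es.index)
    if missing:
        raise ValueError(f"significant patterns absent from table: {sorted(missing)[:5]}")
    values = table.es.loc[sorted(significant)].copy()
    return SpecificityMatrix(values=values)


def _distance(mat: np.ndarray, metric: str, axis_items: list[str]) -> np.ndarray:
    if metric == "correlation":
        sd = mat.std(axis=1)
        flat = [axis_items[i] for i in np.where(sd == 0)[0]]
        if flat:
            raise ValueError(
                f"constant profile under correlation metric: {flat[:5]}"
            )
        return pdist(mat, metric="correlation")
    return pdist(mat, metric=metric)


def hierarchical_bicluster(
    matrix: SpecificityMatrix,
    row_metric: str = "euclidean",
    col_metric: str = "correlation",
    method: str = "average",
    n_row_clusters: int = 2,
    n_col_clusters: int = 2,
) -> tuple[ClusterAssignment, ClusterAssignment]:
    """Agglomerative clustering of patterns (rows) and TFs (columns).

    Defaults follow common specificity-map practice: 1 - Pearson between TF
    profiles, Euclidean between pattern rows, average linkage.  Missing
    cells are imputed as ES 0 (absence of enrichment) for distance
    computation only.  Flat labels come from cutting each tree at the
    requested cluster count.
    """
    vals = matrix.values
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to bicluster")
    if vals.isna().any().any():
        n_missing = int(vals.isna().sum().sum())
        logger.info("imputing %d missing ES cells as 0 for clustering", n_missing)
        vals = vals.fillna(0.0)

    def cluster(mat: np.ndarray, items: list[str], metric: str, k: int) -> ClusterAssignment:
        dist = _distance(mat, metric, items)
        lm = linkage(dist, method=method)
        flat = fcluster(lm, t=k, criterion="maxclust")
        return ClusterAssignment(
            labels={item: int(lab) for item, lab in zip(items, flat)},
            linkage_matrix=lm,
            item_order=list(items),
        )

    rows = cluster(vals.to_numpy(), list(vals.index), row_metric, n_row_clusters)
    cols = cluster(vals.to_numpy().T, list(vals.columns), col_metric, n_col_clusters)
    return rows, cols


def _box_stats(values: np.ndarray) -> dict:
    """Matlab-style boxplot statistics with linear-interpolation quartiles."""
    v = np.sort(values.astype(float))
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q75 - q25
    in_lo = v[v >= q25 - 1.5 * iqr]
    in_hi = v[v <= q75 + 1.5 * iqr]
    lo = float(in_lo[0]) if in_lo.size else float(v[0])
    hi = float(in_hi[-1]) if in_hi.size else float(v[-1])
    outliers = v[(v < lo) | (v > hi)]
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "lo": lo,
        "hi": hi,
        "outliers": [float(x) for x in outliers],
        "n": int(v.size),
    }


def tf_fingerprint(
    table: EnrichmentTable,
    cores: list[CoreWord],
    tf_id: str,
    significant: set[str] | None = None,
) -> FingerprintSummary:
    """ES distribution statistics per core word for one TF.

    Each core word's group holds the ES values of the significant words
    containing it (containment by strand-symmetric submatch).  Core words
    contained in no scored significant word for this TF are omitted with a
    logged notice.
    """
    if not cores:
        raise ValueError("no core words given")
    if tf_id not in table.es.columns:
        raise ValueError(f"unknown TF {tf_id!r}")
    if significant is None:
        significant = significant_patterns(table)
    col = table.es[tf_id]
    groups: dict[str, dict] = {}
    for core in cores:
        members = [
            s for s in significant
            if _contains(s, core.pattern.text) and s in col.index and not np.isnan(col[s])
        ]
        if not members:
            logger.info("core %s: no scored significant word for %s; omitted",
                        core.pattern.text, tf_id)
            continue
        groups[core.pattern.text] = _box_stats(col[sorted(members)].to_numpy())
    return FingerprintSummary(tf_id=tf_id, groups=groups)


def _contains(host: str, core: str) -> bool:
    """Strand-symmetric containment of a possibly-gapped core in a pattern.

    Informative core positions must equal the host character; a core N
    position accepts any host character (including the host's own N).
    Host N positions only accept core N.
    """
    from .patterns import revcomp

    for cand in {core, revcomp(core)}:
        for s in range(0, len(host) - len(cand) + 1):
            ok = True
            for c, h in zip(cand, host[s : s + len(cand)]):
                if c == "N":
                    continue
                if h != c:
                    ok = False
                    break
            if ok:
                return True
    return False
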