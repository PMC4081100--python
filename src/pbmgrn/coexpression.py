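"""Gene-centric co-expression clusters and the hypergeometric target filter.

Tier-P target sets are refined by expression support: for each gene a
co-expression cluster (its top-100 Pearson neighbors in an expression
compendium) is tested for enrichment of the same TF's P targets with an
upper-tail hypergeometric test; genes whose cluster is enriched
(P < 0.05 in at least one compendium) are retained as P+COE targets.
The same hypergeometric machinery evaluates target sets against
differentially expressed (DE) gene sets and against each other, with fold
enrichment (k/n)/(K/N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .promoters import TargetSet

__all__ = [
    "ExpressionCompendium",
    "CoexpressionCluster",
    "HypergeomResult",
    "DESet",
    "coexpression_clusters",
    "hypergeom_pvalue",
    "filter_p_coe",
    "fold_enrichment",
    "de_recovery",
    "target_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionCompendium:
    """A genes-by-samples expression matrix with a compendium id."""

    compendium_id: str
    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.compendium_id}: duplicate gene ids")
        if self.values.shape[1] < 3:
            raise ValueError(f"{self.compendium_id}: need >= 3 samples")
        if self.values.isna().any().any():
            n = int(self.values.isna().sum().sum())
            logger.warning("%s: dropping %d genes with missing values",
                           self.compendium_id, int(self.values.isna().any(axis=1).sum()))
            self.values = self.values.dropna(axis=0)
            del n

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_tsv(cls, path, compendium_id: str | None = None) -> "ExpressionCompendium":
        df = pd.read_csv(path, sep="\t", index_col=0)
        cid = compendium_id if compendium_id is not None else str(path)
        return cls(compendium_id=cid, values=df)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6f")


@dataclass(frozen=True)
class CoexpressionCluster:
    """Top co-expressed neighbors of one focus gene in one compendium."""

    focus_gene: str
    compendium_id: str
    neighbors: tuple[str, ...]


@dataclass(frozen=True)
class HypergeomResult:
    """Upper-tail hypergeometric test of a k-of-n draw from K-of-N."""

    k: int
    n: int
    K: int
    N: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"need 0 <= k <= min(n, K); got k={self.k}, n={self.n}, K={self.K}")
        if not (self.k <= self.n <= self.N):
            raise ValueError(f"need k <= n <= N; got k={self.k}, n={self.n}, N={self.N}")
        if not (self.K <= self.N):
            raise ValueError(f"need K <= N; got K={self.K}, N={self.N}")
        if not (0.0 <= self.p <= 1.0 + 1e-12):
            raise ValueError(f"p out of [0, 1]: {self.p}")


@dataclass
class DESet:
    """Differentially expressed genes from a TF perturbation experiment."""

    tf_id: str
    genes: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# clusters


def coexpression_clusters(
    compendium: ExpressionCompendium,
    top_n: int = 100,
    focus_genes: list[str] | None = None,
) -> dict[str, CoexpressionCluster]:
    """Top-``top_n`` Pearson neighbors for each focus gene.

    Correlation is computed on raw expression values; zero-variance genes
    have no defined correlation and are excluded from neighbor candidacy
    (and, as focus genes, yield no cluster).  Ties in r are broken by gene
    id so clusters are deterministic.
    """
    vals = compendium.values
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    mat = vals.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    ok = sd > 0
    n_flat = int((~ok).sum())
    if n_flat:
        logger.info("%s: %d zero-variance genes excluded from co-expression",
                    compendium.compendium_id, n_flat)
    genes = np.array(vals.index)
    kept_genes = genes[ok]
    kept = mat[ok]
    # standardized rows -> correlation = dot / n_samples
    z = (kept - kept.mean(axis=1, keepdims=True)) / kept.std(axis=1, keepdims=True)
    nsamp = kept.shape[1]

    wanted = list(kept_genes) if focus_genes is None else [
        g for g in focus_genes if g in set(kept_genes)
    ]
    index_of = {g: i for i, g in enumerate(kept_genes)}
    out: dict[str, CoexpressionCluster] = {}
    for g in wanted:
        i = index_of[g]
        r = z @ z[i] / nsamp
        order = sorted(
            (j for j in range(len(kept_genes)) if j != i),
            key=lambda j: (-r[j], kept_genes[j]),
        )
        nb = tuple(kept_genes[j] for j in order[: min(top_n, len(order))])
        out[g] = CoexpressionCluster(g, compendium.compendium_id, nb)
    return out


# ---------------------------------------------------------------------------
# hypergeometric machinery


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> HypergeomResult:
    """Exact upper-tail probability P[X >= k], X ~ Hypergeom(N, K, n).

    Computed by integer summation of the tail, so it is exact to float
    rounding at any problem size used here.
    """
    # validate bounds first so violations raise the named inequality
    HypergeomResult(k=k, n=n, K=K, N=N, p=1.0)
    hi = min(n, K)
    numer = sum(comb(K, i) * comb(N - K, n - i) for i in range(max(k, 0), hi + 1))
    denom = comb(N, n)
    p = numer / denom if denom else 1.0
    return HypergeomResult(k=k, n=n, K=K, N=N, p=float(p))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Fold enrichment (k/n)/(K/N); 1.0 means no enrichment."""
    if n == 0:
        raise ValueError("n must be > 0")
    if K == 0:
        raise ValueError("K must be > 0")
    return (k / n) / (K / N)


# ---------------------------------------------------------------------------
# the P+COE filter and evaluation


def filter_p_coe(
    tf_id: str,
    p_targets: TargetSet,
    clusters_per_compendium: dict[str, dict[str, CoexpressionCluster]],
    universe: set[str],
    alpha: float = 0.05,
    rule: str = "any",
) -> TargetSet:
    """Retain P targets whose co-expression cluster is enriched for P targets.

    For each candidate gene and compendium the test draws the gene's
    neighbor set (n genes) from the universe (N) and counts P targets among
    them (k of K).  ``rule`` decides how the per-compendium verdicts
    combine: enriched in at least one compendium (``any``, the default),
    in a majority (``majority``), or in ``all``.
    """
    if rule not in ("any", "majority", "all"):
        raise ValueError(f"unknown rule {rule!r}")
    if not p_targets.genes <= universe:
        raise ValueError("P targets must be a subset of the universe")
    p_in_universe = p_targets.genes & universe
    K = len(p_in_universe)
    N = len(universe)
    retained: set[str] = set()
    for gene in sorted(p_targets.genes):
        verdicts = []
        for cid, clusters in clusters_per_compendium.items():
            cluster = clusters.get(gene)
            if cluster is None:
                logger.debug("%s absent from compendium %s", gene, cid)
                continue
            neighbors = [nb for nb in cluster.neighbors if nb in universe]
            n = len(neighbors)
            if n == 0:
                continue
            k = sum(1 for nb in neighbors if nb in p_in_universe)
            res = hypergeom_pvalue(min(k, K), n, K, N)
            verdicts.append(res.p < alpha)
        if not verdicts:
            continue
        hits = sum(verdicts)
        keep = (
            hits >= 1 if rule == "any"
            else hits > len(verdicts) / 2 if rule == "majority"
            else hits == len(verdicts)
        )
        if keep:
            retained.add(gene)
    return TargetSet(tf_id=tf_id, tier="P+COE", genes=retained)


def de_recovery(
    targets: TargetSet, de: DESet, universe: set[str]
) -> tuple[HypergeomResult, float]:
    """Enrichment of a target set for DE genes: p-value and fold.

    k = recovered DE genes among the targets, n = targets, K = DE genes,
    N = universe size.  An empty target set yields fold 0 and p 1.
    """
    if not de.genes:
        raise ValueError("empty DE set")
    t = targets.genes & universe
    d = de.genes & universe
    k, n, K, N = len(t & d), len(t), len(d), len(universe)
    if n == 0:
        return HypergeomResult(0, 0, K, N, 1.0), 0.0
    return hypergeom_pvalue(k, n, K, N), fold_enrichment(k, n, K, N)


def target_overlap(
    a: TargetSet, b: TargetSet, universe: set[str]
) -> tuple[int, float, float]:
    """Shared-target statistics between two TFs: (count, fold, p).

    Symmetric in its two arguments by the symmetry of the hypergeometric
    model.
    """
    ga, gb = a.genes & universe, b.genes & universe
    k, n, K, N = len(ga & gb), len(ga), len(gb), len(universe)
    if n == 0 or K == 0:
        return 0, 0.0, 1.0
    res = hypergeom_pvalue(k, n, K, N)
    return k, fold_enrichment(k, n, K, N), res.p
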