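"""TF-target network assembly, functional-module enrichment and evaluation.

All P+COE targets of all TFs form the gene regulatory network (GRN), with
edges carrying the evidence tier and a conservation flag.  Per TF, curated
functional modules are tested for target enrichment (hypergeometric,
P < 0.05), enriched modules' GO terms are propagated to their ancestors,
intersected with a GO-slim vocabulary, and mapped onto 10 fixed functional
categories.  The network is evaluated against curated TF-target
interactions, and a perturbation co-expression analysis partitions
candidate targets into positively and negatively correlated groups
relative to the focal TF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .coexpression import HypergeomResult, fold_enrichment, hypergeom_pvalue
from .promoters import TargetSet

__all__ = [
    "RegulatoryEdge",
    "RegulatoryNetwork",
    "FunctionalModule",
    "ModuleEnrichment",
    "FUNCTIONAL_CATEGORIES",
    "DEFAULT_SLIM_CATEGORY_MAP",
    "build_grn",
    "enrich_modules",
    "propagate_go_terms",
    "categorize_modules",
    "evaluate_known",
    "perturbation_cluster",
    "export_network",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulatoryEdge:
    tf_id: str
    gene_id: str
    tier: str
    conserved: bool = False


@dataclass
class RegulatoryNetwork:
    edges: list[RegulatoryEdge]

    @property
    def tf_ids(self) -> list[str]:
        return sorted({e.tf_id for e in self.edges})

    @property
    def target_genes(self) -> set[str]:
        return {e.gene_id for e in self.edges}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def summary(self) -> dict:
        return {
            "n_tfs": len(self.tf_ids),
            "n_targets": len(self.target_genes),
            "n_edges": self.n_edges,
            "n_conserved_edges": sum(e.conserved for e in self.edges),
        }


@dataclass
class FunctionalModule:
    """A curated gene set with associated GO term annotations."""

    module_id: str
    genes: set[str]
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.module_id}: empty gene set")


@dataclass
class ModuleEnrichment:
    module_id: str
    tf_id: str
    result: HypergeomResult
    enriched: bool
    categories: dict[str, float] = field(default_factory=dict)  # category -> fraction

    def __post_init__(self) -> None:
        if self.enriched and not self.result.p < 0.05:
            # callers may use another alpha; re-derive instead of failing hard
            logger.debug("module %s flagged enriched at p=%.3g", self.module_id, self.result.p)


# The 10 fixed functional categories and the GO-slim terms grouped into
# each.  Slim terms are named, not GO ids, to stay ontology-release
# independent; inputs may map ids to these names.
DEFAULT_SLIM_CATEGORY_MAP: dict[str, str] = {
    "tropism": "tropism",
    "cellular homeostasis": "cellular homeostasis",
    "cell-cell signalling": "stress cell death and signalling",
    "regulation of gene expression, epigenetic": "stress cell death and signalling",
    "response to stress": "stress cell death and signalling",
    "response to biotic stimulus": "stress cell death and signalling",
    "response to abiotic stimulus": "stress cell death and signalling",
    "death": "stress cell death and signalling",
    "cell death": "stress cell death and signalling",
    "response to external stimulus": "stress cell death and signalling",
    "cell communication": "stress cell death and signalling",
    "response to extracellular stimulus": "stress cell death and signalling",
    "transport": "transport",
    "signal transduction": "signal transduction and response to endogenous stimulus",
    "response to endogenous stimulus": "signal transduction and response to endogenous stimulus",
    "catabolic process": "catabolic process",
    "generation of precursor metabolites and energy": "energy lipid carbohydrate and secondary metabolism",
    "photosynthesis": "energy lipid carbohydrate and secondary metabolism",
    "lipid metabolic process": "energy lipid carbohydrate and secondary metabolism",
    "carbohydrate metabolic process": "energy lipid carbohydrate and secondary metabolism",
    "secondary metabolic process": "energy lipid carbohydrate and secondary metabolism",
    "cell cycle": "cell cycle",
    "translation": "translation and protein metabolism",
    "protein metabolic process": "translation and protein metabolism",
    "reproduction": "growth reproduction and development",
    "multicellular organismal development": "growth reproduction and development",
    "anatomical structure morphogenesis": "growth reproduction and development",
    "embryo development": "growth reproduction and development",
    "post-embryonic development": "growth reproduction and development",
    "fruit ripening": "growth reproduction and development",
    "abscission": "growth reproduction and development",
    "pollination": "growth reproduction and development",
    "pollen-pistil interaction": "growth reproduction and development",
    "flower development": "growth reproduction and development",
    "cellular component organization": "growth reproduction and development",
    "cell growth": "growth reproduction and development",
    "cell differentiation": "growth reproduction and development",
    "growth": "growth reproduction and development",
}

FUNCTIONAL_CATEGORIES: tuple[str, ...] = tuple(
    sorted(set(DEFAULT_SLIM_CATEGORY_MAP.values()))
)
assert len(FUNCTIONAL_CATEGORIES) == 10


def build_grn(
    target_sets: list[TargetSet],
    conserved_genes: dict[str, set[str]] | None = None,
) -> RegulatoryNetwork:
    """One edge per (TF, gene) in the P+COE tier.

    ``conserved_genes`` maps tf_id to the genes whose motif instance
    survived the conservation filter; those edges are flagged.
    """
    conserved_genes = conserved_genes or {}
    edges: list[RegulatoryEdge] = []
    for ts in target_sets:
        cons = conserved_genes.get(ts.tf_id, set())
        if not cons <= ts.genes:
            raise ValueError(
                f"{ts.tf_id}: conserved genes must be a subset of the target set"
            )
        for gene in sorted(ts.genes):
            edges.append(RegulatoryEdge(ts.tf_id, gene, ts.tier, gene in cons))
    edges.sort(key=lambda e: (e.tf_id, e.gene_id))
    return RegulatoryNetwork(edges=edges)


def enrich_modules(
    targets: TargetSet,
    modules: list[FunctionalModule],
    universe: set[str],
    alpha: float = 0.05,
) -> list[ModuleEnrichment]:
    """Hypergeometric target enrichment per functional module."""
    t = targets.genes & universe
    n, N = len(t), len(universe)
    out = []
    for mod in modules:
        mg = mod.genes & universe
        if mg != mod.genes:
            raise ValueError(f"module {mod.module_id}: genes outside the universe")
        k, K = len(mg & t), len(mg)
        res = hypergeom_pvalue(k, n, K, N)
        out.append(
            ModuleEnrichment(mod.module_id, targets.tf_id, res, enriched=res.p < alpha)
        )
    return out


def propagate_go_terms(terms: set[str], parent_map: dict[str, set[str]]) -> set[str]:
    """Terms plus all their ancestors under an acyclic parent map."""
    out = set(terms)
    frontier = list(terms)
    steps = 0
    while frontier:
        term = frontier.pop()
        for parent in parent_map.get(term, ()):  # leaves absent from map are roots
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
        steps += 1
        if steps > 10_000_000:
            raise ValueError("GO parent map appears cyclic or pathological")
    return out


def categorize_modules(
    enrichments: list[ModuleEnrichment],
    modules: dict[str, FunctionalModule],
    go_parent_map: dict[str, set[str]],
    slim_terms: set[str] | None = None,
    slim_category_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Map each enriched module's GO annotation onto the 10 categories.

    Each enriched module's GO terms are propagated to ancestors,
    intersected with the slim vocabulary and mapped to categories; the
    module's category profile is the fraction of its slim terms per
    category.  Returns a tidy frame (tf_id, module_id, category, fraction,
    shared_by) where ``shared_by`` counts TFs with this module enriched,
    supporting the >= 5-TF / < 5-TF partition.
    """
    cat_map = DEFAULT_SLIM_CATEGORY_MAP if slim_category_map is None else slim_category_map
    if len(set(cat_map.values())) != 10:
        raise ValueError("slim category map must define exactly 10 categories")
    slim = set(cat_map) if slim_terms is None else slim_terms
    missing = slim - set(cat_map)
    if missing:
        raise ValueError(f"slim terms missing from category map: {sorted(missing)}")

    tfs_per_module: dict[str, set[str]] = {}
    for enr in enrichments:
        if enr.enriched:
            tfs_per_module.setdefault(enr.module_id, set()).add(enr.tf_id)

    rows = []
    for enr in enrichments:
        if not enr.enriched:
            continue
        mod = modules[enr.module_id]
        propagated = propagate_go_terms(mod.go_terms, go_parent_map)
        slim_hits = sorted(propagated & slim)
        if not slim_hits:
            logger.info("module %s: no slim-mappable GO terms; uncategorized", enr.module_id)
            continue
        counts: dict[str, int] = {}
        for term in slim_hits:
            counts[cat_map[term]] = counts.get(cat_map[term], 0) + 1
        total = sum(counts.values())
        enr.categories = {c: counts[c] / total for c in sorted(counts)}
        for cat, frac in enr.categories.items():
            rows.append(
                {
                    "tf_id": enr.tf_id,
                    "module_id": enr.module_id,
                    "category": cat,
                    "fraction": frac,
                    "shared_by": len(tfs_per_module[enr.module_id]),
                }
            )
    return pd.DataFrame(rows, columns=["tf_id", "module_id", "category", "fraction", "shared_by"])


def evaluate_known(
    network: RegulatoryNetwork, curated: list[tuple[str, str]]
) -> float:
    """Fraction of curated TF-target pairs recovered by the network.

    The denominator is restricted to curated pairs whose TF is present in
    the network (interactions of unstudied TFs cannot be recovered).
    """
    if not curated:
        raise ValueError("empty curated interaction list")
    tfs = set(network.tf_ids)
    eligible = [(tf, g) for tf, g in curated if tf in tfs]
    if not eligible:
        return 0.0
    edge_set = {(e.tf_id, e.gene_id) for e in network.edges}
    recovered = sum(1 for pair in eligible if pair in edge_set)
    return recovered / len(eligible)


def perturbation_cluster(
    matrix: pd.DataFrame,
    focal_gene: str,
    candidate_targets: list[str],
) -> tuple[list[str], dict[str, str]]:
    """Cluster candidate targets with the focal TF across perturbations.

    ``matrix`` is conditions x genes (log2 ratios).  Genes are clustered
    agglomeratively (Euclidean distance, average linkage) and each target
    is labeled ``positive`` or ``negative`` by the sign of its Pearson
    correlation with the focal TF's profile.  Constant profiles are
    excluded with a log message.  Returns the leaf ordering and the sign
    partition.
    """
    if focal_gene not in matrix.columns:
        raise ValueError(f"focal gene {focal_gene!r} absent from matrix")
    genes = [focal_gene] + [g for g in candidate_targets if g != focal_gene]
    missing = [g for g in genes if g not in matrix.columns]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    sub = matrix[genes]
    sd = sub.std(axis=0, ddof=0)
    flat = list(sd.index[sd == 0])
    if flat:
        if focal_gene in flat:
            raise ValueError("focal gene has a constant profile")
        logger.info("excluding %d constant gene profiles: %s", len(flat), flat[:5])
        sub = sub.drop(columns=flat)
    data = sub.to_numpy(dtype=float).T  # genes x conditions
    if data.shape[0] < 2:
        raise ValueError("need at least 2 non-constant genes")
    lm = linkage(pdist(data, metric="euclidean"), method="average")
    order = [sub.columns[i] for i in leaves_list(lm)]
    focal = sub[focal_gene].to_numpy(dtype=float)
    signs: dict[str, str] = {}
    for g in sub.columns:
        if g == focal_gene:
            continue
        r = float(np.corrcoef(focal, sub[g].to_numpy(dtype=float))[0, 1])
        signs[g] = "positive" if r >= 0 else "negative"
    return order, signs


def export_network(
    network: RegulatoryNetwork,
    enrichments: list[ModuleEnrichment],
    edge_path,
    module_path,
    graphml_path,
) -> None:
    """Write the edge table, module table and a TF/module GraphML graph.

    Output ordering is fixed (sorted) so repeated exports are
    byte-identical.
    """
    edges = pd.DataFrame(
        [(e.tf_id, e.gene_id, e.tier, e.conserved) for e in network.edges],
        columns=["tf_id", "gene_id", "tier", "conserved"],
    ).sort_values(["tf_id", "gene_id"], kind="mergesort")
    edges.to_csv(edge_path, sep="\t", index=False)

    mods = pd.DataFrame(
        [
            (e.tf_id, e.module_id, e.result.k, e.result.n, e.result.K, e.result.N,
             e.result.p, e.enriched)
            for e in sorted(enrichments, key=lambda x: (x.tf_id, x.module_id))
        ],
        columns=["tf_id", "module_id", "k", "n", "K", "N", "p", "enriched"],
    )
    mods.to_csv(module_path, sep="\t", index=False, float_format="%.6g")

    g = nx.Graph()
    for tf in network.tf_ids:
        g.add_node(f"tf:{tf}", kind="tf")
    for enr in sorted(enrichments, key=lambda x: (x.module_id, x.tf_id)):
        if not enr.enriched:
            continue
        node = f"module:{enr.module_id}"
        if node not in g:
            g.add_node(node, kind="module")
        for cat, frac in sorted(enr.categories.items()):
            g.nodes[node][f"cat_{cat.replace(' ', '_')}"] = round(frac, 6)
        g.add_edge(f"tf:{enr.tf_id}", node, p=float(enr.result.p))
    nx.write_graphml(g, graphml_path)
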