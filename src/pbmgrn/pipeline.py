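"""In-memory end-to-end synthetic study: simulate, score, filter, evaluate.

This is the library counterpart of the CLI's ``all`` command for callers
that want the intermediate objects rather than files: it simulates every
input with planted ground truth, runs PBM scoring, promoter scanning, the
co-expression filter and (optionally) the conservation filter, and returns
the evidence tiers together with their DE fold enrichments.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coexpression import (
    DESet,
    ExpressionCompendium,
    coexpression_clusters,
    de_recovery,
    filter_p_coe,
)
from .footprint import (
    AlignScoring,
    OrthologGroup,
    conservation_profile,
    conserved_instances,
    empirical_fdr,
    extract_footprints,
)
from .pbm import EnrichmentTable, compute_enrichment_table, normalize_probes
from .promoters import MotifHit, Promoter, TargetSet, extract_promoters, predict_targets, seed_kmers
from .simulate import (
    GroundTruth,
    SimulationConfig,
    background_pool,
    simulate_expression,
    simulate_genome,
    simulate_orthologs,
    simulate_pbm,
)

__all__ = ["StudyResult", "run_study", "conserved_targets"]


@dataclass
class StudyResult:
    """Everything a synthetic end-to-end run produced."""

    table: EnrichmentTable
    truth: GroundTruth
    promoters: list[Promoter]
    universe: set[str]
    p_sets: dict[str, TargetSet]
    hit_maps: dict[str, dict[str, list[MotifHit]]]
    pcoe_sets: dict[str, TargetSet]
    conserved_sets: dict[str, TargetSet] = field(default_factory=dict)
    de_sets: dict[str, DESet] = field(default_factory=dict)
    compendia: list[ExpressionCompendium] = field(default_factory=list)
    ortholog_groups: dict[str, OrthologGroup] = field(default_factory=dict)

    def tier_folds(self, tf_id: str) -> dict[str, float]:
        """DE fold enrichment per available evidence tier for one TF."""
        de = self.de_sets[tf_id]
        out = {}
        for tier, sets in (
            ("P", self.p_sets),
            ("P+COE", self.pcoe_sets),
            ("conserved_P+COE", self.conserved_sets),
        ):
            if tf_id in sets:
                _, fold = de_recovery(sets[tf_id], de, self.universe)
                out[tier] = fold
        return out


def conserved_targets(
    tf_id: str,
    pcoe: TargetSet,
    hit_map: dict[str, list[MotifHit]],
    groups: dict[str, OrthologGroup],
    promoter_seqs: dict[str, str],
    scoring: AlignScoring,
    n_null_samples: int,
    seed: int,
    fdr_alpha: float = 0.05,
) -> TargetSet:
    """Conservation filter: P+COE genes with a seed hit inside an FDR<alpha footprint."""
    genes: set[str] = set()
    for idx, gene in enumerate(sorted(pcoe.genes)):
        if gene not in groups or gene not in promoter_seqs:
            continue
        qseq = promoter_seqs[gene]
        group = groups[gene]
        profile = conservation_profile(gene, qseq, group, scoring)
        fps = []
        for level in range(1, len(group.species) + 1):
            fps.extend(extract_footprints(profile, level))
        if not fps:
            continue
        pool = background_pool(groups, gene)
        fps = empirical_fdr(
            gene, qseq, group, fps, pool,
            n_samples=n_null_samples,
            seed=(seed * 1013 + idx) % (2**31),
            scoring=scoring,
            alpha=fdr_alpha,
        )
        flagged = conserved_instances(hit_map.get(gene, []), fps, alpha=fdr_alpha)
        if any(h.conserved for h in flagged):
            genes.add(gene)
    return TargetSet(tf_id=tf_id, tier="conserved_P+COE", genes=genes)


def run_study(
    sim: SimulationConfig,
    seed: int,
    k: int = 8,
    max_gap: int = 0,
    min_foreground: int = 4,
    es_seed: float = 0.45,
    coexp_top_n: int = 50,
    coexp_alpha: float = 0.05,
    n_null_samples: int = 50,
    footprint_tfs: tuple[str, ...] | None = ("TF_A",),
    scoring: AlignScoring = AlignScoring(),
) -> StudyResult:
    """Full synthetic study under one seed.

    The conservation filter is the expensive stage (each gene is scored
    against ``n_null_samples`` resampled ortholog sets), so it is run only
    for ``footprint_tfs`` (None = all TFs), mirroring how perturbation data
    restrict which TFs can be evaluated anyway.
    """
    rng = np.random.default_rng(seed % (2**31))
    experiments, _ = simulate_pbm(sim, rng)
    normalized = [normalize_probes(reps) for _, reps in sorted(experiments.items())]
    table = compute_enrichment_table(
        normalized, k=k, max_gap=max_gap, min_foreground=min_foreground
    )

    with tempfile.TemporaryDirectory() as td:
        fasta, gff3 = Path(td) / "genome.fasta", Path(td) / "genes.gff3"
        truth = simulate_genome(sim, rng, fasta, gff3)
        promoters = extract_promoters(fasta, gff3)
    prom_seqs = {p.gene_id: p.sequence for p in promoters}
    genes = sorted(prom_seqs)
    universe = set(genes)

    compendia, de_sets = simulate_expression(sim, rng, genes, truth)

    p_sets, hit_maps, pcoe_sets = {}, {}, {}
    for tf in sim.tf_ids:
        seeds = seed_kmers(table, tf, es_seed)
        ts, hit_map = predict_targets(tf, promoters, seeds, table)
        ts.genes &= universe
        p_sets[tf] = ts
        hit_maps[tf] = hit_map
        clusters = {
            c.compendium_id: coexpression_clusters(
                c, top_n=coexp_top_n, focus_genes=sorted(ts.genes)
            )
            for c in compendia
        }
        pcoe_sets[tf] = filter_p_coe(tf, ts, clusters, universe, alpha=coexp_alpha)

    result = StudyResult(
        table=table, truth=truth, promoters=promoters, universe=universe,
        p_sets=p_sets, hit_maps=hit_maps, pcoe_sets=pcoe_sets,
        de_sets=de_sets, compendia=compendia,
    )

    wanted = sim.tf_ids if footprint_tfs is None else [
        tf for tf in sim.tf_ids if tf in footprint_tfs
    ]
    if wanted:
        groups = simulate_orthologs(sim, rng, prom_seqs, truth)
        result.ortholog_groups = groups
        for tf in wanted:
            result.conserved_sets[tf] = conserved_targets(
                tf, pcoe_sets[tf], hit_maps[tf], groups, prom_seqs,
                scoring, n_null_samples, seed=seed,
            )
    return result
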