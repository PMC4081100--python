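"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate, at desk scale, the data sources the pipeline
consumes: a universal-design PBM probe set (all 6-mers covered, de
Bruijn-style) with planted core-motif-driven intensities; a genome whose
designated true-target promoters carry one planted binding site (with
intergenic gaps below 1 kb to exercise promoter truncation); expression
compendia in which true targets co-express through a latent TF activity;
orthologous promoters whose planted conserved window diverges far more
slowly than the rest of the sequence; and functional modules enriched for
true targets.  Every generator is a pure function of its configuration and
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coexpression import DESet, ExpressionCompendium
from .footprint import OrthologGroup
from .network import DEFAULT_SLIM_CATEGORY_MAP, FunctionalModule
from .patterns import revcomp
from .pbm import PBMExperiment, ProbeRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "de_bruijn_sequence",
    "simulate_pbm",
    "simulate_genome",
    "simulate_expression",
    "simulate_perturbation",
    "simulate_orthologs",
    "simulate_modules",
    "background_pool",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    The PBM block plants, per TF, a 6-bp core motif (the intensity model)
    and an 8-bp site word (core plus fixed flanks) spiked into
    ``site_copies`` probes, mirroring the replicate spotting a universal
    array gives every word.  Intensity = baseline + amplitude * (best
    window probability ratio under the core PWM), with multiplicative
    lognormal noise; PBM intensities are positive and right-skewed.
    """

    # PBM
    tf_motifs: dict = field(
        default_factory=lambda: {
            "TF_A": ("TTGCGT", "ATTGCGTA"),
            "TF_B": ("TTACTT", "GTTACTTC"),
        }
    )
    n_probes: int = 2000
    probe_length: int = 36
    n_replicates: int = 2
    min_cover: int = 1
    baseline: float = 50.0
    amplitude: float = 2000.0
    noise_sd: float = 0.2
    consensus_prob: float = 0.9
    site_copies: int = 12
    replicate_scales: tuple = (1.0, 1.3)
    # genome
    n_genes: int = 500
    gene_length: int = 200
    gap_choices: tuple = (300, 400, 600, 800, 1200, 1500)
    n_true_targets: int = 30
    site_prob: float = 1.0
    # expression
    n_compendia: int = 2
    n_samples: int = 30
    effect_size: float = 2.0
    expression_noise_sd: float = 1.0
    de_threshold: float = 1.0
    de_background_sd: float = 0.3
    # orthologs
    n_species: int = 4
    substitution_rate: float = 0.5
    conserved_rate: float = 0.02
    conserved_window: int = 40
    # modules
    n_modules: int = 30
    module_size: int = 12
    enriched_modules_per_tf: int = 3
    enriched_purity: float = 0.8

    def __post_init__(self) -> None:
        for name in ("site_prob", "substitution_rate", "conserved_rate",
                     "consensus_prob", "enriched_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.tf_motifs)


@dataclass
class GroundTruth:
    """What was planted: targets, sites, conserved windows, signs, modules."""

    true_targets: dict[str, set[str]] = field(default_factory=dict)
    planted_sites: dict[str, tuple[int, str, str, str]] = field(default_factory=dict)
    # gene -> (promoter offset, strand, site text, tf)
    conserved_windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    regulation_signs: dict[str, int] = field(default_factory=dict)
    module_membership: dict[str, set[str]] = field(default_factory=dict)

    @property
    def all_true_targets(self) -> set[str]:
        out: set[str] = set()
        for genes in self.true_targets.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# PBM


def de_bruijn_sequence(order: int, alphabet: str = "ACGT") -> str:
    """Cyclic de Bruijn sequence containing every ``order``-mer once."""
    k = len(alphabet)
    a = [0] * (k * order)
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > order:
            if order % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return "".join(alphabet[i] for i in seq)


def _core_pwm(core: str, p: float) -> np.ndarray:
    """Width-len(core) PWM: probability ``p`` on the core base, rest split."""
    w = len(core)
    pwm = np.full((w, 4), (1 - p) / 3)
    for i, b in enumerate(core):
        pwm[i, "ACGT".index(b)] = p
    return pwm


def _pwm_best_ratio(seqs: list[str], pwm: np.ndarray) -> np.ndarray:
    """Best-window probability ratio (to the consensus) per probe, both strands."""
    w = pwm.shape[0]
    logp = np.log(pwm)
    logmax = float(np.log(pwm.max(axis=1)).sum())
    enc = np.array([[_BASE_IDX[c] for c in s] for s in seqs], dtype=np.int64)
    n, L = enc.shape
    best = np.full(n, -np.inf)
    for strand_enc in (enc, 3 - enc[:, ::-1]):  # revcomp: complement + reverse
        for s in range(0, L - w + 1):
            window = strand_enc[:, s : s + w]
            score = logp[np.arange(w), window].sum(axis=1)
            np.maximum(best, score, out=best)
    return np.exp(best - logmax)


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def simulate_pbm(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, list[PBMExperiment]], GroundTruth]:
    """Per-TF replicate PBM experiments over one shared probe design.

    The probe set tiles a de Bruijn sequence of order 6 (every ungapped
    6-mer covered at least ``min_cover`` times), pads with random probes,
    and spikes each TF's planted site word into ``site_copies`` random
    probes at random offsets and strands.
    """
    L = config.probe_length
    stride = L - 5
    base = de_bruijn_sequence(6)
    cyc = base + base[:5]
    tile_probes = [cyc[i : i + L] for i in range(0, len(base), stride)]
    tile_probes = [
        p if len(p) == L
        else p + "".join(rng.choice(list("ACGT"), size=L - len(p)))
        for p in tile_probes
    ]
    needed = len(tile_probes) * config.min_cover
    n_spike = config.site_copies * len(config.tf_motifs)
    if config.n_probes < needed + n_spike:
        raise ValueError(
            f"n_probes={config.n_probes} cannot cover all 6-mers {config.min_cover}x "
            f"plus {n_spike} site probes; minimal feasible count is {needed + n_spike}"
        )
    probes = list(tile_probes) * config.min_cover
    while len(probes) < config.n_probes:
        probes.append("".join(rng.choice(list("ACGT"), size=L)))

    # spike planted sites into random non-tile probes
    free = list(range(needed, config.n_probes))
    rng.shuffle(free)
    pos = 0
    for tf in sorted(config.tf_motifs):
        _, site = config.tf_motifs[tf]
        for _ in range(config.site_copies):
            idx = free[pos]
            pos += 1
            off = int(rng.integers(0, L - len(site) + 1))
            planted = site if rng.random() < 0.5 else revcomp(site)
            probes[idx] = probes[idx][:off] + planted + probes[idx][off + len(site):]

    truth = GroundTruth()
    experiments: dict[str, list[PBMExperiment]] = {}
    for tf in sorted(config.tf_motifs):
        core, _ = config.tf_motifs[tf]
        ratio = _pwm_best_ratio(probes, _core_pwm(core, config.consensus_prob))
        signal = config.baseline + config.amplitude * ratio
        reps = []
        for r in range(config.n_replicates):
            scale = (
                config.replicate_scales[r]
                if r < len(config.replicate_scales)
                else 1.0
            )
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=len(probes)))
            intens = signal * noise * scale
            reps.append(
                PBMExperiment(
                    tf_id=tf,
                    probes=[
                        ProbeRecord(f"probe_{i:05d}", seq, float(v), replicate=r + 1)
                        for i, (seq, v) in enumerate(zip(probes, intens))
                    ],
                    n_replicates=1,
                )
            )
        experiments[tf] = reps
    return experiments, truth


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    config: SimulationConfig,
    rng: np.random.Generator,
    out_fasta,
    out_gff3,
) -> GroundTruth:
    """Tandem-gene genome with planted sites in true-target promoters.

    Genes sit on one chromosome, all on the + strand, separated by
    intergenic gaps drawn from ``gap_choices`` (some below 1 kb, so the
    promoter truncation rule is exercised).  Each designated true target
    receives, with probability ``site_prob``, one copy of its TF's site
    word at a uniform random promoter offset on a random strand.
    """
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    truth = GroundTruth()
    pool = list(genes)
    rng.shuffle(pool)
    cursor = 0
    for tf in sorted(config.tf_motifs):
        truth.true_targets[tf] = set(pool[cursor : cursor + config.n_true_targets])
        cursor += config.n_true_targets

    gaps = [int(rng.choice(config.gap_choices)) for _ in genes]
    site_of_tf = {tf: site for tf, (_, site) in config.tf_motifs.items()}
    tf_of_gene: dict[str, str] = {}
    for tf, tg in truth.true_targets.items():
        for g in tg:
            tf_of_gene[g] = tf

    chrom_parts: list[str] = []
    records = []
    pos = 0  # 0-based running coordinate
    for gene, gap in zip(genes, gaps):
        gap_seq = "".join(rng.choice(list("ACGT"), size=gap))
        prom_len = min(1000, gap)
        tf = tf_of_gene.get(gene)
        if tf is not None and rng.random() < config.site_prob:
            site = site_of_tf[tf]
            off = int(rng.integers(0, prom_len - len(site) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else revcomp(site)
            # promoter = last prom_len bases of the gap (gene is + strand)
            gstart = gap - prom_len + off
            gap_seq = gap_seq[:gstart] + planted + gap_seq[gstart + len(site):]
            truth.planted_sites[gene] = (off, strand, site, tf)
        gene_seq = "".join(rng.choice(list("ACGT"), size=config.gene_length))
        chrom_parts.append(gap_seq)
        chrom_parts.append(gene_seq)
        start = pos + gap + 1  # 1-based
        end = start + config.gene_length - 1
        records.append((gene, start, end))
        pos = end
    chrom = "".join(chrom_parts)

    with open(out_fasta, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(chrom), 80):
            fh.write(chrom[i : i + 80] + "\n")
    with open(out_gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region chr1 1 {len(chrom)}\n")
        for gene, start, end in records:
            fh.write(
                f"chr1\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gene};Name={gene}\n"
            )
    return truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: list[str],
    truth: GroundTruth,
) -> tuple[list[ExpressionCompendium], dict[str, DESet]]:
    """Compendia with latent-activity co-expression plus DE sets.

    In every compendium each TF has a latent activity per sample; its true
    targets' expression is sign * effect * activity plus unit Gaussian
    noise, background genes are pure noise.  The DE set of a TF holds the
    true targets whose simulated perturbation contrast exceeds the
    threshold (plus any background gene whose null contrast does, which is
    rare).
    """
    if not truth.regulation_signs:
        for g in sorted(truth.all_true_targets):
            truth.regulation_signs[g] = 1 if rng.random() < 0.5 else -1
    signs = truth.regulation_signs
    tf_of_gene = {
        g: tf for tf, tg in sorted(truth.true_targets.items()) for g in tg
    }
    compendia = []
    for c in range(config.n_compendia):
        activity = {
            tf: rng.normal(0.0, 1.0, size=config.n_samples)
            for tf in sorted(truth.true_targets)
        }
        mat = rng.normal(0.0, config.expression_noise_sd,
                         size=(len(genes), config.n_samples))
        for i, g in enumerate(genes):
            tf = tf_of_gene.get(g)
            if tf is not None:
                mat[i] += signs[g] * config.effect_size * activity[tf]
        compendia.append(
            ExpressionCompendium(
                compendium_id=f"comp{c + 1}",
                values=pd.DataFrame(
                    mat, index=genes,
                    columns=[f"s{j + 1:02d}" for j in range(config.n_samples)],
                ),
            )
        )
    de_sets: dict[str, DESet] = {}
    for tf in sorted(truth.true_targets):
        fc = pd.Series(rng.normal(0.0, config.de_background_sd, size=len(genes)),
                       index=genes)
        for g in truth.true_targets[tf]:
            fc[g] += signs[g] * config.effect_size
        de_sets[tf] = DESet(tf_id=tf, genes=set(fc.index[fc.abs() >= config.de_threshold]))
    return compendia, de_sets


def simulate_perturbation(
    config: SimulationConfig,
    rng: np.random.Generator,
    focal_tf: str,
    truth: GroundTruth,
    n_conditions: int = 60,
    min_fold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition-by-gene log2-ratio matrix around one focal TF.

    Conditions are kept when the focal TF's own |log2 ratio| exceeds
    ``min_fold`` (a 2-fold change), mimicking a stringent condition
    selection; targets follow the focal profile with their planted sign.
    Returns (matrix, per-condition metadata with the focal fold change and
    a simulated p-value).
    """
    if not truth.regulation_signs:
        raise ValueError("ground truth carries no regulation signs; "
                         "run simulate_expression first")
    targets = sorted(truth.true_targets[focal_tf])
    focal = rng.normal(0.0, 1.5, size=n_conditions)
    keep = np.abs(focal) >= min_fold
    cols = {focal_tf: focal}
    for g in targets:
        cols[g] = truth.regulation_signs[g] * focal + rng.normal(
            0.0, 0.3, size=n_conditions
        )
    mat = pd.DataFrame(cols, index=[f"cond{i + 1:03d}" for i in range(n_conditions)])
    pvals = np.where(keep, rng.uniform(0.0, 0.04, size=n_conditions),
                     rng.uniform(0.05, 1.0, size=n_conditions))
    meta = pd.DataFrame(
        {"focal_log2fc": focal, "focal_p": pvals, "selected": keep},
        index=mat.index,
    )
    return mat.loc[keep], meta


# ---------------------------------------------------------------------------
# orthologs


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.where(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_orthologs(
    config: SimulationConfig,
    rng: np.random.Generator,
    promoters: dict[str, str],
    truth: GroundTruth,
) -> dict[str, OrthologGroup]:
    """Orthologous promoters: diverged copies with a planted conserved window.

    True-target promoters are copied per species with substitutions at
    ``substitution_rate`` outside — and ``conserved_rate`` inside — a
    window of ``conserved_window`` bp centered on the planted site.
    Background genes get an independently generated promoter of the same
    length (no orthology signal at all).
    """
    species = [f"sp{j + 1}" for j in range(config.n_species)]
    out: dict[str, OrthologGroup] = {}
    for gene in sorted(promoters):
        qseq = promoters[gene]
        L = len(qseq)
        planted = truth.planted_sites.get(gene)
        per_species: dict[str, str] = {}
        if planted is not None:
            off, _, site, _ = planted
            half = (config.conserved_window - len(site)) // 2
            ws = max(0, off - half)
            we = min(L, off + len(site) + half)
            truth.conserved_windows[gene] = (ws, we)
            for sp in species:
                body = _mutate(qseq, config.substitution_rate, rng)
                window = _mutate(qseq[ws:we], config.conserved_rate, rng)
                per_species[sp] = body[:ws] + window + body[we:]
        else:
            for sp in species:
                per_species[sp] = "".join(rng.choice(list("ACGT"), size=L))
        out[gene] = OrthologGroup(query_gene=gene, promoters=per_species)
    return out


def background_pool(
    groups: dict[str, OrthologGroup], exclude_gene: str
) -> dict[str, list[str]]:
    """Per-species pools of non-orthologous promoters for FDR resampling."""
    pool: dict[str, list[str]] = {}
    for gene in sorted(groups):
        if gene == exclude_gene:
            continue
        for sp, seq in groups[gene].promoters.items():
            pool.setdefault(sp, []).append(seq)
    return pool


# ---------------------------------------------------------------------------
# modules


def simulate_modules(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: list[str],
    truth: GroundTruth,
) -> tuple[list[FunctionalModule], dict[str, set[str]]]:
    """Functional modules, some enriched for a TF's true targets.

    Per TF, ``enriched_modules_per_tf`` modules draw ``enriched_purity`` of
    their members from that TF's true targets; the remaining modules are
    random gene sets.  Each module carries one leaf GO term whose parent is
    a slim term from the shipped 10-category vocabulary, so ancestor
    propagation and categorization are exercised end to end.
    """
    slim_terms = sorted(DEFAULT_SLIM_CATEGORY_MAP)
    parent_map: dict[str, set[str]] = {s: {"biological_process"} for s in slim_terms}
    modules: list[FunctionalModule] = []
    m = 0
    for tf in sorted(truth.true_targets):
        targets = sorted(truth.true_targets[tf])
        for _ in range(config.enriched_modules_per_tf):
            n_true = min(int(round(config.enriched_purity * config.module_size)),
                         len(targets))
            members = set(rng.choice(targets, size=n_true, replace=False))
            rest = [g for g in genes if g not in members]
            members |= set(rng.choice(rest, size=config.module_size - n_true,
                                      replace=False))
            slim = slim_terms[int(rng.integers(len(slim_terms)))]
            leaf = f"leaf_{m:03d}"
            parent_map[leaf] = {slim}
            modules.append(FunctionalModule(f"mod{m:03d}", members, {leaf}))
            truth.module_membership[f"mod{m:03d}"] = set(members)
            m += 1
    while m < config.n_modules:
        members = set(rng.choice(genes, size=config.module_size, replace=False))
        slim = slim_terms[int(rng.integers(len(slim_terms)))]
        leaf = f"leaf_{m:03d}"
        parent_map[leaf] = {slim}
        modules.append(FunctionalModule(f"mod{m:03d}", members, {leaf}))
        m += 1
    return modules, parent_map
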