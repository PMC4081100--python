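"""Multi-species phylogenetic footprinting with an empirical resampling FDR.

Orthologous promoters from up to 11 related species are aligned pairwise to
the query promoter; the gap-free aligned blocks are aggregated into a
per-nucleotide *conservation profile* counting how many species support
each query position.  Maximal runs of positions at support >= c are
*footprints*.  Their significance is assessed empirically: 1000 random
non-orthologous promoter sets with the same species composition are
realigned, and a footprint's FDR is the fraction of random sets containing
a footprint with at least its support and at least its length.  Footprints
with FDR < 5% mark conserved motif instances.

The pairwise aligner is an iterative masked Smith-Waterman block extractor:
the best local alignment is found, its gap-free sub-blocks of sufficient
length and identity are kept, the aligned regions are masked in both
sequences, and the search repeats until no alignment clears the score
threshold.  This yields mutually consistent (non-overlapping) local blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .promoters import MotifHit

__all__ = [
    "AlignScoring",
    "OrthologGroup",
    "AlignedBlock",
    "PairwiseAlignment",
    "ConservationProfile",
    "Footprint",
    "align_promoter_pair",
    "aggregate_profile",
    "conservation_profile",
    "extract_footprints",
    "empirical_fdr",
    "conserved_instances",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scoring for the block extractor.

    ``min_score`` stops the iteration; blocks shorter than ``min_block`` or
    below ``min_identity`` are discarded (but still masked, so iteration
    always progresses).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_score: float = 20.0
    min_block: int = 8
    min_identity: float = 0.7
    max_rounds: int = 50


@dataclass
class OrthologGroup:
    """Orthologous promoter sequences of one query gene, one per species."""

    query_gene: str
    promoters: dict[str, str]  # species id -> promoter sequence

    def __post_init__(self) -> None:
        if not self.promoters:
            raise ValueError(f"{self.query_gene}: ortholog group needs >= 1 species")
        for sp, seq in self.promoters.items():
            if not seq:
                raise ValueError(f"{self.query_gene}/{sp}: empty ortholog promoter")

    @property
    def species(self) -> list[str]:
        return sorted(self.promoters)


@dataclass(frozen=True)
class AlignedBlock:
    """One gap-free aligned block, 0-based half-open on both sequences."""

    query_start: int
    query_end: int
    ortho_start: int
    ortho_end: int
    identity: float

    def __post_init__(self) -> None:
        if self.query_end - self.query_start != self.ortho_end - self.ortho_start:
            raise ValueError("gap-free block must have equal interval lengths")


@dataclass
class PairwiseAlignment:
    query_id: str
    species: str
    blocks: list[AlignedBlock]


@dataclass
class ConservationProfile:
    """Per-nucleotide species-support counts on the query promoter."""

    gene_id: str
    support: np.ndarray  # int array, length = promoter length

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)


@dataclass(frozen=True)
class Footprint:
    """A maximal conserved interval at one support level (0-based, half-open)."""

    gene_id: str
    start: int
    end: int
    level: int
    fdr: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


_ALPHABET = "ACGTNXY"


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a in "XY" or b in "XY" or a == "N" or b == "N":
                mat[a, b] = -1e6  # masked or ambiguous: never align
            elif a == b:
                mat[a, b] = scoring.match
            else:
                mat[a, b] = scoring.mismatch
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = mat
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def align_promoter_pair(
    query: str,
    ortholog: str,
    scoring: AlignScoring = AlignScoring(),
    query_id: str = "query",
    species: str = "species",
) -> PairwiseAlignment:
    """Iterative masked local alignment of one ortholog to the query.

    Repeats best-local-alignment extraction, keeping maximal gap-free
    sub-blocks of length >= ``min_block`` with identity >= ``min_identity``
    and masking every aligned column in both sequences, until no alignment
    scores at least ``min_score``.  Returned blocks are non-overlapping on
    both sequences.
    """
    if not query or not ortholog:
        raise ValueError("both sequences must be non-empty")
    aligner = _make_aligner(scoring)
    q = list(query.upper())
    o = list(ortholog.upper())
    blocks: list[AlignedBlock] = []
    for _ in range(scoring.max_rounds):
        qs_, os_str = "".join(q), "".join(o)
        # score-only pass first: most rounds (and most null resamples) stop
        # here without paying for alignment construction
        if aligner.score(qs_, os_str) < scoring.min_score:
            break
        alns = aligner.align(qs_, os_str)
        try:
            best = alns[0]
        except (IndexError, StopIteration):  # no alignment at all
            break
        qseg, oseg = best.aligned
        for (qs, qe), (os_, oe) in zip(qseg, oseg):
            length = qe - qs
            # maximal-scoring sub-block within the gap-free segment, so a
            # conserved core is not diluted by diverged flanks the aligner
            # happened to drag along
            col = [
                scoring.match if q[qs + i] == o[os_ + i] else scoring.mismatch
                for i in range(length)
            ]
            bs, be = _max_scoring_run(col)
            if be > bs:
                sub_len = be - bs
                matches = sum(1 for i in range(bs, be) if q[qs + i] == o[os_ + i])
                identity = matches / sub_len
                if sub_len >= scoring.min_block and identity >= scoring.min_identity:
                    blocks.append(
                        AlignedBlock(qs + bs, qs + be, os_ + bs, os_ + be, identity)
                    )
            # mask consumed columns regardless of acceptance
            for i in range(qs, qe):
                q[i] = "X"
            for i in range(os_, oe):
                o[i] = "Y"
    blocks.sort(key=lambda b: b.query_start)
    return PairwiseAlignment(query_id=query_id, species=species, blocks=blocks)


def _max_scoring_run(scores: list[float]) -> tuple[int, int]:
    """Kadane's maximum-sum interval; returns a 0-based half-open range."""
    best = 0.0
    best_range = (0, 0)
    cur = 0.0
    start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = s
            start = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_range = (start, i + 1)
    return best_range


def aggregate_profile(
    query_gene: str,
    query_length: int,
    alignments: list[PairwiseAlignment],
) -> ConservationProfile:
    """Per-position count of species with an aligned block covering it.

    A species contributes at most 1 at any position even if it has several
    blocks there.
    """
    support = np.zeros(query_length, dtype=int)
    by_species: dict[str, np.ndarray] = {}
    for aln in alignments:
        if aln.query_id != query_gene:
            raise ValueError(f"alignment of {aln.query_id!r} passed for gene {query_gene!r}")
        mask = by_species.setdefault(aln.species, np.zeros(query_length, dtype=bool))
        for b in aln.blocks:
            if b.query_start < 0 or b.query_end > query_length:
                raise ValueError(
                    f"{query_gene}/{aln.species}: block [{b.query_start}, {b.query_end}) "
                    f"outside query of length {query_length}"
                )
            mask[b.query_start : b.query_end] = True
    for mask in by_species.values():
        support += mask.astype(int)
    return ConservationProfile(gene_id=query_gene, support=support)


def conservation_profile(
    query_gene: str,
    query_seq: str,
    group: OrthologGroup,
    scoring: AlignScoring = AlignScoring(),
) -> ConservationProfile:
    """Align every species' promoter to the query and aggregate support."""
    alignments = [
        align_promoter_pair(query_seq, seq, scoring, query_id=query_gene, species=sp)
        for sp, seq in sorted(group.promoters.items())
    ]
    return aggregate_profile(query_gene, len(query_seq), alignments)


def extract_footprints(profile: ConservationProfile, level: int) -> list[Footprint]:
    """Maximal runs of positions with support >= ``level``."""
    if level < 1:
        raise ValueError("conservation level must be >= 1")
    hits = profile.support >= level
    out: list[Footprint] = []
    start = None
    for i, h in enumerate(hits):
        if h and start is None:
            start = i
        elif not h and start is not None:
            out.append(Footprint(profile.gene_id, start, i, level))
            start = None
    if start is not None:
        out.append(Footprint(profile.gene_id, start, len(hits), level))
    return out


def _max_run_lengths(support: np.ndarray, levels: list[int]) -> dict[int, int]:
    """Longest run of positions at support >= level, for each level."""
    out = {}
    for lev in levels:
        best = cur = 0
        for v in support:
            if v >= lev:
                cur += 1
                if cur > best:
                    best = cur
            else:
                cur = 0
        out[lev] = best
    return out


def empirical_fdr(
    query_gene: str,
    query_seq: str,
    group: OrthologGroup,
    footprints: list[Footprint],
    background_pool: dict[str, list[str]],
    n_samples: int = 1000,
    seed: int = 0,
    scoring: AlignScoring = AlignScoring(),
    alpha: float = 0.05,
) -> list[Footprint]:
    """Empirical FDR for observed footprints by non-orthologous resampling.

    Each null sample draws, for every species in the true group, one random
    promoter from that species' background pool (which must exclude the
    true ortholog), reruns align -> aggregate, and "beats" an observed
    footprint if it contains a run with support >= the footprint's level of
    length >= the footprint's length.  FDR = beats / n_samples.  All
    observed footprints are scored against the same null samples, so FDR is
    non-increasing in support level at fixed length.
    """
    if not footprints:
        return []
    for sp in group.species:
        pool = background_pool.get(sp, [])
        if not pool:
            raise ValueError(
                f"insufficient background pool for species {sp!r} (size {len(pool)})"
            )
    rng = np.random.default_rng(seed)
    levels = sorted({fp.level for fp in footprints})
    beats = {fp: 0 for fp in footprints}
    for _ in range(n_samples):
        alignments = []
        for sp in group.species:
            pool = background_pool[sp]
            seq = pool[int(rng.integers(len(pool)))]
            alignments.append(
                align_promoter_pair(query_seq, seq, scoring, query_id=query_gene, species=sp)
            )
        profile = aggregate_profile(query_gene, len(query_seq), alignments)
        runs = _max_run_lengths(profile.support, levels)
        for fp in footprints:
            if runs[fp.level] >= fp.length:
                beats[fp] += 1
    return [replace(fp, fdr=beats[fp] / n_samples) for fp in footprints]


def gene_level_fdr(footprints: list[Footprint]) -> float | None:
    """Best (smallest) footprint FDR of a gene; None without scored footprints."""
    vals = [fp.fdr for fp in footprints if fp.fdr is not None]
    return min(vals) if vals else None


def conserved_instances(
    hits: list[MotifHit],
    footprints: list[Footprint],
    alpha: float = 0.05,
) -> list[MotifHit]:
    """Flag motif hits fully contained in a significant footprint.

    A hit straddling a footprint edge is not conserved (full containment).
    """
    significant = [fp for fp in footprints if fp.fdr is not None and fp.fdr < alpha]
    out = []
    for h in hits:
        conserved = any(fp.start <= h.offset and h.end <= fp.end for fp in significant)
        out.append(replace(h, conserved=conserved))
    return out
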