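"""Promoter extraction, seed-word scanning and binding-site redesign.

A promoter is the 1000 bp upstream of a gene, truncated when the adjacent
upstream gene lies closer than 1 kb.  Promoters are scanned on both strands
with a TF's high-scoring seed words (ES > 0.45) to call tier-P candidate
target genes; palindromic double sites of the form CGT-N{7,8}-ACG are
scanned separately.  The module also supports redesigning a binding site
into another TF's preferred site with the fewest possible nucleotide
changes (Levenshtein distance).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from pyfaidx import Fasta

from .patterns import KmerPattern, canonical, find_matches
from .pbm import EnrichmentTable

__all__ = [
    "GeneModel",
    "Promoter",
    "MotifHit",
    "TargetSet",
    "read_gene_models",
    "extract_promoters",
    "seed_kmers",
    "scan_promoter",
    "predict_targets",
    "scan_palindromic_sites",
    "motif_edit_distance",
    "design_switch_site",
]

logger = logging.getLogger(__name__)

MAX_PROMOTER_LENGTH = 1000


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene with its distance to the nearest upstream gene."""

    gene_id: str
    chromosome: str
    strand: str
    start: int  # 1-based, inclusive
    end: int
    upstream_gap: int  # bp to the nearest upstream gene boundary (any strand)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.upstream_gap < 0:
            raise ValueError(f"{self.gene_id}: negative upstream distance")


@dataclass(frozen=True)
class Promoter:
    """Upstream regulatory sequence, 5'->3' toward the gene start."""

    gene_id: str
    sequence: str
    chromosome: str
    start: int  # 1-based genomic interval of the extracted region
    end: int
    strand: str  # strand of the gene

    def __post_init__(self) -> None:
        if len(self.sequence) > MAX_PROMOTER_LENGTH:
            raise ValueError(f"{self.gene_id}: promoter longer than 1 kb")


@dataclass(frozen=True)
class MotifHit:
    """A pattern match inside a promoter (0-based from the 5' end)."""

    gene_id: str
    pattern: str  # canonical text
    offset: int
    strand: str
    es: float = float("nan")
    conserved: bool = False

    @property
    def width(self) -> int:
        return len(self.pattern)

    @property
    def end(self) -> int:
        """One past the last covered promoter position."""
        return self.offset + self.width


TIERS = ("P", "P+COE", "conserved_P+COE")


@dataclass
class TargetSet:
    """Candidate target genes of one TF at one evidence tier."""

    tf_id: str
    tier: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}; expected one of {TIERS}")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# GFF3 / FASTA handling


def _validate_gff3(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record (fields < 8)")
            try:
                int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Gene features from a GFF3 file, with upstream distances resolved.

    The upstream gap of a gene is measured to the nearest boundary of any
    other annotated gene on the same chromosome, irrespective of that
    neighbor's strand; a gene whose upstream flank is immediately abutted
    or overlapped gets gap 0.
    """
    import gffutils

    _validate_gff3(gff3_path)
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: list[tuple[str, str, str, int, int]] = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        raw.append((gid, feat.seqid, feat.strand, feat.start, feat.end))

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, chrom, _, s, e in raw:
        by_chrom.setdefault(chrom, []).append((s, e))

    models = []
    for gid, chrom, strand, s, e in raw:
        others = [iv for iv in by_chrom[chrom] if iv != (s, e)]
        if strand == "-":
            starts = [os for os, oe in others if os > e]
            gap = (min(starts) - e - 1) if starts else MAX_PROMOTER_LENGTH
        else:
            ends = [oe for os, oe in others if oe < s]
            gap = (s - max(ends) - 1) if ends else s - 1
        models.append(GeneModel(gid, chrom, strand, s, e, max(gap, 0)))
    return models


def extract_promoters(
    genome_fasta,
    annotation_gff3,
    max_length: int = MAX_PROMOTER_LENGTH,
    max_n_fraction: float = 0.5,
) -> list[Promoter]:
    """Promoters for every annotated gene under the 1-kb/truncation rule.

    For a + strand gene the region [start-L, start-1] is taken as-is; for a
    - strand gene the region [end+1, end+L] is reverse-complemented, so the
    returned sequence always reads 5'->3' toward the gene.  L is the
    upstream gap capped at ``max_length`` (and at the chromosome edge).
    Genes with L = 0 yield no promoter; promoters that are mostly N are
    dropped.  Both cases are logged.
    """
    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    models = read_gene_models(annotation_gff3)
    out: list[Promoter] = []
    for gm in models:
        if gm.chromosome not in genome:
            raise KeyError(f"gene {gm.gene_id}: chromosome {gm.chromosome!r} absent from FASTA")
        chrom_len = len(genome[gm.chromosome])
        if gm.strand == "-":
            length = min(max_length, gm.upstream_gap, max(chrom_len - gm.end, 0))
            if length == 0:
                logger.info("%s: zero-length promoter, skipped", gm.gene_id)
                continue
            start, end = gm.end + 1, gm.end + length
            seq = str(genome[gm.chromosome][start - 1 : end])
            seq = _revcomp_seq(seq)
        else:
            length = min(max_length, gm.upstream_gap, gm.start - 1)
            if length == 0:
                logger.info("%s: zero-length promoter, skipped", gm.gene_id)
                continue
            start, end = gm.start - length, gm.start - 1
            seq = str(genome[gm.chromosome][start - 1 : end])
        if seq.count("N") > max_n_fraction * len(seq):
            logger.warning("%s: promoter >%d%% N, dropped", gm.gene_id, int(100 * max_n_fraction))
            continue
        out.append(Promoter(gm.gene_id, seq, gm.chromosome, start, end, gm.strand))
    return out


def _revcomp_seq(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# scanning


def seed_kmers(
    table: EnrichmentTable, tf_id: str, threshold: float = 0.45
) -> set[str]:
    """High-scoring seed words for one TF: ES strictly greater than 0.45."""
    if tf_id not in table.es.columns:
        raise ValueError(f"no enrichment records for TF {tf_id!r}")
    col = table.es[tf_id].dropna()
    seeds = set(col.index[col > threshold])
    if not seeds:
        logger.info("%s: no seed words above ES %.2f", tf_id, threshold)
    return seeds


def scan_promoter(
    promoter: Promoter, patterns: set[str] | set[KmerPattern]
) -> list[MotifHit]:
    """All strand-symmetric hits of canonical patterns in one promoter.

    Pattern N matches any base; promoter N matches nothing.  Overlapping
    hits are all reported.
    """
    hits: list[MotifHit] = []
    for pat in patterns:
        text = pat.text if isinstance(pat, KmerPattern) else canonical(pat)
        for off, strand in find_matches(promoter.sequence, text):
            hits.append(MotifHit(promoter.gene_id, text, off, strand))
    hits.sort(key=lambda h: (h.offset, h.pattern, h.strand))
    return hits


def predict_targets(
    tf_id: str,
    promoters: list[Promoter],
    seeds: set[str],
    table: EnrichmentTable | None = None,
) -> tuple[TargetSet, dict[str, list[MotifHit]]]:
    """Tier-P target calls: every gene whose promoter has >= 1 seed hit.

    Returns the target set and the per-gene hit lists (annotated with each
    seed's ES when a table is supplied) for downstream conservation work.
    """
    if not seeds:
        raise ValueError("empty seed set")
    hit_map: dict[str, list[MotifHit]] = {}
    genes: set[str] = set()
    for prom in promoters:
        hits = scan_promoter(prom, seeds)
        if hits:
            if table is not None:
                hits = [
                    MotifHit(h.gene_id, h.pattern, h.offset, h.strand,
                             es=table.lookup(h.pattern, tf_id))
                    for h in hits
                ]
            hit_map[prom.gene_id] = hits
            genes.add(prom.gene_id)
    return TargetSet(tf_id=tf_id, tier="P", genes=genes), hit_map


PALINDROME_SPACERS = (7, 8)


def scan_palindromic_sites(promoter: Promoter) -> list[MotifHit]:
    """Palindromic double sites CGT + 7 or 8 arbitrary bases + ACG.

    The pattern class is its own reverse complement, so a forward scan
    covers both strands; both spacer lengths are reported.
    """
    hits: list[MotifHit] = []
    for spacer in PALINDROME_SPACERS:
        text = "CGT" + "N" * spacer + "ACG"
        for off, strand in find_matches(promoter.sequence, text):
            hits.append(MotifHit(promoter.gene_id, text, off, strand))
    hits.sort(key=lambda h: (h.offset, h.pattern))
    return hits


# ---------------------------------------------------------------------------
# binding-site redesign


def motif_edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit substitution/insertion/deletion costs."""
    for name, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"{name}: empty sequence")
        if any(c not in "ACGT" for c in s):
            raise ValueError(f"{name}: non-ACGT character in {s!r}")
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ca != cb),
            ))
        prev = cur
    return prev[-1]


def best_window_es(site: str, tf_id: str, table: EnrichmentTable, k: int = 8) -> float:
    """Maximum ES over all ungapped k-windows of a site for one TF.

    Windows whose canonical word was never scored contribute nothing; a
    site with no scored window returns -0.5 (no evidence of binding).
    """
    best = float("-inf")
    for s in range(0, len(site) - k + 1):
        es = table.lookup(site[s : s + k], tf_id)
        if es == es and es > best:  # NaN-safe
            best = es
    return best if best != float("-inf") else -0.5


def design_switch_site(
    site: str,
    gain_tf: str,
    lose_tf: str,
    table: EnrichmentTable,
    max_edits: int = 3,
    gain_threshold: float = 0.40,
    loss_threshold: float = 0.30,
) -> tuple[str, int] | None:
    """Minimal-substitution redesign switching a site between two TFs.

    Searches substitution neighborhoods of growing radius (1, 2, ...,
    ``max_edits``) for the variant whose best-window ES reaches
    ``gain_threshold`` for ``gain_tf`` while dropping to at most
    ``loss_threshold`` for ``lose_tf``; among equally distant solutions the
    lexicographically smallest wins.  Returns ``(variant, edits)`` or
    ``None`` when the neighborhoods are exhausted.
    """
    if max_edits < 1:
        raise ValueError("max_edits must be >= 1")
    for tf in (gain_tf, lose_tf):
        if tf not in table.es.columns:
            raise ValueError(f"TF {tf!r} absent from enrichment table")
    if any(c not in "ACGT" for c in site):
        raise ValueError(f"non-ACGT character in site {site!r}")

    def satisfies(s: str) -> bool:
        return (
            best_window_es(s, gain_tf, table) >= gain_threshold
            and best_window_es(s, lose_tf, table) <= loss_threshold
        )

    if satisfies(site):
        return site, 0
    for d in range(1, max_edits + 1):
        winners: list[str] = []
        for positions in itertools.combinations(range(len(site)), d):
            for repls in itertools.product("ACGT", repeat=d):
                if any(site[p] == r for p, r in zip(positions, repls)):
                    continue
                variant = list(site)
                for p, r in zip(positions, repls):
                    variant[p] = r
                v = "".join(variant)
                if satisfies(v):
                    winners.append(v)
        if winners:
            return min(winners), d
    return None
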