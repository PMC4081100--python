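"""Protein binding microarray (PBM) probe normalization and k-mer scoring.

A PBM measures, for one transcription factor (TF), the fluorescence of
thousands of double-stranded DNA probes.  The binding preference of the TF
for a short DNA word is summarized by a rank-based *enrichment score* (ES):
probes containing the word (on either strand) form the foreground, all
other probes the background, and

    ES = U / (|F| * |B|) - 1/2,

where ``U`` is the Mann-Whitney count of foreground/background probe pairs
in which the foreground probe is brighter (ties count one half).  ES lies
in [-1/2, +1/2]; +1/2 means every foreground probe outranks every
background probe.  Words reaching ES >= 0.40 for at least one TF are called
*significant*; words with ES > 0.45 later serve as promoter-scanning seeds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .patterns import KmerPattern, canonical, find_matches, revcomp, window_patterns

__all__ = [
    "ProbeRecord",
    "PBMExperiment",
    "EnrichmentRecord",
    "EnrichmentTable",
    "CoreWord",
    "PositionWeightMatrix",
    "normalize_probes",
    "enrichment_score",
    "compute_enrichment_table",
    "significant_patterns",
    "top_pattern",
    "select_core_words",
    "build_pwm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeRecord:
    """One array spot: a probe's variable-region sequence and intensity."""

    probe_id: str
    sequence: str
    intensity: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"negative intensity for probe {self.probe_id}")
        if any(c not in "ACGT" for c in self.sequence):
            raise ValueError(f"probe {self.probe_id}: sequence must be over ACGT")


@dataclass
class PBMExperiment:
    """All probes of one TF's PBM, possibly spanning several replicates."""

    tf_id: str
    probes: list[ProbeRecord]
    n_replicates: int = 1
    flagged_probes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError(f"experiment {self.tf_id}: empty probe list")
        lengths = {len(p.sequence) for p in self.probes}
        if len(lengths) != 1:
            raise ValueError(
                f"experiment {self.tf_id}: probe sequences of unequal length {sorted(lengths)}"
            )

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.probes]

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.probes], dtype=float)


@dataclass(frozen=True)
class EnrichmentRecord:
    pattern: KmerPattern
    tf_id: str
    es: float
    n_foreground: int
    median_intensity: float

    def __post_init__(self) -> None:
        if not (-0.5 - 1e-12 <= self.es <= 0.5 + 1e-12):
            raise ValueError(f"ES out of [-0.5, 0.5]: {self.es}")
        if self.n_foreground < 1:
            raise ValueError("n_foreground must be >= 1")


class EnrichmentTable:
    """Enrichment scores indexed by (canonical pattern, TF).

    Wraps a patterns-by-TFs :class:`pandas.DataFrame` of ES values (NaN for
    words never seen in a TF's probes) plus a parallel foreground-count
    frame.  The significance threshold used downstream is carried as
    metadata.
    """

    def __init__(
        self,
        es: pd.DataFrame,
        n_foreground: pd.DataFrame | None = None,
        threshold: float = 0.40,
    ) -> None:
        if es.index.has_duplicates or es.columns.has_duplicates:
            raise ValueError("one record per (pattern, tf) pair required")
        self.es = es
        self.n_foreground = n_foreground
        self.threshold = threshold

    @property
    def patterns(self) -> list[str]:
        return list(self.es.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.es.columns)

    def lookup(self, pattern: str, tf_id: str) -> float:
        """ES for a (pattern, TF) cell; NaN if the word was never scored."""
        can = canonical(pattern)
        if can in self.es.index and tf_id in self.es.columns:
            return float(self.es.at[can, tf_id])
        return float("nan")

    def to_tsv(self, path) -> None:
        out = self.es.copy()
        out.index.name = "pattern"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, threshold: float = 0.40) -> "EnrichmentTable":
        es = pd.read_csv(path, sep="\t", index_col="pattern")
        return cls(es, threshold=threshold)


@dataclass(frozen=True)
class CoreWord:
    """A 6-mer (or single-gap 7-mer) summarizing part of a TF fingerprint.

    ``es_summary`` maps each TF to (median, q25, q75) of the ES values of
    the significant 8-mers containing this word.
    """

    pattern: KmerPattern
    es_summary: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        width, gap = self.pattern.width, self.pattern.gap_len
        if not ((width == 6 and gap == 0) or (width == 7 and gap == 1)):
            raise ValueError(
                f"core word must be an ungapped 6-mer or single-gap 7-mer: {self.pattern.text}"
            )


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position base probabilities (columns ordered A, C, G, T)."""

    width: int
    probs: tuple  # tuple of 4-tuples, one per position

    def __post_init__(self) -> None:
        if len(self.probs) != self.width:
            raise ValueError("probs length must equal width")
        for col in self.probs:
            if abs(sum(col) - 1.0) > 1e-9 or min(col) < 0:
                raise ValueError("each PWM column must be a probability vector")

    def consensus(self) -> str:
        return "".join("ACGT"[int(np.argmax(col))] for col in self.probs)


# ---------------------------------------------------------------------------
# normalization


def normalize_probes(
    raw_experiments: list[PBMExperiment],
    floor: float | None = None,
) -> PBMExperiment:
    """Combine replicate PBMs into one normalized experiment.

    Each replicate's intensities are scaled so its median matches the mean
    of the replicate medians, then per-probe intensities are averaged on the
    log scale (geometric mean).  Probes whose combined intensity falls below
    ``floor`` (default: 1e-3 of the common median) are flagged — never
    silently dropped — so downstream scoring sees the full probe universe.
    """
    if not raw_experiments:
        raise ValueError("no replicates given")
    tf_ids = {e.tf_id for e in raw_experiments}
    if len(tf_ids) != 1:
        raise ValueError(f"replicates from different TFs: {sorted(tf_ids)}")
    tf_id = tf_ids.pop()

    id_sets = [tuple(p.probe_id for p in e.probes) for e in raw_experiments]
    ref_ids = id_sets[0]
    for i, ids in enumerate(id_sets[1:], start=2):
        if set(ids) != set(ref_ids):
            diff = sorted(set(ids) ^ set(ref_ids))[:10]
            raise ValueError(
                f"replicate {i} probe ids do not match replicate 1; e.g. {diff}"
            )

    medians = [float(np.median(e.intensities)) for e in raw_experiments]
    target = float(np.mean(medians))
    if target <= 0:
        raise ValueError("non-positive median intensity; cannot scale")
    eps = 1e-12
    log_sum: dict[str, float] = {pid: 0.0 for pid in ref_ids}
    seqs: dict[str, str] = {}
    for e, med in zip(raw_experiments, medians):
        scale = target / med if med > 0 else 1.0
        for p in e.probes:
            log_sum[p.probe_id] += math.log(max(p.intensity * scale, eps))
            seqs[p.probe_id] = p.sequence

    n_rep = len(raw_experiments)
    floor_value = 1e-3 * target if floor is None else floor
    probes, flagged = [], []
    for pid in ref_ids:
        val = math.exp(log_sum[pid] / n_rep)
        if val < floor_value:
            flagged.append(pid)
        probes.append(ProbeRecord(pid, seqs[pid], val, replicate=0))
    if flagged:
        logger.info(
            "%s: %d probes below intensity floor %.3g (flagged, kept)",
            tf_id, len(flagged), floor_value,
        )
    return PBMExperiment(
        tf_id=tf_id,
        probes=probes,
        n_replicates=n_rep,
        flagged_probes=frozenset(flagged),
    )


# ---------------------------------------------------------------------------
# enrichment scoring


def _es_from_ranks(ranks: np.ndarray, fg_idx: np.ndarray) -> float:
    """ES from midranks of all probes and foreground indices.

    With average ranks, sum(rank_F) - |F|(|F|+1)/2 equals the tie-half
    Mann-Whitney U exactly.
    """
    nf = fg_idx.size
    nb = ranks.size - nf
    if nf == 0:
        raise ValueError("pattern absent from probe set")
    if nb == 0:
        raise ValueError("no background probes (pattern matches everything)")
    u = float(ranks[fg_idx].sum()) - nf * (nf + 1) / 2.0
    return u / (nf * nb) - 0.5


def enrichment_score(exp: PBMExperiment, pattern: KmerPattern | str) -> EnrichmentRecord:
    """Rank-based enrichment score of one word in one experiment."""
    pat = pattern if isinstance(pattern, KmerPattern) else KmerPattern.from_text(pattern)
    fg = np.array(
        [i for i, s in enumerate(exp.sequences) if find_matches(s, pat)], dtype=int
    )
    if fg.size == 0:
        raise ValueError(f"pattern absent from probe set: {pat.text}")
    intens = exp.intensities
    ranks = rankdata(intens, method="average")
    es = _es_from_ranks(ranks, fg)
    return EnrichmentRecord(
        pattern=pat,
        tf_id=exp.tf_id,
        es=es,
        n_foreground=int(fg.size),
        median_intensity=float(np.median(intens[fg])),
    )


def compute_enrichment_table(
    experiments: list[PBMExperiment],
    k: int = 8,
    max_gap: int = 0,
    threshold: float = 0.40,
    min_foreground: int = 4,
) -> EnrichmentTable:
    """Score every ``k``-informative-position word occurring in the probes.

    Only words actually present in at least one probe of a given experiment
    receive an ES there (a word cannot be scored without foreground);
    absent cells are NaN.  Words matching fewer than ``min_foreground``
    probes are left unscored: the rank statistic of a word seen once or
    twice is dominated by the noise of those few spots (a word unique to
    the single brightest probe always scores +0.5), so a small support
    floor is required before an ES is considered meaningful — the same
    role the built-in word multiplicity of universal array designs plays.
    This indexes each probe's word content once and converts rank sums to
    ES, so the full word universe of a desk-scale array is scored in
    seconds.
    """
    if not experiments:
        raise ValueError("no experiments given")
    frames_es: dict[str, dict[str, float]] = {}
    frames_nf: dict[str, dict[str, int]] = {}
    for exp in experiments:
        ranks = rankdata(exp.intensities, method="average")
        membership: dict[str, set[int]] = {}
        for i, seq in enumerate(exp.sequences):
            for text in set(window_patterns(seq, k, max_gap)):
                membership.setdefault(text, set()).add(i)
        n = ranks.size
        es_col, nf_col = {}, {}
        for text, idx_set in membership.items():
            nf = len(idx_set)
            if nf == n or nf < min_foreground:  # unscoreable or unreliable
                continue
            idx = np.fromiter(idx_set, dtype=int, count=nf)
            es_col[text] = _es_from_ranks(ranks, idx)
            nf_col[text] = nf
        frames_es[exp.tf_id] = es_col
        frames_nf[exp.tf_id] = nf_col
    es = pd.DataFrame(frames_es).sort_index()
    nf = pd.DataFrame(frames_nf).reindex(es.index)
    return EnrichmentTable(es, n_foreground=nf, threshold=threshold)


def top_pattern(table: EnrichmentTable, tf_id: str, ungapped_only: bool = True) -> str:
    """The TF's highest-ES word, deterministically tie-broken.

    Ties on ES prefer the word with more foreground probes (broader
    support), then the lexicographically smaller canonical text.
    """
    if tf_id not in table.es.columns:
        raise ValueError(f"no enrichment records for TF {tf_id!r}")
    col = table.es[tf_id].dropna()
    if ungapped_only:
        col = col[[("N" not in p) for p in col.index]]
    if col.empty:
        raise ValueError(f"no scored patterns for TF {tf_id!r}")
    if table.n_foreground is not None and tf_id in table.n_foreground.columns:
        nf = table.n_foreground[tf_id].reindex(col.index).fillna(0)
    else:
        nf = pd.Series(0, index=col.index)
    order = sorted(col.index, key=lambda p: (-col[p], -nf[p], p))
    return order[0]


def significant_patterns(
    table: EnrichmentTable, threshold: float | None = None
) -> set[str]:
    """Words with ES >= threshold (inclusive) for at least one TF."""
    if table.es.empty:
        raise ValueError("empty enrichment table")
    thr = table.threshold if threshold is None else threshold
    best = table.es.max(axis=1, skipna=True)
    return set(best.index[best >= thr])


# ---------------------------------------------------------------------------
# core words


def _core_candidates(sig_text: str) -> set[str]:
    """Candidate core words contained in one significant pattern.

    Ungapped 6-mer windows, length-7 windows carrying the pattern's own
    single N, and length-7 ungapped windows with one interior position
    degenerated to N.  All canonicalized.
    """
    out: set[str] = set()
    n = len(sig_text)
    for w, make_gapped in ((6, False), (7, True)):
        for s in range(0, n - w + 1):
            win = sig_text[s : s + w]
            n_count = win.count("N")
            if n_count == 0:
                if not make_gapped:
                    out.add(canonical(win))
                else:
                    for i in range(1, w - 1):
                        out.add(canonical(win[:i] + "N" + win[i + 1 :]))
            elif n_count == 1 and make_gapped and win[0] != "N" and win[-1] != "N":
                out.add(canonical(win))
    return out


def select_core_words(
    table: EnrichmentTable,
    significant: set[str] | None = None,
) -> list[CoreWord]:
    """Greedy cover of the significant words by 6-mer / gapped-7-mer cores.

    Candidates are scored by their maximum per-TF median ES over the
    significant words containing them; the cover repeatedly takes the
    candidate covering the most still-uncovered words (ties broken by
    higher score, then lexicographically smaller canonical text) until
    every significant word contains at least one selected core.
    """
    if significant is None:
        significant = significant_patterns(table)
    if not significant:
        return []
    containing: dict[str, set[str]] = {}
    for sig in significant:
        for cand in _core_candidates(sig):
            containing.setdefault(cand, set()).add(sig)

    summaries: dict[str, dict] = {}
    score: dict[str, float] = {}
    for cand, pats in containing.items():
        rows = table.es.reindex(sorted(pats))
        summaries[cand] = {
            tf: (
                float(col.median()),
                float(col.quantile(0.25)),
                float(col.quantile(0.75)),
            )
            for tf, col in rows.items()
            if col.notna().any()
        }
        medians = rows.median(axis=0, skipna=True)
        score[cand] = float(medians.max()) if medians.notna().any() else float("-inf")
    uncovered = set(significant)
    chosen: list[str] = []
    while uncovered:
        best = min(
            containing,
            key=lambda c: (-len(containing[c] & uncovered), -score[c], c),
        )
        if not containing[best] & uncovered:
            # remaining significant words contain no candidate (too short) —
            # cannot be covered; stop rather than loop
            logger.warning("%d significant words contain no core candidate", len(uncovered))
            break
        chosen.append(best)
        uncovered -= containing[best]
    return [
        CoreWord(pattern=KmerPattern.from_text(c), es_summary=summaries[c])
        for c in sorted(chosen)
    ]


# ---------------------------------------------------------------------------
# PWM construction


def _best_alignment(seed: str, word: str, min_overlap: int = 6) -> tuple[int, str]:
    """Offset and orientation aligning ``word`` to ``seed`` with maximal
    base agreement over >= ``min_overlap`` overlapping positions.

    Offset is the position of ``word``'s first base in seed coordinates.
    Ties prefer smaller |offset|, then forward orientation, then smaller
    offset.
    """
    best: tuple[float, int, int, int, str] | None = None
    for orient, w in (("+", word), ("-", revcomp(word))):
        lo = -(len(w) - min_overlap)
        hi = len(seed) - min_overlap
        for off in range(lo, hi + 1):
            matches = 0
            overlap = 0
            for j, c in enumerate(w):
                p = off + j
                if 0 <= p < len(seed):
                    overlap += 1
                    if seed[p] == c:
                        matches += 1
            if overlap < min_overlap:
                continue
            key = (-matches, abs(off), 0 if orient == "+" else 1, off)
            if best is None or key < best[:4]:
                best = (*key, orient)
    if best is None:
        return 0, "+"
    return best[3], best[4]


def build_pwm(
    table: EnrichmentTable, tf_id: str, top_n: int = 10, pseudocount: float = 0.01
) -> PositionWeightMatrix:
    """ES-weighted PWM from a TF's top-scoring ungapped words.

    The highest-ES ungapped word anchors the coordinate frame; each further
    word is aligned to it (either orientation, >= 6 overlapping positions)
    and contributes its ES as a weighted base count per aligned column.
    Columns are normalized with a small pseudocount so no base has
    probability zero.
    """
    if tf_id not in table.es.columns:
        raise ValueError(f"no enrichment records for TF {tf_id!r}")
    col = table.es[tf_id].dropna()
    col = col[[("N" not in p) for p in col.index]]
    if col.empty:
        raise ValueError(f"no ungapped patterns scored for TF {tf_id!r}")
    ranked = col.sort_values(ascending=False, kind="mergesort")
    words = list(ranked.index[:top_n])
    seed = words[0]
    width = len(seed)
    counts = np.full((width, 4), pseudocount, dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for word in words:
        weight = max(float(ranked[word]), 0.0)
        off, orient = _best_alignment(seed, word)
        w = word if orient == "+" else revcomp(word)
        for j, c in enumerate(w):
            p = off + j
            if 0 <= p < width:
                counts[p, base_idx[c]] += weight
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(width=width, probs=tuple(tuple(row) for row in probs))
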