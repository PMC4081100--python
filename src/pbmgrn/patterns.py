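"""Gapped and ungapped DNA words with reverse-complement canonical forms.

A :class:`KmerPattern` is a DNA word over ``{A, C, G, T, N}`` in which the
``N`` positions, if any, form a single contiguous interior run (a "gap").
Because protein binding microarrays are double-stranded, a word and its
reverse complement are indistinguishable binding targets; every pattern is
therefore stored in *canonical* form, the lexicographic minimum of the word
and its reverse complement.  All matching is strand-symmetric.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "revcomp",
    "canonical",
    "KmerPattern",
    "enumerate_patterns",
    "find_matches",
    "window_patterns",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = re.compile(r"^[ACGTN]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a word and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass(frozen=True)
class KmerPattern:
    """A canonical DNA word with an optional single interior gap of Ns.

    Attributes
    ----------
    text:
        Canonical pattern text over ``{A, C, G, T, N}``.
    n_informative:
        Number of non-``N`` positions.
    gap_len:
        Length of the contiguous ``N`` run (0 for ungapped words).
    """

    text: str
    n_informative: int
    gap_len: int

    @classmethod
    def from_text(cls, text: str) -> "KmerPattern":
        """Build a pattern from raw text, canonicalizing and validating.

        Raises
        ------
        ValueError
            If the text contains characters outside ``ACGTN``, starts or
            ends with ``N``, or has more than one run of ``N``.
        """
        if not text or not _VALID.match(text):
            raise ValueError(f"invalid pattern text: {text!r}")
        if text[0] == "N" or text[-1] == "N":
            raise ValueError(f"pattern may not start or end with N: {text!r}")
        runs = re.findall(r"N+", text)
        if len(runs) > 1:
            raise ValueError(f"N positions must form one contiguous run: {text!r}")
        gap = len(runs[0]) if runs else 0
        can = canonical(text)
        return cls(text=can, n_informative=len(can) - gap, gap_len=gap)

    def __post_init__(self) -> None:
        object.__setattr__(self, "text", canonical(self.text))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text

    @property
    def width(self) -> int:
        return len(self.text)


def enumerate_patterns(k: int, max_gap: int = 0) -> list[KmerPattern]:
    """All canonical patterns with ``k`` informative positions and one
    contiguous gap of ``0..max_gap`` Ns.

    The gap, when present, sits strictly between the first and last
    informative position, so a pattern of width ``k + g`` has ``k - 1``
    possible gap placements for each gap length ``g >= 1``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    seen: set[str] = set()
    out: list[KmerPattern] = []
    for bases in itertools.product("ACGT", repeat=k):
        word = "".join(bases)
        for gap in range(0, max_gap + 1):
            if gap == 0:
                candidates: Iterator[str] = iter((word,))
            else:
                candidates = (
                    word[:i] + "N" * gap + word[i:] for i in range(1, k)
                )
            for cand in candidates:
                can = canonical(cand)
                if can not in seen:
                    seen.add(can)
                    out.append(KmerPattern.from_text(can))
    return out


def _match_offsets(seq: str, text: str) -> list[int]:
    """Offsets where ``text`` matches ``seq``; pattern N matches any base,
    sequence N matches nothing.  Overlapping matches are all reported."""
    rx = re.compile("(?=(" + "".join("[ACGT]" if c == "N" else c for c in text) + "))")
    return [m.start() for m in rx.finditer(seq)]


def find_matches(seq: str, pattern: KmerPattern | str) -> list[tuple[int, str]]:
    """All strand-symmetric matches of a canonical pattern in ``seq``.

    Returns ``(offset, strand)`` pairs, 0-based from the 5' end of ``seq``.
    Strand ``+`` means the canonical text itself matches at that offset,
    ``-`` means its reverse complement does.  A position where both
    orientations match (palindromic pattern) is reported once, as ``+``.
    """
    text = pattern.text if isinstance(pattern, KmerPattern) else canonical(pattern)
    hits = {off: "+" for off in _match_offsets(seq, text)}
    rc = revcomp(text)
    if rc != text:
        for off in _match_offsets(seq, rc):
            hits.setdefault(off, "-")
    return sorted(hits.items())


def window_patterns(seq: str, k: int, max_gap: int) -> Iterator[str]:
    """Canonical patterns of ``k`` informative positions occurring in ``seq``.

    Yields one canonical text per occurrence (duplicates included); windows
    containing non-ACGT characters are skipped.  Used to index which probes
    contain which words.
    """
    n = len(seq)
    ok = [c in "ACGT" for c in seq]
    # prefix sums to reject windows containing N quickly
    bad = [0] * (n + 1)
    for i, good in enumerate(ok):
        bad[i + 1] = bad[i] + (0 if good else 1)
    for gap in range(0, max_gap + 1):
        w = k + gap
        for start in range(0, n - w + 1):
            if bad[start + w] - bad[start] != 0:
                continue
            window = seq[start : start + w]
            if gap == 0:
                yield canonical(window)
            else:
                for i in range(1, k):
                    yield canonical(window[:i] + "N" * gap + window[i + gap :])
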