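"""Psycholinguistic norms lexicon: per-word property lookup and annotation.

Eight properties per word: length (letters), log frequency, semantic
diversity, semantic neighbourhood density, concreteness, age of acquisition,
and orthographic/phonological Levenshtein distance-20 (OLD/PLD).  Content
tokens of a transcript are annotated with these properties; they feed the
word-properties PCA.  A word absent from the lexicon falls back to its
singular form (plates -> plate); tokens still missing are dropped and
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fluency import FUNCTION_WORDS
from .transcripts import CleanTranscript

#: Column order of the lexicon CSV and of every property vector.
PROPERTY_NAMES = (
    "length",
    "log_frequency",
    "semantic_diversity",
    "semantic_neighbourhood_density",
    "concreteness",
    "age_of_acquisition",
    "old",
    "pld",
)


@dataclass(frozen=True)
class WordNorms:
    word: str
    length: float
    log_frequency: float
    semantic_diversity: float
    semantic_neighbourhood_density: float
    concreteness: float
    age_of_acquisition: float
    old: float
    pld: float

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PROPERTY_NAMES], dtype=float)

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.vector()).all())


@dataclass(frozen=True)
class LookupResult:
    norms: WordNorms
    fallback: bool  # True when resolved via the singular form


def _singular_candidates(word: str) -> list[str]:
    cands = []
    if word.endswith("ies") and len(word) > 3:
        cands.append(word[:-3] + "y")
    if word.endswith("es") and len(word) > 2:
        cands.append(word[:-2])
    if word.endswith("s") and len(word) > 1:
        cands.append(word[:-1])
    return cands


class NormsLexicon:
    """Map word -> :class:`WordNorms`, with singular-form fallback lookup."""

    def __init__(self, entries: Iterable[WordNorms], provenance: str = ""):
        self._entries: dict[str, WordNorms] = {}
        for e in entries:
            key = e.word.lower()
            if key in self._entries:
                raise ValueError(f"duplicate lexicon entry: {key!r}")
            self._entries[key] = e
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def words(self) -> list[str]:
        return list(self._entries)

    def lookup(self, word: str) -> LookupResult | None:
        """Exact match first; otherwise the singular form for plural suffixes
        (-s, -es, -ies -> -y), flagged as a fallback; else None."""
        key = word.lower()
        hit = self._entries.get(key)
        if hit is not None:
            return LookupResult(hit, fallback=False)
        for cand in _singular_candidates(key):
            hit = self._entries.get(cand)
            if hit is not None:
                return LookupResult(hit, fallback=True)
        return None

    # -- CSV round trip ------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "NormsLexicon":
        df = pd.read_csv(path)
        expected = ["word", *PROPERTY_NAMES]
        if list(df.columns) != expected:
            raise ValueError(f"lexicon CSV must have columns {expected}, got {list(df.columns)}")
        entries = [
            WordNorms(word=str(r.word).lower(), **{p: float(getattr(r, p)) if pd.notna(getattr(r, p)) else float("nan") for p in PROPERTY_NAMES})
            for r in df.itertuples(index=False)
        ]
        return cls(entries, provenance=provenance if provenance is not None else str(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"word": w, **dict(zip(PROPERTY_NAMES, e.vector()))} for w, e in self._entries.items()]
        return pd.DataFrame(rows, columns=["word", *PROPERTY_NAMES])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class CoverageReport:
    """Token bookkeeping: dropped + annotated + function = total."""

    total_tokens: int
    function_tokens: int
    annotated_tokens: int
    dropped_tokens: int
    fallback_tokens: int
    dropped_words: list[str]

    def __post_init__(self):
        assert self.dropped_tokens + self.annotated_tokens + self.function_tokens == self.total_tokens


def annotate_content_words(
    transcript: CleanTranscript,
    lexicon: NormsLexicon,
    function_list: Iterable[str] = FUNCTION_WORDS,
) -> tuple[list[tuple[str, WordNorms]], CoverageReport]:
    """Annotate every content *token* (not type) with its norms.

    Token-level annotation means a participant's property averages are
    weighted by usage.  Tokens with no norms entry (after the singular
    fallback) are dropped and counted in the coverage report.
    """
    functional = frozenset(function_list)
    annotated: list[tuple[str, WordNorms]] = []
    n_func = n_drop = n_fall = 0
    dropped: list[str] = []
    for tok in transcript.tokens:
        if tok in functional:
            n_func += 1
            continue
        hit = lexicon.lookup(tok)
        if hit is None:
            n_drop += 1
            dropped.append(tok)
            continue
        if hit.fallback:
            n_fall += 1
        annotated.append((tok, hit.norms))
    report = CoverageReport(
        total_tokens=transcript.n_tokens,
        function_tokens=n_func,
        annotated_tokens=len(annotated),
        dropped_tokens=n_drop,
        fallback_tokens=n_fall,
        dropped_words=dropped,
    )
    return annotated, report
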