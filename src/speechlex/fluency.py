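"""The 13 speech-fluency measures computed per transcript.

Token and type counts for words, word bigrams and word trigrams; the three
type-to-token ratios; total speaking time and words per minute; the
function-to-content word proportion; and the combination ratio (trigram
tokens / word tokens, an index of connected multi-word output).  These are
the inputs to the fluency PCA.  N-grams never bridge an excluded disfluency
span or a clause boundary: they are counted within runs only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable

from .transcripts import CleanTranscript

#: Bundled closed-class (function word) list: articles, demonstratives,
#: prepositions, pronouns, auxiliaries, conjunctions, particles, quantifiers.
#: Overridable wherever a function list is accepted.
FUNCTION_WORDS: frozenset[str] = frozenset(
    """
    a an the this that these those
    i you he she it we they me him her us them my your his its our their
    mine yours hers ours theirs myself yourself himself herself itself
    ourselves themselves who whom whose which what
    in on at by for with about against between into through during before
    after above below to from up down out off over under again of near
    beside behind around upon onto
    am is are was were be been being have has had having do does did doing
    will would shall should may might must can could
    and but or nor so yet if because although while whereas unless since
    when where why how than as
    not no nor n't
    there here then just also very too quite rather some any each every all
    both few more most other such only own same
    it's that's there's he's she's i'm you're we're they're i've we've
    you've they've i'll he'll she'll we'll you'll they'll isn't aren't
    wasn't weren't don't doesn't didn't won't wouldn't can't couldn't
    shouldn't hasn't haven't hadn't
    """.split()
)


@dataclass
class FluencyProfile:
    """The 13 fluency measures for one participant x picture transcript."""

    word_tokens: int
    word_types: int
    bigram_tokens: int
    bigram_types: int
    trigram_tokens: int
    trigram_types: int
    ttr_word: float
    ttr_bigram: float
    ttr_trigram: float
    total_time_s: float
    words_per_minute: float
    function_content_proportion: float
    combination_ratio: float

    MEASURES = (
        "word_tokens",
        "word_types",
        "bigram_tokens",
        "bigram_types",
        "trigram_tokens",
        "trigram_types",
        "ttr_word",
        "ttr_bigram",
        "ttr_trigram",
        "total_time_s",
        "words_per_minute",
        "function_content_proportion",
        "combination_ratio",
    )

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def missing(self) -> list[str]:
        """Measures undefined for this transcript (flagged as NaN)."""
        return [m for m in self.MEASURES if isinstance(getattr(self, m), float) and math.isnan(getattr(self, m))]


def ngram_counts(transcript: CleanTranscript, n: int) -> tuple[int, int]:
    """Token and type counts for word n-grams, confined within runs.

    tokens = sum over runs of max(0, run_length - n + 1); types = number of
    distinct n-gram strings.  An empty transcript yields (0, 0).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    tokens = 0
    types: set[tuple[str, ...]] = set()
    for run in transcript.runs:
        span = len(run) - n + 1
        if span <= 0:
            continue
        tokens += span
        for i in range(span):
            types.add(tuple(run[i : i + n]))
    return tokens, len(types)


def words_per_minute(word_tokens: int, duration_s: float) -> float:
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    return word_tokens / (duration_s / 60.0)


def function_content_proportion(
    transcript: CleanTranscript, function_list: Iterable[str] = FUNCTION_WORDS
) -> float:
    """Ratio of function-word tokens to content-word tokens.

    Raises ``ValueError`` when there are no content tokens (undefined ratio).
    """
    functional = frozenset(function_list)
    if not functional:
        raise ValueError("function word list is empty")
    n_func = sum(1 for t in transcript.tokens if t in functional)
    n_content = transcript.n_tokens - n_func
    if n_content == 0:
        raise ValueError("no content tokens; function/content proportion undefined")
    return n_func / n_content


def fluency_profile(
    transcript: CleanTranscript, function_list: Iterable[str] = FUNCTION_WORDS
) -> FluencyProfile:
    """Assemble all 13 measures; undefined ratios come back as NaN.

    TTRs are undefined on an empty transcript; the function/content
    proportion is undefined when every token is functional.
    """
    w_tok, w_typ = ngram_counts(transcript, 1)
    b_tok, b_typ = ngram_counts(transcript, 2)
    t_tok, t_typ = ngram_counts(transcript, 3)
    try:
        fcp = function_content_proportion(transcript, function_list)
    except ValueError:
        fcp = float("nan")
    return FluencyProfile(
        word_tokens=w_tok,
        word_types=w_typ,
        bigram_tokens=b_tok,
        bigram_types=b_typ,
        trigram_tokens=t_tok,
        trigram_types=t_typ,
        ttr_word=w_typ / w_tok if w_tok else float("nan"),
        ttr_bigram=b_typ / b_tok if b_tok else float("nan"),
        ttr_trigram=t_typ / t_tok if t_tok else float("nan"),
        total_time_s=transcript.duration_s,
        words_per_minute=words_per_minute(w_tok, transcript.duration_s),
        function_content_proportion=fcp,
        combination_ratio=t_tok / w_tok if w_tok else 0.0,
    )
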