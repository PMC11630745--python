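"""Annotated picture-description transcripts: parsing, IO and transcriber agreement.

Transcripts are plain text in a small disfluency-markup dialect.  Spans of
"false speech" -- material a transcriber marked as a false start, grammatical
error, filler, pause, repetition, unintelligible stretch or neologism -- are
written ``{code words...}`` and are excluded from every downstream count.
Clause boundaries (``//``) and prosodic breaks (``%``) retain no words but
split the transcript into *runs*: maximal token spans that n-gram counting
may not bridge.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class Group(str, enum.Enum):
    """Diagnostic group labels."""

    control = "control"
    svPPA = "svPPA"
    lvPPA = "lvPPA"
    nfvPPA = "nfvPPA"
    PSP = "PSP"
    CBS = "CBS"


#: Patient groups with predominant motor-speech/agrammatic features.
MOTOR_GROUPS = frozenset({Group.nfvPPA, Group.PSP, Group.CBS})
#: Patient groups with predominant lexico-semantic features.
LEXICOSEMANTIC_GROUPS = frozenset({Group.svPPA, Group.lvPPA})


class Picture(str, enum.Enum):
    """Picture-description stimuli."""

    cookie_theft = "cookie_theft"
    beach_scene = "beach_scene"


class ExclusionCode(str, enum.Enum):
    """Disfluency codes whose spans are excluded from analysis."""

    false_start = "fs"
    grammatical_error = "gram"
    filler = "fill"
    pause = "pause"
    repetition = "rep"
    unintelligible = "unint"
    neologism = "neo"


_CODES = {c.value for c in ExclusionCode}

#: Segmentation marks: retain no tokens, break n-gram runs.
CLAUSE_BOUNDARY = "//"
PROSODIC_BREAK = "%"


class ParseError(ValueError):
    """Malformed transcript markup; carries the byte offset of the defect."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class RawTranscript:
    """One participant x picture description, as transcribed (markup intact)."""

    participant_id: str
    group: Group
    picture: Picture
    duration_s: float
    text: str

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "picture", Picture(self.picture))


@dataclass(frozen=True)
class CleanTranscript:
    """Retained tokens after disfluency exclusion, grouped into runs."""

    participant_id: str
    group: Group
    picture: Picture
    duration_s: float
    runs: tuple[tuple[str, ...], ...]

    @property
    def tokens(self) -> list[str]:
        return [t for run in self.runs for t in run]

    @property
    def n_tokens(self) -> int:
        return sum(len(run) for run in self.runs)

    def serialize(self) -> str:
        """Markup-free text whose re-parse reproduces ``runs`` exactly."""
        return f" {CLAUSE_BOUNDARY} ".join(" ".join(run) for run in self.runs)


_STRIP_RE = re.compile(r"^[^\w]+|[^\w]+$", re.UNICODE)


def normalize_token(raw: str) -> str:
    """Lower-case and strip terminal punctuation.

    Internal apostrophes and hyphens are kept, so contractions ("it's") and
    hyphenated words ("tip-toe") stay single tokens.
    """
    tok = raw.lower()
    # protect internal apostrophes/hyphens; strip everything else at the edges
    tok = _STRIP_RE.sub("", tok)
    return tok


def parse_transcript(raw: RawTranscript) -> CleanTranscript:
    """Parse markup, drop excluded spans, and split retained words into runs.

    Raises
    ------
    ParseError
        On an unbalanced brace, a nested brace, or an unknown exclusion code;
        the error names the byte offset in ``raw.text``.
    """
    text = raw.text
    runs: list[tuple[str, ...]] = []
    current: list[str] = []

    def close_run():
        if current:
            runs.append(tuple(current))
            current.clear()

    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "{":
            end = text.find("}", i + 1)
            if end < 0:
                raise ParseError("unbalanced '{'", i)
            inner = text[i + 1 : end]
            if "{" in inner:
                raise ParseError("nested '{'", i + 1 + inner.index("{"))
            code = inner.split(None, 1)[0] if inner.split() else ""
            if code not in _CODES:
                raise ParseError(f"unknown exclusion code {code!r}", i)
            close_run()
            i = end + 1
        elif ch == "}":
            raise ParseError("unbalanced '}'", i)
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "{}":
                j += 1
            word = text[i:j]
            if word == CLAUSE_BOUNDARY or word == PROSODIC_BREAK:
                close_run()
            else:
                tok = normalize_token(word)
                if tok:
                    current.append(tok)
            i = j
    close_run()
    return CleanTranscript(
        participant_id=raw.participant_id,
        group=raw.group,
        picture=raw.picture,
        duration_s=raw.duration_s,
        runs=tuple(runs),
    )


def _lcs_matched_positions(a: Sequence[str], b: Sequence[str]) -> list[int]:
    """Indices in ``a`` matched under a longest-common-subsequence alignment."""
    n, m = len(a), len(b)
    # DP table of LCS lengths; O(n*m) is fine at transcript scale
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = L[i], L[i + 1]
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = max(nxt[j], row[j + 1])
    matched = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            matched.append(i)
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return matched


def percent_agreement(
    reference: CleanTranscript,
    other: CleanTranscript,
    word_list: Iterable[str] | None = None,
) -> float:
    """Transcriber agreement: matching words / total words of the reference.

    Words are aligned positionally by longest common subsequence.  With
    ``word_list``, agreement is restricted to reference tokens in the list
    (e.g. checklist targets only).

    Raises
    ------
    ValueError
        If the (possibly restricted) reference has zero words, where the
        proportion is undefined.
    """
    if (reference.participant_id, reference.picture) != (other.participant_id, other.picture):
        raise ValueError("agreement requires the same participant and picture")
    ref, oth = reference.tokens, other.tokens
    matched = _lcs_matched_positions(ref, oth)
    if word_list is not None:
        words = {w.lower() for w in word_list}
        denom = sum(1 for t in ref if t in words)
        num = sum(1 for i in matched if ref[i] in words)
    else:
        denom = len(ref)
        num = len(matched)
    if denom == 0:
        raise ValueError("reference transcript has no words; agreement undefined")
    return num / denom


# ---------------------------------------------------------------------------
# File formats


def write_transcript(raw: RawTranscript, path: str | Path) -> None:
    """Write the header + annotated body format (round-trips exactly)."""
    path = Path(path)
    path.write_text(
        f"#id: {raw.participant_id}\n"
        f"#group: {raw.group.value}\n"
        f"#picture: {raw.picture.value}\n"
        f"#duration_s: {raw.duration_s!r}\n"
        f"{raw.text}",
        encoding="utf-8",
    )


def read_transcript(path: str | Path) -> RawTranscript:
    lines = Path(path).read_text(encoding="utf-8").split("\n")
    header: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#") and ":" in line:
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    missing = {"id", "group", "picture", "duration_s"} - set(header)
    if missing:
        raise ValueError(f"{path}: missing header fields {sorted(missing)}")
    return RawTranscript(
        participant_id=header["id"],
        group=Group(header["group"]),
        picture=Picture(header["picture"]),
        duration_s=float(header["duration_s"]),
        text="\n".join(lines[body_start:]),
    )


@dataclass
class ManifestRow:
    participant_id: str
    group: Group
    picture: Picture
    path: str
    scores: dict[str, float] = field(default_factory=dict)


def read_manifest(path: str | Path) -> list[ManifestRow]:
    """Cohort manifest CSV: participant_id, group, picture, path, score columns."""
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            scores = {
                k: float(v)
                for k, v in rec.items()
                if k not in ("participant_id", "group", "picture", "path") and v not in ("", None)
            }
            rows.append(
                ManifestRow(
                    participant_id=rec["participant_id"],
                    group=Group(rec["group"]),
                    picture=Picture(rec["picture"]),
                    path=rec["path"],
                    scores=scores,
                )
            )
    return rows


def write_manifest(rows: list[ManifestRow], path: str | Path) -> None:
    score_cols = sorted({k for r in rows for k in r.scores})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "group", "picture", "path", *score_cols])
        for r in rows:
            w.writerow(
                [r.participant_id, r.group.value, r.picture.value, r.path]
                + [repr(r.scores[c]) if c in r.scores else "" for c in score_cols]
            )
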