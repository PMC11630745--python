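"""Synthetic cohorts with the statistical structure the pipeline assumes.

The study's clinical transcripts are not public, so this module generates
cohorts that emulate the group effects the analysis is designed to detect:

* reduced total output and rate in the motor groups (nfvPPA, PSP, CBS),
  modelled as a negative-binomial token count (overdispersed across
  patients) with group-specific means;
* a lexical-choice tilt -- words are sampled with probability proportional
  to a softmax of weighted, z-scored psycholinguistic properties -- toward
  short, high-frequency, high-semantic-diversity words in svPPA/lvPPA and
  toward earlier-acquired words in nfvPPA/CBS;
* planted checklist-discriminative scene words with group-specific
  production probabilities (the recoverable ground truth);
* a norms lexicon drawn from a three-cluster correlated Gaussian model
  (length/OLD/PLD; frequency/SemD/neighbourhood density/-concreteness;
  age of acquisition) so the word-properties PCA has a three-component
  structure to find;
* group-specific disfluency rates realized as markup spans, and cognitive
  sub-score distributions (ACE-R, MLSE) separating the pairs that word
  production alone cannot.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .norms import PROPERTY_NAMES, NormsLexicon, WordNorms
from .transcripts import (
    Group,
    ManifestRow,
    Picture,
    RawTranscript,
    write_manifest,
    write_transcript,
)

# ---------------------------------------------------------------------------
# Norms lexicon generator

#: Target correlation structure: three property clusters.
_P = {name: i for i, name in enumerate(PROPERTY_NAMES)}


def _target_correlation() -> np.ndarray:
    R = np.eye(len(PROPERTY_NAMES))

    def set_r(a, b, r):
        R[_P[a], _P[b]] = R[_P[b], _P[a]] = r

    # cluster A: word-form length/complexity
    set_r("length", "old", 0.80)
    set_r("length", "pld", 0.80)
    set_r("old", "pld", 0.80)
    # cluster B: semantic richness (concreteness loads negatively)
    set_r("log_frequency", "semantic_diversity", 0.77)
    set_r("log_frequency", "semantic_neighbourhood_density", 0.77)
    set_r("semantic_diversity", "semantic_neighbourhood_density", 0.77)
    set_r("concreteness", "log_frequency", -0.77)
    set_r("concreteness", "semantic_diversity", -0.77)
    set_r("concreteness", "semantic_neighbourhood_density", -0.77)
    # cluster C: age of acquisition, weakly tied to both
    set_r("age_of_acquisition", "log_frequency", -0.30)
    set_r("age_of_acquisition", "length", 0.30)
    set_r("age_of_acquisition", "concreteness", -0.20)
    # weak cross-cluster form/semantics links
    set_r("length", "log_frequency", -0.12)
    set_r("old", "log_frequency", -0.12)
    set_r("pld", "log_frequency", -0.12)
    set_r("length", "semantic_diversity", -0.15)
    return R


#: Marginal (mean, sd, lower clip, upper clip) per property.
_MARGINALS = {
    "length": (5.5, 1.8, 2.0, 14.0),
    "log_frequency": (3.0, 0.9, 0.2, 6.5),
    "semantic_diversity": (1.9, 0.35, 0.5, 3.0),
    "semantic_neighbourhood_density": (0.45, 0.12, 0.05, 0.95),
    "concreteness": (3.3, 0.9, 1.0, 5.0),
    "age_of_acquisition": (7.5, 2.2, 2.0, 16.0),
    "old": (2.2, 0.8, 0.5, 6.0),
    "pld": (2.0, 0.8, 0.5, 6.0),
}

_CONSONANTS = "bcfhjklmprtvz"  # excludes s/d/n/g so synthetic words have no inflection-like endings
_VOWELS = "aeiou"


def _make_word(length: int, rng: np.random.Generator) -> str:
    letters = []
    for i in range(max(2, length)):
        pool = _CONSONANTS if i % 2 == 0 else _VOWELS
        letters.append(pool[rng.integers(len(pool))])
    if letters[-1] in _VOWELS + "sdng":
        letters[-1] = _CONSONANTS[rng.integers(len(_CONSONANTS))]
    return "".join(letters)


def generate_norms(
    n_words: int,
    seed: int,
    named_words: Sequence[str] = (),
    correlation: np.ndarray | None = None,
) -> NormsLexicon:
    """Draw a synthetic norms lexicon from the 3-cluster correlated model.

    ``named_words`` (e.g. picture scene words) get the first property draws,
    with the length property overwritten by their actual letter count;
    remaining entries are synthetic letter strings whose spelling length
    matches their length property.  Deterministic in (n_words, seed).
    """
    if n_words < 8:
        raise ValueError("need at least 8 words")
    rng = np.random.default_rng(seed)
    R = _target_correlation() if correlation is None else np.asarray(correlation, float)
    lam, vec = np.linalg.eigh(R)
    if lam.min() < 1e-8:  # nudge to PSD if a hand-set structure is indefinite
        lam = np.clip(lam, 1e-6, None)
        R = vec @ np.diag(lam) @ vec.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    Z = rng.multivariate_normal(np.zeros(len(PROPERTY_NAMES)), R, size=n_words, method="cholesky")
    cols = {}
    for j, name in enumerate(PROPERTY_NAMES):
        m, s, lo, hi = _MARGINALS[name]
        cols[name] = np.clip(m + s * Z[:, j], lo, hi)
    cols["length"] = np.round(cols["length"])
    named = [w.lower() for w in named_words]
    if len(set(named)) != len(named):
        raise ValueError("named_words contains duplicates")
    entries = []
    used = set(named)
    for i in range(n_words):
        if i < len(named):
            word = named[i]
            cols["length"][i] = len(word)
        else:
            while True:
                word = _make_word(int(cols["length"][i]), rng)
                if word not in used:
                    break
            used.add(word)
        entries.append(WordNorms(word=word, **{p: float(cols[p][i]) for p in PROPERTY_NAMES}))
    return NormsLexicon(entries, provenance=f"synthetic 3-cluster model, seed={seed}")


# ---------------------------------------------------------------------------
# Group production profiles

#: Scene words planted as checklist candidates, per picture.
PICTURE_WORDS: dict[Picture, list[str]] = {
    Picture.cookie_theft: [
        "overflow", "sink", "stool", "jar", "curtain",
        "steal", "reach", "wash", "cookie", "cupboard",
        "boy", "girl", "mother", "water", "plate",
        "dish", "window", "fall", "dry", "tap",
    ],
    Picture.beach_scene: [
        "sandcastle", "bucket", "spade", "kite", "towel",
        "paddle", "swim", "dig", "seagull", "lighthouse",
        "dog", "ball", "boat", "sea", "sand",
        "wave", "fish", "crab", "shell", "cliff",
    ],
}

#: Default per-group production probabilities for the planted word slots.
#: Slots 0-4 separate controls from every patient group; slots 5-7 separate
#: the motor from the lexico-semantic cluster; slots 8-9 are svPPA-sensitive
#: low-frequency nouns; slots 10+ are produced broadly (weakly informative).
_SLOT_PROBS = {
    "control": [0.90] * 5 + [0.85] * 3 + [0.80] * 2 + [0.75] * 10,
    "lexsem": [0.25] * 5 + [0.80] * 3 + [0.55] * 2 + [0.65] * 10,
    "motor": [0.25] * 5 + [0.15] * 3 + [0.60] * 2 + [0.55] * 10,
}


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one diagnostic group."""

    group: Group
    mean_tokens: float  # mean content-token count (negative binomial)
    dispersion: float  # NB size parameter; smaller = more overdispersed
    duration_mean: float  # seconds
    duration_sd: float
    tilt: Mapping[str, float] = field(default_factory=dict)  # property -> softmax weight
    disfluency_rates: Mapping[str, float] = field(default_factory=dict)  # code -> per-token rate
    function_rate: float = 0.45  # function tokens per content token
    #: probability per token of retracing the last 2-3 words ("the water...
    #: the water is overflowing") -- real connected speech reuses phrases,
    #: which is what gives bigram/trigram TTRs values below 1
    phrase_repeat_rate: float = 0.05
    word_production: Mapping[str, float] | None = None  # planted word -> prob; None = slot defaults
    cognitive: Mapping[str, tuple[float, float]] = field(default_factory=dict)  # score -> (mean, sd)

    def production_prob(self, picture: Picture, word: str) -> float:
        if self.word_production is not None:
            return float(self.word_production.get(word, 0.6))
        slot = PICTURE_WORDS[picture].index(word)
        if self.group is Group.control:
            probs = _SLOT_PROBS["control"]
        elif self.group in (Group.svPPA, Group.lvPPA):
            probs = list(_SLOT_PROBS["lexsem"])
            if self.group is Group.svPPA:
                probs[8] = probs[9] = 0.15  # anomia for low-frequency nouns
        else:
            probs = _SLOT_PROBS["motor"]
        return float(probs[slot])


def _cog(mean_by_score: Mapping[str, float], sd: float = 1.5) -> dict[str, tuple[float, float]]:
    return {k: (v, sd) for k, v in mean_by_score.items()}


#: ACE-R sub-scores out of {attention 18, memory 26, fluency 14, language 26,
#: visuospatial 16}; MLSE domains out of 20 each (arbitrary-but-fixed scale).
_CONTROL_COG = {
    "acer_attention": 17.5, "acer_memory": 24.5, "acer_fluency": 12.5,
    "acer_language": 25.0, "acer_visuospatial": 15.5,
    "mlse_motor_speech": 19.5, "mlse_phonology": 19.0, "mlse_semantics": 19.0,
    "mlse_syntax": 19.0, "mlse_working_memory": 18.5,
}


def _patient_cog(**overrides: float) -> dict[str, tuple[float, float]]:
    base = dict(_CONTROL_COG)
    base.update({"acer_language": 19.0, "acer_memory": 20.0, "acer_fluency": 8.0})
    base.update(overrides)
    return _cog(base)


def default_profiles() -> dict[Group, GroupProfile]:
    """The study conditions: output volume, lexical tilt, disfluency and
    cognitive-score separations per diagnostic group."""
    quiet = {"fill": 0.02, "rep": 0.01}
    return {
        Group.control: GroupProfile(
            group=Group.control, mean_tokens=110, dispersion=14,
            duration_mean=65, duration_sd=10, tilt={},
            disfluency_rates=quiet, function_rate=0.45,
            cognitive=_cog(_CONTROL_COG, sd=1.0),
        ),
        Group.svPPA: GroupProfile(
            group=Group.svPPA, mean_tokens=105, dispersion=12,
            duration_mean=70, duration_sd=10,
            tilt={"log_frequency": 1.0, "semantic_diversity": 0.8, "length": -0.6},
            disfluency_rates={"fill": 0.04, "rep": 0.02},
            function_rate=0.50,
            cognitive=_patient_cog(mlse_semantics=9.0, mlse_phonology=18.0,
                                   acer_memory=17.0, acer_language=16.0),
        ),
        Group.lvPPA: GroupProfile(
            group=Group.lvPPA, mean_tokens=92, dispersion=12,
            duration_mean=72, duration_sd=10,
            tilt={"log_frequency": 0.8, "semantic_diversity": 0.6, "length": -0.5},
            disfluency_rates={"fill": 0.05, "rep": 0.03, "pause": 0.03},
            function_rate=0.48,
            cognitive=_patient_cog(mlse_phonology=10.0, mlse_working_memory=11.0,
                                   mlse_semantics=17.0),
        ),
        Group.nfvPPA: GroupProfile(
            group=Group.nfvPPA, mean_tokens=45, dispersion=8,
            duration_mean=80, duration_sd=12,
            tilt={"age_of_acquisition": -0.8},
            disfluency_rates={"fs": 0.05, "gram": 0.04, "fill": 0.06, "pause": 0.05, "rep": 0.04},
            function_rate=0.32,
            cognitive=_patient_cog(mlse_motor_speech=9.0, mlse_syntax=8.0,
                                   mlse_phonology=14.0),
        ),
        Group.PSP: GroupProfile(
            group=Group.PSP, mean_tokens=52, dispersion=8,
            duration_mean=80, duration_sd=12,
            tilt={"age_of_acquisition": -0.3},
            disfluency_rates={"fill": 0.05, "pause": 0.06, "rep": 0.03},
            function_rate=0.40,
            cognitive=_patient_cog(mlse_motor_speech=12.0, mlse_syntax=15.0,
                                   acer_fluency=5.0),
        ),
        Group.CBS: GroupProfile(
            group=Group.CBS, mean_tokens=56, dispersion=8,
            duration_mean=78, duration_sd=12,
            tilt={"age_of_acquisition": -0.7},
            disfluency_rates={"fill": 0.05, "pause": 0.05, "rep": 0.03},
            function_rate=0.40,
            cognitive=_patient_cog(mlse_motor_speech=13.0, mlse_syntax=15.5,
                                   acer_visuospatial=10.0),
        ),
    }


#: The study's group sizes, used as the default cohort specification.
DEFAULT_GROUP_SIZES: dict[Group, int] = {
    Group.control: 24, Group.svPPA: 9, Group.lvPPA: 9,
    Group.nfvPPA: 9, Group.PSP: 10, Group.CBS: 13,
}

_FUNCTION_SAMPLE = (
    "the a an and is are was on in it of to with he she they there "
    "this that but so then his her its at for"
).split()

_FILLERS = ("um", "er", "uh")


# ---------------------------------------------------------------------------
# Transcript generation


def _tilt_logits(norms_df: pd.DataFrame, tilt: Mapping[str, float]) -> np.ndarray:
    logits = np.zeros(len(norms_df))
    for prop, w in tilt.items():
        col = norms_df[prop].to_numpy(dtype=float)
        z = (col - col.mean()) / col.std(ddof=0)
        logits += w * z
    return logits


def generate_transcript(
    profile: GroupProfile,
    lexicon: NormsLexicon,
    picture: Picture,
    rng: np.random.Generator,
    participant_id: str = "p000",
    _norms_df: pd.DataFrame | None = None,
) -> tuple[RawTranscript, dict]:
    """One annotated picture description drawn from a group profile.

    Returns the transcript and its ground truth (which planted words were
    produced, and the realized content-token count).  ``_norms_df`` is a
    cache of ``lexicon.to_frame().set_index("word")`` for batch callers.
    """
    norms_df = lexicon.to_frame().set_index("word") if _norms_df is None else _norms_df
    targets = PICTURE_WORDS[picture]
    produced_targets = [w for w in targets if rng.random() < profile.production_prob(picture, w)]
    # realized target forms: occasionally pluralized (scored via root match)
    target_forms = [
        w + "s" if (not w.endswith("s") and rng.random() < 0.15) else w for w in produced_targets
    ]
    n_content = int(rng.negative_binomial(
        profile.dispersion, profile.dispersion / (profile.dispersion + profile.mean_tokens)
    ))
    background_vocab = norms_df.drop(index=[w for w in targets if w in norms_df.index])
    logits = _tilt_logits(background_vocab, profile.tilt)
    prob = np.exp(logits - logits.max())
    prob /= prob.sum()
    n_bg = max(0, n_content - len(target_forms))
    bg_words = list(rng.choice(background_vocab.index.to_numpy(), size=n_bg, p=prob))
    content = bg_words + list(target_forms)
    rng.shuffle(content)
    # interleave function words
    tokens: list[str] = []
    for w in content:
        if rng.random() < profile.function_rate / (1 + profile.function_rate):
            tokens.append(_FUNCTION_SAMPLE[rng.integers(len(_FUNCTION_SAMPLE))])
        tokens.append(w)
        # retrace a short phrase occasionally (repeated word combinations)
        if len(tokens) >= 3 and rng.random() < profile.phrase_repeat_rate:
            tokens.extend(tokens[-int(rng.integers(2, 4)):])
    # clause boundaries and disfluency spans
    out: list[str] = []
    since_boundary = 0
    next_boundary = int(rng.integers(6, 13))
    for tok in tokens:
        for code, rate in profile.disfluency_rates.items():
            if rng.random() < rate:
                if code == "fill":
                    out.append(f"{{fill {_FILLERS[rng.integers(len(_FILLERS))]}}}")
                elif code == "rep" and out and not out[-1].startswith(("{", "//")):
                    out.append(f"{{rep {out[-1]}}}")
                elif code == "fs":
                    out.append(f"{{fs {tok[: max(1, len(tok) // 2)]}}}")
                elif code == "gram":
                    out.append(f"{{gram {_FUNCTION_SAMPLE[rng.integers(len(_FUNCTION_SAMPLE))]}}}")
                elif code == "pause":
                    out.append("{pause}")
                elif code == "unint":
                    out.append("{unint xxx}")
                elif code == "neo":
                    out.append(f"{{neo {_make_word(5, rng)}}}")
        out.append(tok)
        since_boundary += 1
        if since_boundary >= next_boundary:
            out.append("//")
            since_boundary = 0
            next_boundary = int(rng.integers(6, 13))
    duration = float(max(20.0, rng.normal(profile.duration_mean, profile.duration_sd)))
    raw = RawTranscript(
        participant_id=participant_id,
        group=profile.group,
        picture=picture,
        duration_s=round(duration, 1),
        text=" ".join(out),
    )
    truth = {
        "produced_targets": produced_targets,
        "n_content_tokens": len(content),
    }
    return raw, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Sizes, profiles and lexicon parameters for one synthetic cohort."""

    group_sizes: Mapping[Group, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    profiles: Mapping[Group, GroupProfile] = field(default_factory=default_profiles)
    n_words: int = 500
    pictures: tuple[Picture, ...] = (Picture.cookie_theft, Picture.beach_scene)
    id_prefix: str = "sub"


@dataclass
class SyntheticCohort:
    lexicon: NormsLexicon
    transcripts: list[RawTranscript]
    participants: pd.DataFrame  # index participant_id; group + cognitive scores
    ground_truth: dict
    seed: int

    def tokens_by_participant(self, picture: Picture):
        from .transcripts import parse_transcript

        return {
            t.participant_id: parse_transcript(t).tokens
            for t in self.transcripts
            if t.picture is picture
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        (out_dir / "transcripts").mkdir(parents=True, exist_ok=True)
        rows = []
        for t in self.transcripts:
            rel = f"transcripts/{t.participant_id}_{t.picture.value}.txt"
            write_transcript(t, out_dir / rel)
            scores = {
                k: float(v)
                for k, v in self.participants.loc[t.participant_id].items()
                if k != "group"
            }
            rows.append(ManifestRow(t.participant_id, t.group, t.picture, rel, scores))
        write_manifest(rows, out_dir / "manifest.csv")
        self.lexicon.to_csv(out_dir / "norms.csv")
        (out_dir / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=1, sort_keys=True))


def generate_cohort(
    spec: CohortSpec | None = None, seed: int = 0, lexicon: NormsLexicon | None = None
) -> SyntheticCohort:
    """Generate a full cohort: lexicon, both pictures per participant,
    cognitive scores and attached ground truth.  Reproducible from (spec, seed).

    Pass ``lexicon`` to share one vocabulary across cohorts (e.g. a disjoint
    out-of-sample test cohort speaks the same language as the training one).
    """
    spec = spec or CohortSpec()
    if not spec.group_sizes:
        raise ValueError("need at least one group")
    ss = np.random.SeedSequence(seed)
    norms_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    if lexicon is None:
        named = [w for pic in spec.pictures for w in PICTURE_WORDS[pic]]
        named = list(dict.fromkeys(named))
        lexicon = generate_norms(spec.n_words, norms_seed, named_words=named)
    transcripts: list[RawTranscript] = []
    part_rows = {}
    truth_by_participant: dict[str, dict] = {}
    norms_df = lexicon.to_frame().set_index("word")
    idx = 0
    for group in [g for g in Group if g in spec.group_sizes]:
        profile = spec.profiles[group]
        for _ in range(spec.group_sizes[group]):
            pid = f"{spec.id_prefix}{idx:03d}"
            idx += 1
            child = np.random.default_rng(ss.spawn(1)[0])
            scores = {
                name: round(float(np.clip(child.normal(m, sd), 0, None)), 1)
                for name, (m, sd) in profile.cognitive.items()
            }
            part_rows[pid] = {"group": group.value, **scores}
            truth_by_participant[pid] = {}
            for pic in spec.pictures:
                raw, truth = generate_transcript(
                    profile, lexicon, pic, child, participant_id=pid, _norms_df=norms_df
                )
                transcripts.append(raw)
                truth_by_participant[pid][pic.value] = truth
    participants = pd.DataFrame(part_rows).T
    participants.index.name = "participant_id"
    ground_truth = {
        "seed": seed,
        "group_sizes": {g.value: int(n) for g, n in spec.group_sizes.items()},
        "planted_tilts": {g.value: dict(spec.profiles[g].tilt) for g in spec.group_sizes},
        "planted_production": {
            pic.value: {
                g.value: {w: spec.profiles[g].production_prob(pic, w) for w in PICTURE_WORDS[pic]}
                for g in spec.group_sizes
            }
            for pic in spec.pictures
        },
        "per_participant": truth_by_participant,
    }
    return SyntheticCohort(
        lexicon=lexicon,
        transcripts=transcripts,
        participants=participants,
        ground_truth=ground_truth,
        seed=seed,
    )


def null_spec(n_per_group: int = 20, groups: tuple[Group, Group] = (Group.control, Group.svPPA),
              n_words: int = 200) -> CohortSpec:
    """Two groups generated by the *identical* process (the control profile):
    any downstream classification signal is leakage or chance."""
    # pin word production explicitly: the per-group slot defaults would
    # otherwise differ by diagnostic label, which is exactly what a null
    # cohort must not do
    base = replace(
        default_profiles()[Group.control],
        word_production={w: 0.6 for w in PICTURE_WORDS[Picture.cookie_theft]},
    )
    return CohortSpec(
        group_sizes={groups[0]: n_per_group, groups[1]: n_per_group},
        profiles={groups[0]: base, groups[1]: replace(base, group=groups[1])},
        n_words=n_words,
        pictures=(Picture.cookie_theft,),
    )
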