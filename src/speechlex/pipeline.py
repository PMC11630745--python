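"""Staged pipeline: quantify -> annotate -> pca -> distribution -> checklist -> validate.

Each stage reads only serialized artifacts (CSV/JSON) from the run directory,
so the pipeline is restartable at any stage, and a rerun with the same config
and seed is byte-identical.  The YAML config carries every tunable parameter
(quartile edges are fixed by the method; k folds, seeds, lambda grid and the
rank tie-break order are explicit).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import checklist as cl
from . import distribution as dist
from . import pca as pca_mod
from .fluency import FUNCTION_WORDS, FluencyProfile, fluency_profile
from .norms import PROPERTY_NAMES, NormsLexicon, annotate_content_words
from .simulate import CohortSpec, generate_cohort
from .transcripts import Group, Picture, parse_transcript, read_manifest, read_transcript

logger = logging.getLogger(__name__)

_FLOAT = "%.10g"

FLUENCY_LABELS = ["speech quanta", "lexical richness", "speech complexity"]
WORD_LABELS = ["length", "semantic richness", "acquisition age"]


@dataclass
class RunConfig:
    cohort_dir: str = "cohort"
    out_dir: str = "run"
    test_cohort_dir: str | None = None  # disjoint cohort for out-of-sample validation
    seed: int = 0
    simulate: bool = False  # generate the cohort into cohort_dir first
    simulate_n_words: int = 500
    k_folds: int = 4
    n_lambdas: int = 30
    top_n_words: int = 15
    n_components: int | None = 3  # scree override; None = pure elbow selection
    varimax_tol: float = 1e-8
    merge_psp_cbs: bool = True
    min_producers: int = 2  # screen out words produced by fewer participants

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _load_cohort(cohort_dir: Path):
    manifest = read_manifest(cohort_dir / "manifest.csv")
    transcripts = {}
    for row in manifest:
        raw = read_transcript(cohort_dir / row.path)
        transcripts[(row.participant_id, row.picture)] = parse_transcript(raw)
    lexicon = NormsLexicon.from_csv(cohort_dir / "norms.csv")
    return manifest, transcripts, lexicon


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig) -> None:
    cohort = generate_cohort(CohortSpec(n_words=cfg.simulate_n_words), seed=cfg.seed)
    cohort.write(cfg.cohort_dir)
    if cfg.test_cohort_dir:
        # the held-out cohort speaks the same language: shared lexicon,
        # independent participants
        test = generate_cohort(
            CohortSpec(n_words=cfg.simulate_n_words, id_prefix="tst"),
            seed=cfg.seed + 1,
            lexicon=cohort.lexicon,
        )
        test.write(cfg.test_cohort_dir)


def stage_quantify(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, transcripts, _ = _load_cohort(Path(cfg.cohort_dir))
    records = []
    for row in manifest:
        prof = fluency_profile(transcripts[(row.participant_id, row.picture)])
        records.append({"participant_id": row.participant_id, "group": row.group.value,
                        "picture": row.picture.value, **prof.to_dict()})
    wide = pd.DataFrame(records)
    wide.to_csv(out / "fluency_wide.csv", index=False, float_format=_FLOAT)
    long = wide.melt(id_vars=["participant_id", "group", "picture"],
                     var_name="measure", value_name="value")
    long.to_csv(out / "fluency_long.csv", index=False, float_format=_FLOAT)


def stage_annotate(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    manifest, transcripts, lexicon = _load_cohort(Path(cfg.cohort_dir))
    records, coverage = [], []
    for row in manifest:
        annotated, report = annotate_content_words(
            transcripts[(row.participant_id, row.picture)], lexicon
        )
        for tok, norms in annotated:
            records.append({"participant_id": row.participant_id, "group": row.group.value,
                            "picture": row.picture.value, "token": tok, "word": norms.word})
        coverage.append({"participant_id": row.participant_id, "picture": row.picture.value,
                         "total_tokens": report.total_tokens, "function_tokens": report.function_tokens,
                         "annotated_tokens": report.annotated_tokens,
                         "dropped_tokens": report.dropped_tokens,
                         "fallback_tokens": report.fallback_tokens})
    pd.DataFrame(records).to_csv(out / "annotated_tokens.csv", index=False)
    pd.DataFrame(coverage).to_csv(out / "annotation_coverage.csv", index=False)


def _kmo_or_none(df: pd.DataFrame, what: str) -> float | None:
    """Sampling adequacy is diagnostic; degenerate inputs (e.g. collinear
    counts in very small cohorts) report None instead of aborting the run."""
    try:
        return pca_mod.kmo(df)
    except ValueError as exc:
        logger.warning("KMO unavailable for %s: %s", what, exc)
        return None


def _drop_constant(df: pd.DataFrame, what: str) -> pd.DataFrame:
    sd = df.std(ddof=1)
    constant = list(df.columns[sd == 0])
    if constant:
        logger.warning("%s: dropping constant features %s", what, constant)
    return df.loc[:, sd > 0]


def stage_pca(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    _, _, lexicon = _load_cohort(Path(cfg.cohort_dir))

    # fluency PCA: rows are participant x picture observations
    wide = pd.read_csv(out / "fluency_wide.csv")
    feats = _drop_constant(wide[list(FluencyProfile.MEASURES)].dropna(), "fluency measures")
    kmo_fluency = _kmo_or_none(feats, "fluency")
    eig = np.linalg.eigvalsh(np.corrcoef(
        ((feats - feats.mean()) / feats.std(ddof=1)).to_numpy(), rowvar=False))[::-1]
    k_flu = pca_mod.scree_select(eig, override=cfg.n_components)
    flu = pca_mod.pca_varimax(feats, k_flu, component_labels=FLUENCY_LABELS[:k_flu], tol=cfg.varimax_tol)
    flu.to_json(out / "fluency_pca.json")
    scores = wide.loc[feats.index, ["participant_id", "group", "picture"]].copy()
    scores = pd.concat([scores, flu.row_scores], axis=1)
    scores.to_csv(out / "fluency_pc_scores.csv", index=False, float_format=_FLOAT)

    # word-properties PCA on the pooled unique-word speech corpus
    tokens = pd.read_csv(out / "annotated_tokens.csv")
    corpus = sorted(tokens["word"].unique())
    mat = pd.DataFrame(
        [lexicon.lookup(w).norms.vector() for w in corpus], index=corpus, columns=list(PROPERTY_NAMES)
    ).dropna()
    mat = _drop_constant(mat, "word properties")
    kmo_words = _kmo_or_none(mat, "word properties")
    eig_w = np.linalg.eigvalsh(np.corrcoef(
        ((mat - mat.mean()) / mat.std(ddof=1)).to_numpy(), rowvar=False))[::-1]
    k_w = pca_mod.scree_select(eig_w, override=cfg.n_components)
    wpca = pca_mod.pca_varimax(mat, k_w, component_labels=WORD_LABELS[:k_w], tol=cfg.varimax_tol)
    wpca.to_json(out / "word_pca.json")
    wpca.row_scores.rename_axis("word").to_csv(out / "word_pc_scores.csv", float_format=_FLOAT)

    # participant-averaged word scores, per picture
    frames = []
    for pic, sub in tokens.groupby("picture"):
        by_part = {pid: g["word"].tolist() for pid, g in sub.groupby("participant_id")}
        means, flagged = pca_mod.project_words_and_average(wpca.row_scores, by_part)
        if flagged:
            logger.warning("picture %s: participants with no scorable tokens: %s", pic, flagged)
        means.insert(0, "picture", pic)
        frames.append(means.reset_index())
    pd.concat(frames).to_csv(out / "participant_word_scores.csv", index=False, float_format=_FLOAT)

    meta = wide[["participant_id", "group", "picture"]]
    pw = pd.read_csv(out / "participant_word_scores.csv").merge(
        meta.drop_duplicates(), on=["participant_id", "picture"])
    comp_cols = [c for c in pw.columns if c.startswith("PC")]
    anova = {
        "fluency_one_way": {
            comp: {k2: v for k2, v in res.items() if k2 in ("F", "p", "df")}
            for comp, res in pca_mod.pc_group_tests(
                flu.row_scores, wide.loc[feats.index, "group"]).items()
        },
        "word_two_way": {
            comp: {k2: v for k2, v in res.items() if not k2.startswith("anova")}
            for comp, res in pca_mod.pc_group_tests(
                pw[comp_cols], pw["group"], task=pw["picture"]).items()
        },
        "kmo": {"fluency": kmo_fluency, "words": kmo_words},
        "k": {"fluency": k_flu, "words": k_w},
        "explained_variance": {
            "fluency": flu.total_explained_variance, "words": wpca.total_explained_variance
        },
    }
    _write_json(anova, out / "pca_tests.json")


def stage_distribution(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    tokens = pd.read_csv(out / "annotated_tokens.csv")
    wscores = pd.read_csv(out / "word_pc_scores.csv").set_index("word")
    comp_cols = list(wscores.columns)
    tok = tokens.merge(wscores, left_on="word", right_index=True)
    count_rows, map_rows, diff_rows, anova_out = [], [], [], {}
    for pic, sub in tok.groupby("picture"):
        groups = sub.groupby("participant_id")["group"].first()
        for comp in comp_cols:
            by_part = {pid: g[comp].to_numpy() for pid, g in sub.groupby("participant_id")}
            table = dist.quartile_count_table(by_part)
            for pid, row in table.iterrows():
                count_rows.append({"picture": pic, "component": comp, "participant_id": pid,
                                   "group": groups[pid], **row.to_dict()})
            anova_out[f"{pic}/{comp}"] = {
                k2: v for k2, v in dist.quartile_rm_anova(table, groups).items()
                if not isinstance(v, pd.DataFrame)
            }
        # bivariate maps on the first two components
        x, y = comp_cols[0], comp_cols[1]
        maps_by_group: dict[str, list] = {}
        for pid, g in sub.groupby("participant_id"):
            m = dist.proportion_map(g[x].to_numpy(), g[y].to_numpy(), axes=(x, y))
            maps_by_group.setdefault(groups[pid], []).append(m)
        mean_maps = {grp: dist.group_mean_map(ms) for grp, ms in maps_by_group.items()}
        for grp, m in mean_maps.items():
            for i in range(4):
                for j in range(4):
                    map_rows.append({"picture": pic, "group": grp, "x_bin": i, "y_bin": j,
                                     "proportion": m.grid[i, j]})
        ctrl = Group.control.value
        if ctrl in maps_by_group:
            for grp, ms in maps_by_group.items():
                if grp == ctrl or len(ms) < 2:
                    continue
                d = dist.difference_map(ms, maps_by_group[ctrl])
                for i in range(4):
                    for j in range(4):
                        diff_rows.append({"picture": pic, "group": grp, "x_bin": i, "y_bin": j,
                                          "difference": d.grid[i, j], "t": d.t[i, j], "p": d.p[i, j]})
    pd.DataFrame(count_rows).to_csv(out / "quartile_counts.csv", index=False, float_format=_FLOAT)
    pd.DataFrame(map_rows).to_csv(out / "group_maps.csv", index=False, float_format=_FLOAT)
    pd.DataFrame(diff_rows).to_csv(out / "difference_maps.csv", index=False, float_format=_FLOAT)
    # cellwise p-values are reported uncorrected (the maps are descriptive);
    # note emitted so downstream readers see the multiplicity caveat
    anova_out["note"] = "difference-map cell p-values are uncorrected two-tailed Welch t-tests"
    _write_json(anova_out, out / "distribution_tests.json")


def _checklist_inputs(cfg: RunConfig, cohort_dir: Path, picture: Picture):
    manifest, transcripts, _ = _load_cohort(cohort_dir)
    tokens_by_part = {
        r.participant_id: transcripts[(r.participant_id, r.picture)].tokens
        for r in manifest if r.picture is picture
    }
    groups = pd.Series({r.participant_id: r.group.value for r in manifest if r.picture is picture})
    cognitive = pd.DataFrame({r.participant_id: r.scores for r in manifest if r.picture is picture}).T
    return tokens_by_part, groups, cognitive


def stage_derive_checklist(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    for picture in Picture:
        tokens_by_part, groups, _ = _checklist_inputs(cfg, Path(cfg.cohort_dir), picture)
        if not tokens_by_part:
            continue
        classes = cl.unique_word_classes(
            tokens_by_part, function_list=FUNCTION_WORDS, min_producers=cfg.min_producers
        )
        indicator = cl.build_indicator_matrix(tokens_by_part, classes)
        pooled = cl.pairwise_selection(indicator, groups, cv_folds=cfg.k_folds,
                                       seed=cfg.seed, n_lambdas=cfg.n_lambdas)
        by_target = {c.target: c for c in classes}
        table, checklist = cl.rank_and_truncate(
            indicator, groups, pooled, by_target, picture.value,
            top_n=cfg.top_n_words, cv_folds=cfg.k_folds, seed=cfg.seed, n_lambdas=cfg.n_lambdas,
        )
        table.to_csv(out / f"ranked_words_{picture.value}.csv", index=False, float_format=_FLOAT)
        checklist.to_csv(out / f"checklist_{picture.value}.csv")
        _write_json(
            {
                "pooled_words": pooled.pooled_words,
                "n_candidate_words": int(indicator.shape[1]),
                "zero_word_contrasts": [list(c) for c in pooled.zero_word_contrasts],
                "per_contrast": {f"{a}_vs_{b}": words for (a, b), words in pooled.per_contrast.items()},
            },
            out / f"selection_{picture.value}.json",
        )


def read_checklist_csv(path: str | Path) -> cl.Checklist:
    df = pd.read_csv(path)
    classes, seen = [], set()
    for _, row in df.iterrows():
        if row["target"] in seen:
            continue
        seen.add(row["target"])
        classes.append(cl.EquivalenceClass(row["target"], frozenset(str(row["variants"]).split("|"))))
    return cl.Checklist(picture=df["picture"].iloc[0] if len(df) else "", classes=classes)


def stage_validate(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    results: dict = {}
    for picture in Picture:
        path = out / f"checklist_{picture.value}.csv"
        if not path.exists():
            continue
        checklist = read_checklist_csv(path)
        tokens_by_part, groups, cognitive = _checklist_inputs(cfg, Path(cfg.cohort_dir), picture)
        indicator = cl.build_indicator_matrix(tokens_by_part, checklist.classes)
        pic_res = {
            "kfold": {
                name: rep.to_dict()
                for name, rep in cl.hierarchical_validate(
                    indicator, groups, scheme="kfold", seed=cfg.seed, k=cfg.k_folds,
                    merge_psp_cbs=cfg.merge_psp_cbs, n_lambdas=cfg.n_lambdas,
                ).items()
            }
        }
        if not cognitive.empty:
            augmented, _ = cl.augment_with_cognitive(indicator, cognitive)
            pic_res["kfold_with_cognitive"] = {
                name: rep.to_dict()
                for name, rep in cl.hierarchical_validate(
                    augmented, groups.loc[augmented.index], scheme="kfold", seed=cfg.seed,
                    k=cfg.k_folds, merge_psp_cbs=cfg.merge_psp_cbs, n_lambdas=cfg.n_lambdas,
                ).items()
            }
        if cfg.test_cohort_dir:
            t_tokens, t_groups, _ = _checklist_inputs(cfg, Path(cfg.test_cohort_dir), picture)
            if t_tokens:
                t_ind = cl.build_indicator_matrix(t_tokens, checklist.classes)
                pic_res["out_of_sample"] = {
                    name: rep.to_dict()
                    for name, rep in cl.hierarchical_validate(
                        indicator, groups, scheme="out_of_sample", seed=cfg.seed,
                        merge_psp_cbs=cfg.merge_psp_cbs, test_indicator=t_ind,
                        test_groups=t_groups, n_lambdas=cfg.n_lambdas,
                    ).items()
                }
        results[picture.value] = pic_res
    _write_json(results, out / "validation.json")


STAGES = (
    "quantify",
    "annotate",
    "pca",
    "distribution",
    "derive-checklist",
    "validate",
)

_STAGE_FN = {
    "quantify": stage_quantify,
    "annotate": stage_annotate,
    "pca": stage_pca,
    "distribution": stage_distribution,
    "derive-checklist": stage_derive_checklist,
    "validate": stage_validate,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage in order; returns the run directory.

    Pre-flight checks that all referenced inputs exist (after simulation if
    configured); each artifact directory is stamped with the config hash and
    seed so reruns are auditable.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        stage_simulate(cfg)
    cohort = Path(cfg.cohort_dir)
    for required in ("manifest.csv", "norms.csv"):
        if not (cohort / required).exists():
            raise FileNotFoundError(f"pre-flight: missing {cohort / required}")
    _write_json({"config_hash": cfg.config_hash(), "seed": cfg.seed}, out / "run_meta.json")
    cfg.to_yaml(out / "config.yaml")
    for name in STAGES:
        try:
            _STAGE_FN[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed on cohort {cfg.cohort_dir!r}: {exc}") from exc
    return out
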