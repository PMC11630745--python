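"""Data-driven word checklists: derivation, fitting and validation.

Whether a participant produced each candidate word is coded 1/0, with
dialect synonyms (boy/chap/lad/bloke) and inflectional variants
(plate/plates, digging/dig) collapsed into equivalence classes.  Candidate
words are screened by L1-penalized (LASSO) logistic regressions for every
pairwise group contrast; the selected words are pooled, the regressions
re-run on the pooled list, and words rank-ordered by (i) how many pairwise
models keep them, (ii) their largest |beta|, and (iii) the largest
between-group difference in production proportion.  The top 15 form the
checklist, validated by stratified k-fold cross-validation and on a held-out
cohort, hierarchically: patients vs controls, then "motor" (nfvPPA/PSP/CBS)
vs "lexico-semantic" (svPPA/lvPPA), then pairs within each cluster.
Cognitive sub-scores (ACE-R/MLSE) can supplement the word indicators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .transcripts import Group, LEXICOSEMANTIC_GROUPS, MOTOR_GROUPS

logger = logging.getLogger(__name__)

_VOWELS = set("aeiou")


def root(word: str) -> str:
    """Inflectional root: strip -s/-es/-ies/-ing/-ed/-en, undoing doubling.

    digging -> dig, plates -> plate, carries -> carry.  Heuristic by design;
    explicit variant lists take precedence wherever classes are matched.
    """
    w = word.lower()

    def undouble(stem: str) -> str:
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]
        return stem

    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    for suf in ("ing", "ed", "en"):
        if w.endswith(suf) and len(w) - len(suf) >= 2:
            return undouble(w[: -len(suf)])
    if w.endswith("es") and len(w) > 4 and w[:-2].endswith(("s", "x", "z", "ch", "sh")):
        return w[:-2]  # dishes -> dish, glasses -> glass
    if w.endswith("s") and not w.endswith("ss") and len(w) > 3:
        return w[:-1]  # plates -> plate
    return w


def roots_match(a: str, b: str) -> bool:
    """Root equality, tolerating the dropped silent -e (baking vs bake)."""
    ra, rb = root(a), root(b)
    return ra == rb or ra + "e" == rb or rb + "e" == ra


@dataclass(frozen=True)
class EquivalenceClass:
    """A checklist target word plus its dialect/inflectional variants."""

    target: str
    variants: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "target", self.target.lower())
        object.__setattr__(self, "variants", frozenset(v.lower() for v in self.variants) | {self.target})

    def matches(self, token: str) -> bool:
        token = token.lower()
        if token in self.variants:
            return True
        return any(roots_match(token, v) for v in self.variants)


def score_word(produced_tokens: Sequence[str], eq_class: EquivalenceClass) -> int:
    """1 iff any produced token belongs to the equivalence class."""
    return int(any(eq_class.matches(t) for t in produced_tokens))


def build_indicator_matrix(
    tokens_by_participant: Mapping[str, Sequence[str]],
    classes: Sequence[EquivalenceClass],
) -> pd.DataFrame:
    """Participants x classes binary production matrix."""
    targets = [c.target for c in classes]
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate equivalence-class targets")
    pids = list(tokens_by_participant)
    if len(set(pids)) != len(pids):
        raise ValueError("duplicate participants")
    data = {
        c.target: [score_word(tokens_by_participant[p], c) for p in pids] for c in classes
    }
    df = pd.DataFrame(data, index=pids)
    df.index.name = "participant_id"
    return df


def unique_word_classes(
    tokens_by_participant: Mapping[str, Sequence[str]],
    function_list: frozenset[str] = frozenset(),
    min_producers: int = 1,
) -> list[EquivalenceClass]:
    """One equivalence class per inflectional root of the produced content words.

    This is the "all unique words produced" predictor set for the screening
    regressions: every content word any participant produced, with its
    observed inflectional variants collapsed onto the most frequent form.
    """
    by_root: dict[str, dict[str, int]] = {}
    for tokens in tokens_by_participant.values():
        for t in tokens:
            if t in function_list:
                continue
            by_root.setdefault(root(t), {}).setdefault(t, 0)
            by_root[root(t)][t] += 1
    # fold e-tolerant root pairs (plates -> "plat" joins plate -> "plate")
    for key in sorted(by_root):
        if key.endswith("e") and key[:-1] in by_root:
            for form, n in by_root.pop(key).items():
                by_root[key[:-1]][form] = by_root[key[:-1]].get(form, 0) + n
    classes = []
    for _, forms in sorted(by_root.items()):
        target = max(forms, key=lambda w: (forms[w], -len(w), w))
        classes.append(EquivalenceClass(target=target, variants=frozenset(forms)))
    if min_producers > 1:
        produced = build_indicator_matrix(tokens_by_participant, classes)
        keep = produced.sum(axis=0) >= min_producers
        classes = [c for c in classes if keep[c.target]]
    return classes


# ---------------------------------------------------------------------------
# L1-penalized logistic regression


@dataclass
class LassoFit:
    """A cross-validated L1 logistic fit over a decreasing lambda path."""

    columns: list[str]
    lambda_path: np.ndarray
    cv_deviance: np.ndarray  # mean per-observation binomial deviance per lambda
    selected_lambda: float
    intercept: float
    betas: pd.Series
    seed: int
    cv_folds: int
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def selected_words(self) -> list[str]:
        return [c for c, b in self.betas.items() if abs(b) > 1e-10]


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 5000, tol: float = 1e-10):
    """One L1-logistic solve at penalty lambda on the (1/n)*loss scale.

    Coordinate descent via liblinear; the intercept rides along as a scaled
    pseudo-feature, so its residual penalty is O(lambda / intercept_scaling)
    and numerically negligible.
    """
    n = X.shape[0]
    clf = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        solver="liblinear",
        C=1.0 / (n * lam),
        intercept_scaling=1e6,
        max_iter=max_iter,
        tol=tol,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(X, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def _deviance(y: np.ndarray, prob: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-2 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int, min_ratio: float) -> np.ndarray:
    """Decreasing path from the smallest lambda that zeroes every coefficient."""
    ybar = y.mean()
    lam_max = np.max(np.abs(X.T @ (y - ybar))) / len(y)
    lam_max = max(lam_max, 1e-6)
    return lam_max * np.logspace(0, np.log10(min_ratio), n_lambdas)


def fit_lasso_logistic(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    cv_folds: int = 4,
    seed: int = 0,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
) -> LassoFit:
    """L1 logistic regression with k-fold CV choice of the penalty.

    The selected lambda minimizes mean cross-validated binomial deviance;
    ties go to the larger lambda (parsimony).  Binary 0/1 predictors are
    deliberately *not* standardized (a shared scale keeps |beta| comparable
    across words for the ranking step); continuous supplements should be
    z-scored upstream.  The model is refit on all rows at the chosen lambda.
    Constant columns are dropped (and recorded).  Complete separation is
    handled by the penalty itself: betas stay finite for lambda > 0.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("y must contain exactly two classes")
    sd = X.std(axis=0, ddof=0)
    dropped = [str(c) for c in X.columns[sd == 0]]
    if dropped:
        logger.info("dropping %d constant columns: %s", len(dropped), dropped[:8])
        X = X.loc[:, sd > 0]
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    folds = min(cv_folds, int(counts.min()))
    if folds < cv_folds:
        logger.warning("reducing CV folds from %d to %d (smallest class)", cv_folds, folds)
    lams = lambda_grid(Xv, y, n_lambdas, lambda_min_ratio)

    if X.shape[1] == 0:
        base = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        return LassoFit(
            columns=[], lambda_path=lams, cv_deviance=np.full(len(lams), np.nan),
            selected_lambda=float(lams[0]), intercept=float(np.log(base / (1 - base))),
            betas=pd.Series(dtype=float), seed=seed, cv_folds=folds, dropped_columns=dropped,
        )

    dev = np.zeros(len(lams))
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(Xv, y))
        for li, lam in enumerate(lams):
            fold_dev = []
            for tr, te in splits:
                b0, b = _fit_l1(Xv[tr], y[tr], lam, max_iter=1000, tol=1e-6)
                prob = 1.0 / (1.0 + np.exp(-(b0 + Xv[te] @ b)))
                fold_dev.append(_deviance(y[te], prob))
            dev[li] = float(np.mean(fold_dev))
        best = int(np.argmin(np.round(dev, 10)))  # ties -> first = larger lambda
    else:
        logger.warning("too few members per class for CV; using mid-path lambda")
        dev[:] = np.nan
        best = len(lams) // 2
    sel = float(lams[best])
    b0, b = _fit_l1(Xv, y, sel)
    return LassoFit(
        columns=[str(c) for c in X.columns],
        lambda_path=lams,
        cv_deviance=dev,
        selected_lambda=sel,
        intercept=b0,
        betas=pd.Series(b, index=[str(c) for c in X.columns]),
        seed=seed,
        cv_folds=folds,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# Pairwise screening, pooling, ranking


def pairwise_contrasts(groups: Sequence[Group | str]) -> list[tuple[str, str]]:
    """Control-vs-patient contrasts first, then patient-vs-patient pairs."""
    labels = []
    for g in groups:
        g = Group(g).value if not isinstance(g, Group) else g.value
        if g not in labels:
            labels.append(g)
    order = [g.value for g in Group if g.value in labels]
    pairs = []
    if Group.control.value in order:
        pairs += [(Group.control.value, g) for g in order if g != Group.control.value]
    patients = [g for g in order if g != Group.control.value]
    pairs += list(combinations(patients, 2))
    return pairs


@dataclass
class PooledSelection:
    per_contrast: dict[tuple[str, str], list[str]]
    pooled_words: list[str]
    zero_word_contrasts: list[tuple[str, str]]


def pairwise_selection(
    indicator: pd.DataFrame,
    groups: pd.Series,
    cv_folds: int = 4,
    seed: int = 0,
    n_lambdas: int = 30,
) -> PooledSelection:
    """LASSO screening over every pairwise group contrast; union the survivors.

    Contrasts where the penalty eliminates every word are recorded -- these
    are the contrasts word production alone cannot separate, and they
    motivate the hierarchical classification stages.
    """
    groups = pd.Series(groups, index=indicator.index).astype(str)
    per_contrast: dict[tuple[str, str], list[str]] = {}
    zero = []
    pooled: list[str] = []
    for a, b in pairwise_contrasts(groups.unique()):
        mask = groups.isin([a, b])
        sub = indicator.loc[mask]
        y = (groups[mask] == b).to_numpy(dtype=int)
        if min((y == 0).sum(), (y == 1).sum()) < 4:
            logger.warning("contrast %s vs %s: a group has <4 members; CV folds reduced", a, b)
        fit = fit_lasso_logistic(sub, y, cv_folds=cv_folds, seed=seed, n_lambdas=n_lambdas)
        sel = fit.selected_words
        per_contrast[(a, b)] = sel
        if not sel:
            zero.append((a, b))
        for w in sel:
            if w not in pooled:
                pooled.append(w)
    return PooledSelection(per_contrast=per_contrast, pooled_words=sorted(pooled), zero_word_contrasts=zero)


def proportion_difference(column: pd.Series, groups: pd.Series, a: str, b: str) -> float:
    """|production proportion in group a - production proportion in group b|."""
    groups = pd.Series(groups, index=column.index).astype(str)
    ma, mb = groups == a, groups == b
    if not ma.any() or not mb.any():
        raise ValueError(f"empty group in contrast {a} vs {b}")
    return float(abs(column[ma].mean() - column[mb].mean()))


@dataclass
class Checklist:
    picture: str
    classes: list[EquivalenceClass]
    coefficients: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    @property
    def targets(self) -> list[str]:
        return [c.target for c in self.classes]

    def to_csv(self, path: str | Path) -> None:
        """Scoresheet CSV: picture,target,variants(|-separated),contrast,beta."""
        rows = []
        for c in self.classes:
            variants = "|".join(sorted(c.variants))
            wrote = False
            for (a, b), betas in sorted(self.coefficients.items()):
                if c.target in betas.index and abs(betas[c.target]) > 1e-10:
                    rows.append((self.picture, c.target, variants, f"{a}_vs_{b}", f"{betas[c.target]:.10g}"))
                    wrote = True
            if not wrote:
                rows.append((self.picture, c.target, variants, "", ""))
        pd.DataFrame(rows, columns=["picture", "target", "variants", "contrast", "beta"]).to_csv(
            path, index=False
        )


def rank_and_truncate(
    indicator: pd.DataFrame,
    groups: pd.Series,
    pooled: PooledSelection,
    classes_by_target: Mapping[str, EquivalenceClass],
    picture: str,
    top_n: int = 15,
    cv_folds: int = 4,
    seed: int = 0,
    n_lambdas: int = 30,
) -> tuple[pd.DataFrame, Checklist]:
    """Re-run each pairwise LASSO on the pooled words, rank, keep the top 15.

    Ranking is lexicographic: appearance count across pairwise models (desc),
    then max |beta| (desc), then max between-group production-proportion
    difference (desc), then alphabetical for full determinism.
    """
    groups = pd.Series(groups, index=indicator.index).astype(str)
    if not pooled.pooled_words:
        logger.warning("empty pooled word set: empty checklist")
        table = pd.DataFrame(columns=["word", "appearance_count", "max_abs_beta", "proportion_difference", "rank"])
        return table, Checklist(picture=picture, classes=[])
    sub_ind = indicator[pooled.pooled_words]
    appearance = {w: 0 for w in pooled.pooled_words}
    max_beta = {w: 0.0 for w in pooled.pooled_words}
    prop_diff = {w: 0.0 for w in pooled.pooled_words}
    coefficients: dict[tuple[str, str], pd.Series] = {}
    for a, b in pairwise_contrasts(groups.unique()):
        mask = groups.isin([a, b])
        y = (groups[mask] == b).to_numpy(dtype=int)
        fit = fit_lasso_logistic(sub_ind.loc[mask], y, cv_folds=cv_folds, seed=seed, n_lambdas=n_lambdas)
        coefficients[(a, b)] = fit.betas
        for w in fit.selected_words:
            appearance[w] += 1
            max_beta[w] = max(max_beta[w], abs(fit.betas[w]))
        for w in pooled.pooled_words:
            prop_diff[w] = max(prop_diff[w], proportion_difference(indicator[w], groups, a, b))
    table = pd.DataFrame(
        {
            "word": pooled.pooled_words,
            "appearance_count": [appearance[w] for w in pooled.pooled_words],
            "max_abs_beta": [max_beta[w] for w in pooled.pooled_words],
            "proportion_difference": [prop_diff[w] for w in pooled.pooled_words],
        }
    ).sort_values(
        by=["appearance_count", "max_abs_beta", "proportion_difference", "word"],
        ascending=[False, False, False, True],
        kind="stable",
    )
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.reset_index(drop=True)
    top = table.head(top_n)["word"].tolist()
    if len(top) < top_n:
        logger.warning("checklist has only %d words (pooled set smaller than %d)", len(top), top_n)
    checklist = Checklist(
        picture=picture,
        classes=[classes_by_target[w] for w in top],
        coefficients={k: v.loc[[w for w in top if w in v.index]] for k, v in coefficients.items()},
    )
    return table, checklist


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Classification outcome for one contrast (positive class = index 1)."""

    contrast: str
    scheme: str  # "kfold" | "out_of_sample"
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    accuracy: float
    sensitivity: float
    specificity: float
    predictions: pd.DataFrame
    seed: int

    @classmethod
    def from_predictions(
        cls, contrast: str, scheme: str, y_true, y_pred, prob, index, seed: int
    ) -> "ValidationReport":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        conf = np.array([[tn, fp], [fn, tp]])
        acc = (tn + tp) / conf.sum()
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        preds = pd.DataFrame({"y_true": y_true, "y_pred": y_pred, "prob": prob}, index=index)
        return cls(contrast, scheme, conf, float(acc), float(sens), float(spec), preds, seed)

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "scheme": self.scheme,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "seed": self.seed,
        }


def kfold_validate(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    contrast: str = "",
    k: int = 4,
    seed: int = 0,
    n_lambdas: int = 30,
) -> ValidationReport:
    """Stratified k-fold validation with threshold 0.5 on predicted probability.

    Within each fold, the LASSO (including its inner CV penalty choice and any
    implicit word selection) sees the training rows only, so selection cannot
    leak into the held-out fold.
    """
    y = np.asarray(y, dtype=int)
    k_eff = min(k, int(np.bincount(y).min()))
    if k_eff < 2:
        raise ValueError("a class is too small for k-fold validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    y_pred = np.zeros_like(y)
    prob_all = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        fit = fit_lasso_logistic(X.iloc[tr], y[tr], cv_folds=min(4, k_eff), seed=seed, n_lambdas=n_lambdas)
        prob = _predict(fit, X.iloc[te])
        prob_all[te] = prob
        y_pred[te] = (prob > 0.5).astype(int)
    return ValidationReport.from_predictions(contrast, "kfold", y, y_pred, prob_all, X.index, seed)


def nested_kfold_validate(
    indicator: pd.DataFrame,
    groups: pd.Series,
    y: np.ndarray | pd.Series,
    contrast: str = "",
    k: int = 4,
    seed: int = 0,
    top_n: int = 15,
    n_lambdas: int = 30,
) -> ValidationReport:
    """Strict nested validation: the whole checklist derivation (pairwise
    screening, pooling, ranking, truncation) is re-run inside each training
    fold, so not even the choice of the 15 words sees the held-out fold.

    This is the conservative alternative to validating a fixed published
    checklist (where only coefficients are re-estimated per fold); both are
    defensible readings of k-fold validation of a derived scoresheet.
    """
    groups = pd.Series(groups, index=indicator.index).astype(str)
    y = np.asarray(y, dtype=int)
    k_eff = min(k, int(np.bincount(y).min()))
    if k_eff < 2:
        raise ValueError("a class is too small for k-fold validation")
    classes = {c: EquivalenceClass(c) for c in indicator.columns}
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    y_pred = np.zeros_like(y)
    prob_all = np.zeros(len(y))
    for tr, te in skf.split(indicator, y):
        sub, sub_groups = indicator.iloc[tr], groups.iloc[tr]
        pooled = pairwise_selection(sub, sub_groups, seed=seed, n_lambdas=n_lambdas)
        if pooled.pooled_words:
            _, checklist = rank_and_truncate(
                sub, sub_groups, pooled, classes, picture="", top_n=top_n,
                seed=seed, n_lambdas=n_lambdas,
            )
            cols = checklist.targets
        else:
            cols = list(indicator.columns)  # degenerate fold: no screening signal
        fit = fit_lasso_logistic(sub[cols], y[tr], cv_folds=min(4, k_eff),
                                 seed=seed, n_lambdas=n_lambdas)
        prob = _predict(fit, indicator.iloc[te][cols])
        prob_all[te] = prob
        y_pred[te] = (prob > 0.5).astype(int)
    return ValidationReport.from_predictions(
        contrast, "nested_kfold", y, y_pred, prob_all, indicator.index, seed
    )


def oos_validate(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    contrast: str = "",
    seed: int = 0,
    n_lambdas: int = 30,
) -> ValidationReport:
    """Refit on the full training cohort, predict a disjoint test cohort."""
    overlap = set(X_train.index) & set(X_test.index)
    if overlap:
        raise ValueError(f"test cohort shares participants with training: {sorted(overlap)[:5]}")
    missing = [c for c in X_train.columns if c not in X_test.columns]
    if missing:
        raise ValueError(f"test matrix lacks columns {missing[:5]}")
    fit = fit_lasso_logistic(X_train, np.asarray(y_train, dtype=int), seed=seed, n_lambdas=n_lambdas)
    prob = _predict(fit, X_test[X_train.columns])
    y_pred = (prob > 0.5).astype(int)
    return ValidationReport.from_predictions(
        contrast, "out_of_sample", y_test, y_pred, prob, X_test.index, seed
    )


def _predict(fit: LassoFit, X: pd.DataFrame) -> np.ndarray:
    if not fit.columns:
        eta = np.full(len(X), fit.intercept)
    else:
        eta = fit.intercept + X[fit.columns].to_numpy(dtype=float) @ fit.betas.to_numpy()
    return 1.0 / (1.0 + np.exp(-eta))


def hierarchical_validate(
    indicator: pd.DataFrame,
    groups: pd.Series,
    scheme: str = "kfold",
    seed: int = 0,
    k: int = 4,
    merge_psp_cbs: bool = True,
    test_indicator: pd.DataFrame | None = None,
    test_groups: pd.Series | None = None,
    n_lambdas: int = 30,
) -> dict[str, ValidationReport]:
    """Three-stage hierarchical classification on a checklist indicator matrix.

    Stage 1: controls vs all patients.  Stage 2 (patients): motor
    (nfvPPA/PSP/CBS) vs lexico-semantic (svPPA/lvPPA).  Stage 3: pairs within
    each cluster; PSP and CBS are merged into one class by default (small
    samples).  ``scheme`` is "kfold" or "out_of_sample" (the latter needs the
    disjoint test cohort arguments).
    """
    if scheme not in ("kfold", "out_of_sample"):
        raise ValueError(f"unknown scheme {scheme!r}")
    oos = scheme == "out_of_sample"
    if oos and (test_indicator is None or test_groups is None):
        raise ValueError("out-of-sample validation needs a test cohort")
    groups = pd.Series(groups, index=indicator.index).astype(str)
    if oos:
        test_groups = pd.Series(test_groups, index=test_indicator.index).astype(str)
    motor = {g.value for g in MOTOR_GROUPS}
    lexsem = {g.value for g in LEXICOSEMANTIC_GROUPS}

    def stage(name, mask_fn, y_fn):
        m_tr = mask_fn(groups)
        y_tr = y_fn(groups[m_tr])
        if oos:
            m_te = mask_fn(test_groups)
            if m_te.sum() == 0 or len(np.unique(y_fn(test_groups[m_te]))) < 2:
                return None
            return oos_validate(
                indicator.loc[m_tr], y_tr, test_indicator.loc[m_te], y_fn(test_groups[m_te]),
                contrast=name, seed=seed, n_lambdas=n_lambdas,
            )
        return kfold_validate(indicator.loc[m_tr], y_tr, contrast=name, k=k, seed=seed, n_lambdas=n_lambdas)

    reports: dict[str, ValidationReport] = {}
    reports["controls_vs_patients"] = stage(
        "controls_vs_patients",
        lambda g: pd.Series(True, index=g.index),
        lambda g: (g != Group.control.value).to_numpy(dtype=int),
    )
    r = stage(
        "motor_vs_lexicosemantic",
        lambda g: g.isin(motor | lexsem),
        lambda g: g.isin(motor).to_numpy(dtype=int),
    )
    if r is not None:
        reports["motor_vs_lexicosemantic"] = r
    r = stage(
        "svPPA_vs_lvPPA",
        lambda g: g.isin({"svPPA", "lvPPA"}),
        lambda g: (g == "lvPPA").to_numpy(dtype=int),
    )
    if r is not None:
        reports["svPPA_vs_lvPPA"] = r
    if merge_psp_cbs:
        pairs = [("nfvPPA", ("PSP", "CBS"))]
    else:
        pairs = [("nfvPPA", ("PSP",)), ("nfvPPA", ("CBS",)), ("PSP", ("CBS",))]
    for a, bs in pairs:
        name = f"{a}_vs_{'+'.join(bs)}"
        r = stage(
            name,
            lambda g, a=a, bs=bs: g.isin({a, *bs}),
            lambda g, bs=bs: g.isin(bs).to_numpy(dtype=int),
        )
        if r is not None:
            reports[name] = r
    return {k_: v for k_, v in reports.items() if v is not None}


def augment_with_cognitive(
    indicator: pd.DataFrame, cognitive: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Append z-scored cognitive sub-score columns to the word indicators.

    All-missing or constant score columns are dropped with a warning; rows
    with any remaining missing score are dropped (listwise) and returned.
    Binary word columns are untouched, so downstream fitting is identical.
    """
    cognitive = cognitive.loc[cognitive.index.intersection(indicator.index)]
    keep_cols = []
    for c in cognitive.columns:
        col = cognitive[c]
        if col.isna().all():
            logger.warning("cognitive column %r is all-missing; dropped", c)
            continue
        if col.std(ddof=0) == 0 or np.isnan(col.std(ddof=0)):
            logger.warning("cognitive column %r is constant; dropped", c)
            continue
        keep_cols.append(c)
    cog = cognitive[keep_cols]
    complete = cog.dropna()
    dropped_rows = sorted(set(indicator.index) - set(complete.index))
    if dropped_rows:
        logger.info("dropping %d rows with incomplete cognitive scores", len(dropped_rows))
    rows = indicator.index.intersection(complete.index)
    z = (complete.loc[rows] - complete.loc[rows].mean()) / complete.loc[rows].std(ddof=1)
    out = pd.concat([indicator.loc[rows], z], axis=1)
    return out, [str(r) for r in dropped_rows]
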