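"""Varimax-rotated PCA with sampling-adequacy and scree-based selection.

Two PCAs are run in this pipeline: one on the 13 fluency measures
(rows = participant x picture observations) and one on the 8 psycholinguistic
properties of the pooled unique-word "speech corpus" (rows = words).  Both
use correlation-matrix PCA (features are z-scored: the measures mix counts,
ratios and minutes), retain k components by the scree elbow (maximum second
difference, i.e. maximum acceleration of the eigenvalue curve, with an
explicit override since the elbow rule is inherently visual), and rotate
with varimax under Kaiser row normalization.

Rotation is computed by the classic pairwise Jacobi sweep algorithm.  Scores
are the standardized data projected on the rotated (orthonormal) component
basis, so total variance explained is conserved under rotation.  Each rotated
component is sign-normalized so that its largest-|loading| feature loads
positively, which makes refits bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ScreeAmbiguityError(ValueError):
    """The scree curve has no elbow (e.g. a flat spectrum)."""


def kmo(feature_matrix: np.ndarray | pd.DataFrame) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum of squared off-diagonal correlations over that sum plus the
    sum of squared off-diagonal partial correlations (partialling out all
    other variables, via the inverse correlation matrix).

    Raises on a singular correlation matrix, and on an identity correlation
    matrix (all off-diagonal correlations zero), where KMO is undefined.
    In the bivariate case the partial correlation equals the correlation, so
    KMO is 0.5 for any nonzero correlation.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("KMO needs a 2-D matrix with at least 2 features")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("KMO needs more rows than features")
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix; KMO undefined") from exc
    if np.linalg.cond(R) > 1e12:
        raise ValueError("near-singular correlation matrix; KMO unreliable")
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    p2 = np.sum(partial[off] ** 2)
    if r2 + p2 == 0 or np.isclose(r2, 0):
        raise ValueError("all off-diagonal correlations are zero; KMO undefined")
    return float(r2 / (r2 + p2))


def scree_select(eigenvalues: Sequence[float], override: int | None = None) -> int:
    """Elbow (Cattell) selection: the point of maximum acceleration.

    Operationalized as the index of the maximum second difference of the
    descending eigenvalue curve; ``override`` forces a fixed k regardless.
    """
    if override is not None:
        if override < 1:
            raise ValueError("override k must be >= 1")
        return int(override)
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("scree selection needs at least 3 eigenvalues")
    if np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be sorted descending")
    d2 = lam[:-2] - 2 * lam[1:-1] + lam[2:]  # acceleration at positions 1..n-2
    if np.ptp(d2) < 1e-10:
        raise ScreeAmbiguityError("flat scree curve: no elbow; pass override=k")
    return int(np.argmax(d2)) + 1


def varimax_rotation(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Orthogonal varimax rotation matrix R for a p x k loading matrix.

    Classic pairwise Jacobi sweeps: for each column pair, the planar angle
    maximizing the varimax criterion in closed form; repeat until the largest
    rotation angle in a sweep falls below ``tol``.  Kaiser normalization
    divides rows by their communalities before rotation (and is undone by the
    caller simply because R is returned, not the rotated loadings).
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return np.eye(k)
    if kaiser_normalize:
        h = np.sqrt(np.sum(L**2, axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    for _ in range(max_sweeps):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2 * x * y
                A, B = u.sum(), v.sum()
                num = 2 * (u @ v) - 2 * A * B / p
                den = (u @ u) - (v @ v) - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) <= tol:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        if max_angle <= tol:
            break
    return R


@dataclass
class PCAResult:
    """Fitted correlation-matrix PCA with varimax rotation."""

    feature_names: list[str]
    mean: np.ndarray  # per-feature standardization mean
    sd: np.ndarray  # per-feature standardization sd (ddof=1)
    eigenvalues: np.ndarray  # all p eigenvalues, descending
    k: int
    rotation: np.ndarray  # k x k orthogonal matrix
    basis: np.ndarray  # feature x k rotated orthonormal basis (for scoring)
    loadings: pd.DataFrame  # feature x component, rotated & sign-normalized
    explained_variance_proportion: np.ndarray  # per rotated component
    row_scores: pd.DataFrame  # row x component
    component_labels: list[str] = field(default_factory=list)

    @property
    def total_explained_variance(self) -> float:
        return float(self.explained_variance_proportion.sum())

    def score(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Project new rows (same features) onto the rotated basis."""
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean) / self.sd
        return Z @ self.basis

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "k": self.k,
            "rotation": self.rotation.tolist(),
            "loadings": self.loadings.values.tolist(),
            "basis": self.basis.tolist(),
            "explained_variance_proportion": self.explained_variance_proportion.tolist(),
            "component_labels": self.component_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def pca_varimax(
    feature_matrix: pd.DataFrame,
    k: int,
    component_labels: Sequence[str] | None = None,
    tol: float = 1e-8,
) -> PCAResult:
    """Z-score, eigendecompose the correlation matrix, retain k, varimax-rotate.

    Raises ``ValueError`` naming the feature if any feature is constant, and
    on incomplete data (complete-case input is the caller's responsibility).
    """
    if not isinstance(feature_matrix, pd.DataFrame):
        feature_matrix = pd.DataFrame(np.asarray(feature_matrix, dtype=float))
    X = feature_matrix.to_numpy(dtype=float)
    names = [str(c) for c in feature_matrix.columns]
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains missing/non-finite values")
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k={k} out of range for {X.shape[1]} features")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(names, sd):
        if s == 0:
            raise ValueError(f"constant feature: {name!r}")
    Z = (X - mean) / sd
    R_corr = np.corrcoef(X, rowvar=False)
    lam, vec = np.linalg.eigh(R_corr)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam = np.clip(lam, 0.0, None)
    Vk = vec[:, :k]
    # deterministic pre-rotation sign: largest-|component| entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vk[:, j])))
        if Vk[i, j] < 0:
            Vk[:, j] = -Vk[:, j]
    unrotated = Vk * np.sqrt(lam[:k])
    R = varimax_rotation(unrotated, tol=tol)
    loadings = unrotated @ R
    basis = Vk @ R
    # sign convention on rotated components
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            basis[:, j] = -basis[:, j]
            R[:, j] = -R[:, j]
    # order rotated components by explained variance, descending (stable)
    explained = np.sum(loadings**2, axis=0) / X.shape[1]
    order_r = np.argsort(-explained, kind="stable")
    loadings, basis, R, explained = loadings[:, order_r], basis[:, order_r], R[:, order_r], explained[order_r]
    comp_names = [f"PC{j + 1}" for j in range(k)]
    scores = Z @ basis
    result = PCAResult(
        feature_names=names,
        mean=mean,
        sd=sd,
        eigenvalues=lam,
        k=k,
        rotation=R,
        basis=basis,
        loadings=pd.DataFrame(loadings, index=names, columns=comp_names),
        explained_variance_proportion=explained,
        row_scores=pd.DataFrame(scores, index=feature_matrix.index, columns=comp_names),
        component_labels=list(component_labels) if component_labels else [],
    )
    return result


def project_words_and_average(
    word_scores: pd.DataFrame,
    tokens_by_participant: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Average word PC scores over each participant's content tokens.

    ``word_scores`` is the row_scores frame of the word-properties PCA,
    indexed by word.  Token-level averaging weights by usage.  Participants
    with zero scorable tokens are omitted and returned in the flagged list.
    """
    rows, flagged = {}, []
    for pid, tokens in tokens_by_participant.items():
        present = [t for t in tokens if t in word_scores.index]
        if not present:
            flagged.append(pid)
            continue
        rows[pid] = word_scores.loc[present].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "participant_id"
    return out, flagged


# ---------------------------------------------------------------------------
# Group tests on PC scores


def pc_group_tests(
    scores: pd.DataFrame,
    groups: pd.Series,
    task: pd.Series | None = None,
) -> dict[str, dict]:
    """ANOVA on PC scores: one-way by group, or two-way group x task.

    Returns, per component, the ANOVA table (F and p per effect) and -- for
    the one-way case -- the Tukey HSD pairwise table.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = pd.Series(groups, index=scores.index).astype(str)
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    out: dict[str, dict] = {}
    for comp in scores.columns:
        df = pd.DataFrame({"score": scores[comp].to_numpy(), "group": groups.to_numpy()})
        if task is None:
            fit = ols("score ~ C(group)", data=df).fit()
            table = sm.stats.anova_lm(fit, typ=2)
            tukey = pairwise_tukeyhsd(df["score"], df["group"])
            tukey_df = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
            out[comp] = {
                "F": float(table.loc["C(group)", "F"]),
                "p": float(table.loc["C(group)", "PR(>F)"]),
                "df": (int(table.loc["C(group)", "df"]), int(table.loc["Residual", "df"])),
                "anova_table": table,
                "tukey": tukey_df,
            }
        else:
            df["task"] = pd.Series(task, index=scores.index).astype(str).to_numpy()
            fit = ols("score ~ C(group) * C(task)", data=df).fit()
            table = sm.stats.anova_lm(fit, typ=2)
            out[comp] = {
                "F_group": float(table.loc["C(group)", "F"]),
                "p_group": float(table.loc["C(group)", "PR(>F)"]),
                "F_task": float(table.loc["C(task)", "F"]),
                "p_task": float(table.loc["C(task)", "PR(>F)"]),
                "F_interaction": float(table.loc["C(group):C(task)", "F"]),
                "p_interaction": float(table.loc["C(group):C(task)", "PR(>F)"]),
                "anova_table": table,
            }
    return out
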