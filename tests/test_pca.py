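"""PCA stage: KMO vs an independent partial-correlation oracle, scree elbow,
varimax vs an independently coded SVD-based rotation, scoring and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from speechlex.pca import (
    PCAResult,
    ScreeAmbiguityError,
    kmo,
    pc_group_tests,
    pca_varimax,
    project_words_and_average,
    scree_select,
    varimax_rotation,
)

# ---------------------------------------------------------------------------
# independent oracles


def kmo_by_regression(X):
    """KMO with partial correlations obtained by regressing out all other
    variables (residual correlation), independent of the inverse-matrix route."""
    X = np.asarray(X, float)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    partial = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            A = np.column_stack([np.ones(n), Z[:, others]])
            ri = Z[:, i] - A @ np.linalg.lstsq(A, Z[:, i], rcond=None)[0]
            rj = Z[:, j] - A @ np.linalg.lstsq(A, Z[:, j], rcond=None)[0]
            partial[i, j] = partial[j, i] = np.corrcoef(ri, rj)[0, 1]
    off = ~np.eye(p, dtype=bool)
    return np.sum(R[off] ** 2) / (np.sum(R[off] ** 2) + np.sum(partial[off] ** 2))


def varimax_svd(loadings, tol=1e-10, max_iter=5000):
    """SVD-based varimax (the textbook alternating algorithm), with Kaiser
    row normalization; independent of the pairwise Jacobi implementation."""
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    h = np.sqrt((L**2).sum(1))
    h[h == 0] = 1.0
    L = L / h[:, None]
    R = np.eye(k)
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(L.T @ (LR**3 - LR @ np.diag((LR**2).sum(0)) / p))
        R_new = u @ vt
        delta = np.abs(R_new - R).max()
        R = R_new
        if delta < 1e-13:
            break
    return (L @ R) * h[:, None]


def match_columns(A, B):
    """Max |difference| between matrices up to column sign and permutation."""
    k = A.shape[1]
    used, total = set(), 0.0
    for j in range(k):
        best = None
        for m in range(k):
            if m in used:
                continue
            for s in (1, -1):
                d = np.abs(A[:, j] - s * B[:, m]).max()
                if best is None or d < best[0]:
                    best = (d, m)
        used.add(best[1])
        total = max(total, best[0])
    return total


# ---------------------------------------------------------------------------
# KMO


class TestKMO:
    def test_bivariate_closed_form_is_half(self):
        rng = np.random.default_rng(0)
        for r in (0.3, -0.7, 0.95):
            cov = np.array([[1, r], [r, 1]])
            X = rng.multivariate_normal([0, 0], cov, size=200)
            assert kmo(X) == pytest.approx(0.5, abs=1e-12)

    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            A = rng.normal(size=(50, 3))
            X = A @ rng.normal(size=(3, 6)) + 0.8 * rng.normal(size=(50, 6))
            assert kmo(X) == pytest.approx(kmo_by_regression(X), abs=1e-10)

    def test_identity_correlation_is_undefined(self):
        X = np.kron(np.eye(4), np.ones(5)).T  # orthogonal indicator columns
        with pytest.raises(ValueError):
            kmo(X + 0)

    def test_singular_matrix_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # exact collinearity
        with pytest.raises(ValueError):
            kmo(X)


# ---------------------------------------------------------------------------
# scree


class TestScree:
    def test_hand_second_difference(self):
        assert scree_select([5, 3, 2, 0.3, 0.25, 0.2]) == 3

    def test_flat_spectrum_is_ambiguous(self):
        with pytest.raises(ScreeAmbiguityError):
            scree_select([1.0, 1.0, 1.0, 1.0])

    def test_override_wins(self):
        assert scree_select([1.0, 1.0, 1.0, 1.0], override=3) == 3
        assert scree_select([5, 3, 2, 0.3, 0.25, 0.2], override=2) == 2

    def test_too_few_eigenvalues(self):
        with pytest.raises(ValueError):
            scree_select([2.0, 1.0])

    def test_requires_descending_order(self):
        with pytest.raises(ValueError):
            scree_select([1.0, 2.0, 0.5])


# ---------------------------------------------------------------------------
# varimax


def planted_matrix(seed, n=100, p=8, k=3):
    rng = np.random.default_rng(seed)
    F = rng.normal(size=(n, k))
    load = np.zeros((p, k))
    for i in range(p):
        load[i, i % k] = rng.uniform(0.7, 1.0)
    X = F @ load.T + 0.3 * rng.normal(size=(n, p))
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])


class TestVarimax:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_svd_reference_up_to_sign_permutation(self, seed):
        X = planted_matrix(seed)
        res = pca_varimax(X, 3)
        # rebuild the unrotated loadings the same way and rotate via the oracle
        Z = (X - X.mean()) / X.std(ddof=1)
        lam, vec = np.linalg.eigh(np.corrcoef(X.to_numpy(), rowvar=False))
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        unrot = vec[:, :3] * np.sqrt(lam[:3])
        ref = varimax_svd(unrot)
        assert match_columns(res.loadings.to_numpy(), ref) < 1e-6

    def test_rotation_is_orthogonal_and_variance_conserved(self):
        X = planted_matrix(10)
        res = pca_varimax(X, 3)
        R = res.rotation
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-8
        lam = np.sort(np.linalg.eigvalsh(np.corrcoef(X.to_numpy(), rowvar=False)))[::-1]
        pre = lam[:3].sum() / X.shape[1]
        assert res.total_explained_variance == pytest.approx(pre, abs=1e-8)

    def test_simple_structure_is_a_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.9, 0.8, 0.85]
        L[3:, 1] = [0.7, 0.9, 0.75]
        R = varimax_rotation(L)
        # identity up to sign/permutation
        assert np.abs(np.abs(R) - np.eye(2)[np.argmax(np.abs(R), axis=0)]).max() < 1e-6

    def test_scores_zero_mean_and_deterministic_refit(self):
        X = planted_matrix(5)
        res1, res2 = pca_varimax(X, 3), pca_varimax(X, 3)
        assert np.abs(res1.row_scores.mean(0)).max() < 1e-8
        assert res1.row_scores.equals(res2.row_scores)
        assert res1.loadings.equals(res2.loadings)

    def test_sign_convention(self):
        res = pca_varimax(planted_matrix(6), 3)
        L = res.loadings.to_numpy()
        for j in range(3):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_constant_feature_named_in_error(self):
        X = planted_matrix(7)
        X["f0"] = 1.0
        with pytest.raises(ValueError, match="f0"):
            pca_varimax(X, 3)


# ---------------------------------------------------------------------------
# word-score projection and group tests


class TestProjection:
    def test_single_word_repeated(self):
        scores = pd.DataFrame({"PC1": [1.5, -2.0]}, index=["boy", "dog"])
        out, flagged = project_words_and_average(scores, {"p1": ["boy", "boy"]})
        assert out.loc["p1", "PC1"] == 1.5 and not flagged

    def test_opposite_scores_average_to_zero(self):
        scores = pd.DataFrame({"PC1": [1.0, -1.0]}, index=["a", "b"])
        out, _ = project_words_and_average(scores, {"p1": ["a", "b"]})
        assert out.loc["p1", "PC1"] == 0.0

    def test_participant_without_scorable_tokens_flagged(self):
        scores = pd.DataFrame({"PC1": [1.0]}, index=["a"])
        out, flagged = project_words_and_average(scores, {"p1": ["zz"], "p2": ["a"]})
        assert flagged == ["p1"] and list(out.index) == ["p2"]


class TestGroupTests:
    def test_identical_groups_give_f_near_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=20)
        scores = pd.DataFrame({"PC1": np.concatenate([vals, vals])})
        groups = pd.Series(["a"] * 20 + ["b"] * 20)
        res = pc_group_tests(scores, groups)
        assert res["PC1"]["F"] == pytest.approx(0.0, abs=1e-10)
        assert res["PC1"]["p"] > 0.99

    def test_one_way_f_matches_scipy(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"PC1": rng.normal(size=30)})
        groups = pd.Series(np.repeat(["a", "b", "c"], 10))
        res = pc_group_tests(scores, groups)
        f_ref, p_ref = stats.f_oneway(*(scores["PC1"][groups == g] for g in "abc"))
        assert res["PC1"]["F"] == pytest.approx(f_ref, abs=1e-8)
        assert res["PC1"]["p"] == pytest.approx(p_ref, abs=1e-8)

    def test_planted_shift_detected_by_tukey(self):
        rng = np.random.default_rng(2)
        hits = 0
        for s in range(40):
            r = np.random.default_rng(s)
            scores = pd.DataFrame({"PC1": np.concatenate([r.normal(0, 1, 20), r.normal(3, 1, 20)])})
            groups = pd.Series(["a"] * 20 + ["b"] * 20)
            tk = pc_group_tests(scores, groups)["PC1"]["tukey"]
            hits += float(tk["p-adj"].iloc[0]) < 0.001
        assert hits >= 39

    def test_two_way_reports_all_effects(self):
        rng = np.random.default_rng(3)
        n = 40
        scores = pd.DataFrame({"PC1": rng.normal(size=n)})
        groups = pd.Series(np.repeat(["a", "b"], n // 2))
        task = pd.Series(list(np.tile(["x", "y"], n // 2)))
        res = pc_group_tests(scores, groups, task=task)["PC1"]
        assert {"F_group", "F_task", "F_interaction"} <= set(res)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            pc_group_tests(pd.DataFrame({"PC1": [1.0, 2.0]}), pd.Series(["a", "a"]))
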