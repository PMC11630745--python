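"""Checklist derivation: equivalence scoring, LASSO limits vs a reference
solver, pairwise selection, rank ordering and hierarchical validation."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from speechlex.checklist import (
    EquivalenceClass,
    augment_with_cognitive,
    build_indicator_matrix,
    fit_lasso_logistic,
    hierarchical_validate,
    kfold_validate,
    lambda_grid,
    oos_validate,
    pairwise_contrasts,
    pairwise_selection,
    proportion_difference,
    rank_and_truncate,
    root,
    score_word,
    unique_word_classes,
    ValidationReport,
)


class TestRootAndScoring:
    @pytest.mark.parametrize(
        "word,expected",
        [("digging", "dig"), ("plates", "plate"), ("carries", "carry"),
         ("overflowing", "overflow"), ("washed", "wash"), ("stools", "stool"),
         ("glass", "glass"), ("dig", "dig")],
    )
    def test_inflectional_roots(self, word, expected):
        assert root(word) == expected

    def test_dialect_variants(self):
        boy = EquivalenceClass("boy", frozenset({"chap", "lad", "bloke"}))
        assert score_word(["a", "chap", "here"], boy) == 1
        assert score_word(["the", "boys"], boy) == 1  # inflection of a variant
        assert score_word(["dog", "cat"], boy) == 0

    def test_root_match_on_target(self):
        dig = EquivalenceClass("dig")
        assert score_word(["digging"], dig) == 1
        assert score_word(["digs"], dig) == 1

    def test_monotone_in_tokens(self):
        c = EquivalenceClass("sink")
        toks = ["boy", "ran"]
        assert score_word(toks, c) == 0
        assert score_word(toks + ["sink"], c) == 1
        assert score_word(toks + ["sink", "more", "words"], c) == 1


class TestIndicatorMatrix:
    def test_rows_and_duplicates(self):
        classes = [EquivalenceClass("boy"), EquivalenceClass("sink")]
        toks = {"p1": ["boy", "sink"], "p2": ["dog"], "p3": ["boy", "boy"]}
        ind = build_indicator_matrix(toks, classes)
        assert ind.loc["p1"].tolist() == [1, 1]
        assert ind.loc["p2"].tolist() == [0, 0]
        assert ind.loc["p3"].tolist() == [1, 0]

    def test_identical_token_sets_identical_rows(self):
        classes = [EquivalenceClass("boy"), EquivalenceClass("sink")]
        ind = build_indicator_matrix({"a": ["boy"], "b": ["boy"]}, classes)
        assert ind.loc["a"].equals(ind.loc["b"])

    def test_unique_word_classes_merge_inflections(self):
        toks = {"p1": ["plates", "digging"], "p2": ["plate", "dig", "dig"]}
        classes = unique_word_classes(toks)
        targets = {c.target for c in classes}
        assert len(classes) == 2
        ind = build_indicator_matrix(toks, classes)
        assert (ind.to_numpy() == 1).all()

    def test_column_means_track_planted_probabilities(self):
        rng = np.random.default_rng(0)
        n, p_true = 400, 0.3
        toks = {f"p{i}": (["sink"] if rng.random() < p_true else ["dog"]) for i in range(n)}
        ind = build_indicator_matrix(toks, [EquivalenceClass("sink")])
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(ind["sink"].mean() - p_true) < 3 * se


class TestLasso:
    def test_lambda_to_infinity_limit(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.integers(0, 2, (60, 8)).astype(float))
        y = (rng.random(60) < 0.6).astype(int)
        lam_max = lambda_grid(X.to_numpy(), y, 2, 0.5)[0]
        fit = fit_lasso_logistic(X, y, seed=0, n_lambdas=3, lambda_min_ratio=0.9)
        # at the top of the path every coefficient is zero by construction
        from speechlex.checklist import _fit_l1
        b0, b = _fit_l1(X.to_numpy(), y, 10 * lam_max)
        assert np.abs(b).max() == 0.0
        assert b0 == pytest.approx(math.log(y.mean() / (1 - y.mean())), abs=1e-4)

    def test_lambda_to_zero_matches_unpenalized_mle(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (80, 4)).astype(float)
        eta = -0.5 + X @ np.array([1.0, -0.8, 0.3, 0.0])
        y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(int)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        from speechlex.checklist import _fit_l1
        b0, b = _fit_l1(X, y, 1e-9, max_iter=200000, tol=1e-12)
        assert b0 == pytest.approx(mle.params[0], abs=1e-4)
        assert np.abs(b - mle.params[1:]).max() < 1e-4

    def test_perfect_discriminator_selected(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.integers(0, 2, (60, 10)).astype(float),
                             columns=[f"w{i}" for i in range(10)])
            y = X["w0"].to_numpy().astype(int)
            fit = fit_lasso_logistic(X, y, seed=s)
            hits += "w0" in fit.selected_words
        assert hits >= 19

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.ones((10, 2)))
        with pytest.raises(ValueError):
            fit_lasso_logistic(X, np.ones(10, dtype=int))

    def test_constant_columns_dropped_and_logged(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"w0": rng.integers(0, 2, 40).astype(float), "w1": 1.0})
        y = rng.integers(0, 2, 40)
        fit = fit_lasso_logistic(X, y, seed=0)
        assert fit.dropped_columns == ["w1"]
        assert "w1" not in fit.betas.index

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.integers(0, 2, (50, 12)).astype(float))
        y = rng.integers(0, 2, 50)
        f1 = fit_lasso_logistic(X, y, seed=5)
        f2 = fit_lasso_logistic(X, y, seed=5)
        assert f1.betas.equals(f2.betas) and f1.selected_lambda == f2.selected_lambda


class TestPairwiseSelection:
    def test_contrast_enumeration_for_six_groups(self):
        pairs = pairwise_contrasts(["control", "svPPA", "lvPPA", "nfvPPA", "PSP", "CBS"])
        assert len(pairs) == 15
        assert sum(1 for a, _ in pairs if a == "control") == 5

    def test_perfect_separator_pooled(self):
        rng = np.random.default_rng(0)
        n = 24
        ind = pd.DataFrame({
            "sep": [1.0] * (n // 2) + [0.0] * (n // 2),
            **{f"n{i}": rng.integers(0, 2, n).astype(float) for i in range(5)},
        }, index=[f"p{i}" for i in range(n)])
        groups = pd.Series(["control"] * (n // 2) + ["svPPA"] * (n // 2), index=ind.index)
        pooled = pairwise_selection(ind, groups, seed=0)
        assert "sep" in pooled.pooled_words

    def test_null_groups_modal_empty_selection(self):
        """With identically generated groups the pooled set is empty or tiny
        in the modal seed."""
        sizes = []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            ind = pd.DataFrame(
                rng.integers(0, 2, (40, 30)).astype(float),
                columns=[f"w{i}" for i in range(30)],
                index=[f"p{i}" for i in range(40)],
            )
            groups = pd.Series(["control"] * 20 + ["svPPA"] * 20, index=ind.index)
            pooled = pairwise_selection(ind, groups, seed=s)
            sizes.append(len(pooled.pooled_words))
        assert np.median(sizes) <= 3


class TestProportionDifference:
    def _col(self, a_vals, b_vals):
        col = pd.Series(a_vals + b_vals, index=[f"p{i}" for i in range(len(a_vals + b_vals))])
        groups = pd.Series(["a"] * len(a_vals) + ["b"] * len(b_vals), index=col.index)
        return col, groups

    def test_all_versus_none_is_one(self):
        col, groups = self._col([1] * 10, [0] * 10)
        assert proportion_difference(col, groups, "a", "b") == 1.0

    def test_identical_rates_zero(self):
        col, groups = self._col([1, 0] * 5, [0, 1] * 5)
        assert proportion_difference(col, groups, "a", "b") == 0.0

    def test_eight_of_ten_vs_three_of_ten(self):
        col, groups = self._col([1] * 8 + [0] * 2, [1] * 3 + [0] * 7)
        assert proportion_difference(col, groups, "a", "b") == pytest.approx(0.5)


class TestRanking:
    def _run(self, ind, groups):
        pooled = pairwise_selection(ind, groups, seed=0)
        classes = {c: EquivalenceClass(c) for c in ind.columns}
        return rank_and_truncate(ind, groups, pooled, classes, "cookie_theft", seed=0)

    def test_lexicographic_order(self):
        """Appearance count dominates |beta|, which dominates proportion
        difference, with alphabetical tie-break."""
        table = pd.DataFrame({
            "word": ["a", "b", "c", "d"],
            "appearance_count": [1, 3, 3, 1],
            "max_abs_beta": [9.0, 0.1, 2.0, 9.0],
            "proportion_difference": [0.9, 0.5, 0.1, 0.9],
        })
        ordered = table.sort_values(
            by=["appearance_count", "max_abs_beta", "proportion_difference", "word"],
            ascending=[False, False, False, True], kind="stable",
        )["word"].tolist()
        assert ordered == ["c", "b", "a", "d"]

    def test_derivation_recovers_planted_separators(self):
        rng = np.random.default_rng(7)
        n = 50
        idx = [f"p{i}" for i in range(n)]
        groups = pd.Series(["control"] * 25 + ["svPPA"] * 25, index=idx)
        data = {}
        for w in ("alpha", "beta", "gamma"):  # planted: produced by controls
            data[w] = [float(rng.random() < 0.9)] * 0 or [
                float(rng.random() < (0.9 if g == "control" else 0.15)) for g in groups
            ]
        for i in range(20):  # noise words
            data[f"noise{i:02d}"] = rng.integers(0, 2, n).astype(float).tolist()
        ind = pd.DataFrame(data, index=idx)
        table, checklist = self._run(ind, groups)
        assert {"alpha", "beta", "gamma"} <= set(checklist.targets)

    def test_empty_pool_gives_empty_checklist(self):
        ind = pd.DataFrame({"w": [1.0, 1.0, 0.0, 0.0]}, index=list("abcd"))
        groups = pd.Series(["control", "svPPA", "control", "svPPA"], index=ind.index)
        pooled = pairwise_selection(ind, groups, seed=0)
        if not pooled.pooled_words:  # modal outcome for an uninformative word
            table, checklist = rank_and_truncate(
                ind, groups, pooled, {"w": EquivalenceClass("w")}, "cookie_theft")
            assert checklist.targets == [] and len(table) == 0


class TestValidation:
    def test_confusion_arithmetic(self):
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [1] * 2 + [0] * 8
        rep = ValidationReport.from_predictions(
            "c", "kfold", y_true, y_pred, np.linspace(0, 1, 20), list(range(20)), 0)
        assert rep.confusion.tolist() == [[8, 2], [1, 9]]
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.85)

    def test_perfectly_separating_word_gives_full_accuracy(self):
        rng = np.random.default_rng(0)
        n = 40
        X = pd.DataFrame({
            "sep": [1.0] * 20 + [0.0] * 20,
            "noise": rng.integers(0, 2, n).astype(float),
        }, index=[f"p{i}" for i in range(n)])
        y = np.array([1] * 20 + [0] * 20)
        rep = kfold_validate(X, y, k=4, seed=0)
        assert rep.accuracy == 1.0

    def test_oos_rejects_overlapping_cohorts(self):
        X = pd.DataFrame({"w": [1.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            oos_validate(X, [1, 0], X, [1, 0])

    def test_hierarchical_stages_present(self, small_cohort):
        from speechlex.transcripts import Picture
        toks = small_cohort.tokens_by_participant(Picture.cookie_theft)
        classes = unique_word_classes(toks, min_producers=2)
        ind = build_indicator_matrix(toks, classes)
        groups = small_cohort.participants["group"]
        reports = hierarchical_validate(ind, groups, scheme="kfold", seed=0, k=2)
        assert {"controls_vs_patients", "motor_vs_lexicosemantic",
                "svPPA_vs_lvPPA", "nfvPPA_vs_PSP+CBS"} <= set(reports)
        for rep in reports.values():
            assert rep.confusion.sum() == len(rep.predictions)


class TestAugment:
    def test_constant_column_dropped(self):
        ind = pd.DataFrame({"w": [1.0, 0.0, 1.0]}, index=list("abc"))
        cog = pd.DataFrame({"s1": [5.0, 5.0, 5.0], "s2": [1.0, 2.0, 3.0]}, index=list("abc"))
        out, dropped = augment_with_cognitive(ind, cog)
        assert "s1" not in out.columns and "s2" in out.columns

    def test_column_count_and_zscoring(self):
        ind = pd.DataFrame({"w": [1.0, 0.0, 1.0, 0.0]}, index=list("abcd"))
        cog = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0], "s2": [9.0, 7.0, 5.0, 6.0]},
                           index=list("abcd"))
        out, _ = augment_with_cognitive(ind, cog)
        assert out.shape[1] == 3
        assert out["s1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["s1"].std(ddof=1) == pytest.approx(1.0)
        assert out["w"].tolist() == [1.0, 0.0, 1.0, 0.0]  # binary untouched

    def test_incomplete_rows_dropped(self):
        ind = pd.DataFrame({"w": [1.0, 0.0, 1.0]}, index=list("abc"))
        cog = pd.DataFrame({"s": [1.0, np.nan, 3.0]}, index=list("abc"))
        out, dropped = augment_with_cognitive(ind, cog)
        assert dropped == ["b"] and list(out.index) == ["a", "c"]

    def test_informative_score_beats_words_only(self):
        """When the separation lives in a cognitive score, the augmented model
        outperforms the words-only model on the same folds."""
        wins = 0
        for s in range(8):
            rng = np.random.default_rng(s)
            n = 48
            idx = [f"p{i}" for i in range(n)]
            y = np.array([1] * (n // 2) + [0] * (n // 2))
            ind = pd.DataFrame(
                rng.integers(0, 2, (n, 6)).astype(float),
                columns=[f"w{i}" for i in range(6)], index=idx)
            cog = pd.DataFrame({"score": y * 2.0 + rng.normal(0, 0.7, n)}, index=idx)
            aug, _ = augment_with_cognitive(ind, cog)
            acc_w = kfold_validate(ind, y, k=4, seed=s).accuracy
            acc_a = kfold_validate(aug, y, k=4, seed=s).accuracy
            wins += acc_a >= acc_w
        assert wins >= 7


class TestNestedKfold:
    def test_planted_separator_survives_nested_derivation(self):
        """When a word genuinely separates the groups, re-deriving the
        checklist inside every fold still classifies well."""
        from speechlex.checklist import nested_kfold_validate

        rng = np.random.default_rng(4)
        n = 48
        idx = [f"p{i}" for i in range(n)]
        groups = pd.Series(["control"] * 24 + ["svPPA"] * 24, index=idx)
        y = (groups == "svPPA").astype(int).to_numpy()
        data = {"sep": [float(g == "control") for g in groups]}
        for i in range(15):
            data[f"noise{i:02d}"] = rng.integers(0, 2, n).astype(float)
        ind = pd.DataFrame(data, index=idx)
        rep = nested_kfold_validate(ind, groups, y, k=4, seed=0, n_lambdas=10)
        assert rep.scheme == "nested_kfold"
        assert rep.accuracy >= 0.9
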