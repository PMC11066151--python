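import numpy as np
import pandas as pd
import pytest

from frontsig.gene_stats import auc_mann_whitney
from frontsig.io_formats import (
    EARLY_RELAPSE,
    NO_RELAPSE,
    read_signature,
    write_signature,
)
from frontsig.model_train_eval import (
    SignatureModel,
    TuningConfig,
    combine_scores,
    confusion_at_cutoff,
    evaluate_scores,
    fit_elasticnet,
    loocv,
    predict_score,
    roc_auc_ci,
    score_agreement,
    signature_features,
    train_signature_model,
)
from frontsig.module_builder import GeneModule

E, N = EARLY_RELAPSE, NO_RELAPSE

FAST_TUNING = TuningConfig(l1_ratios=(0.55,), cs=(1.0,), n_splits=3)


def labels(n_pos, n_neg, index=None):
    s = pd.Series([E] * n_pos + [N] * n_neg)
    if index is not None:
        s.index = index
    return s


class TestFitElasticnet:
    def test_separable_feature_reaches_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        f = pd.DataFrame({"m1": np.r_[rng.normal(3, 0.1, 10),
                                      rng.normal(-3, 0.1, 10)]},
                         index=[f"s{i}" for i in range(20)])
        pheno = labels(10, 10, f.index)
        coef, intercept, _, cv_auc, _ = fit_elasticnet(f, pheno, seed=1)
        assert cv_auc == 1.0
        assert coef[0] > 0

    def test_constant_features_give_zero_coefficients_and_prior_scores(self):
        f = pd.DataFrame({"m1": np.ones(12), "m2": np.full(12, 3.0)},
                         index=[f"s{i}" for i in range(12)])
        pheno = labels(4, 8, f.index)
        coef, intercept, std, _, _ = fit_elasticnet(f, pheno, seed=0)
        assert np.allclose(coef, 0.0)
        model = SignatureModel(
            modules=[GeneModule("m1", ("GA",), (1,), "S"),
                     GeneModule("m2", ("GB",), (1,), "S")],
            module_coefficients=coef, intercept=intercept,
            n_g=1, n_f=2, standardization=std)
        scores = predict_score(model, f)
        assert np.allclose(scores, 4 / 12, atol=1e-3)  # class prior

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        f = pd.DataFrame(rng.normal(size=(16, 3)), columns=list("abc"),
                         index=[f"s{i}" for i in range(16)])
        pheno = labels(8, 8, f.index)
        a = fit_elasticnet(f, pheno, seed=3)
        b = fit_elasticnet(f, pheno, seed=3)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_single_class_rejected(self):
        f = pd.DataFrame({"m1": [1.0, 2.0, 3.0, 4.0]},
                         index=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError):
            fit_elasticnet(f, labels(4, 0, f.index), seed=0)


class TestPredictScore:
    def _model(self, coef, intercept):
        return SignatureModel(
            modules=[GeneModule("m1", ("GA",), (1,), "S")],
            module_coefficients=np.array(coef, dtype=float),
            intercept=intercept, n_g=1, n_f=1, standardization=None)

    def test_zero_model_scores_half(self):
        model = self._model([0.0], 0.0)
        f = pd.DataFrame({"m1": [-4.0, 0.0, 7.0]}, index=list("xyz"))
        assert np.allclose(predict_score(model, f), 0.5)

    def test_monotone_in_positive_coefficient_feature(self):
        model = self._model([2.0], -0.3)
        f = pd.DataFrame({"m1": [-1.0, 0.0, 1.0, 5.0]},
                         index=list("wxyz"))
        scores = predict_score(model, f)
        assert scores.is_monotonic_increasing
        assert ((scores > 0) & (scores < 1)).all()

    def test_round_trip_through_signature_json(self, tmp_path):
        model = SignatureModel(
            modules=[GeneModule("m1", ("GA", "GB"), (1, -1), "S", 0.9)],
            module_coefficients=np.array([1.25]), intercept=-0.5,
            n_g=2, n_f=1,
            standardization=(np.array([0.1]), np.array([2.0])))
        f = pd.DataFrame({"m1": [0.3, -1.2, 4.0]}, index=list("abc"))
        before = predict_score(model, f)
        write_signature(model, tmp_path / "m.json")
        after = predict_score(read_signature(tmp_path / "m.json"), f)
        assert np.array_equal(before.values, after.values)

    def test_missing_feature_rejected(self):
        model = self._model([1.0], 0.0)
        f = pd.DataFrame({"other": [1.0]}, index=["a"])
        with pytest.raises(KeyError, match="m1"):
            predict_score(model, f)


class TestTrainSignatureModel:
    def test_grid_restricted_to_one_point(self, small_study):
        s = small_study
        model = train_signature_model(
            s["bulk"], s["phenotype"], s["gene_sets"],
            n_g_grid=(3,), n_f_grid=(4,), b=25, seed=1, tuning=FAST_TUNING)
        assert model.n_g == 3 and model.n_f == 4
        assert len(model.modules) == 4
        assert all(m.n_g == 3 for m in model.modules)

    def test_planted_sets_dominate_selected_modules(self, small_study):
        s = small_study
        model = train_signature_model(
            s["bulk"], s["phenotype"], s["gene_sets"],
            n_g_grid=(3, 4), n_f_grid=(3, 4), b=25, seed=1,
            tuning=FAST_TUNING)
        sources = {m.source_set for m in model.modules}
        assert sources & set(s["config"].planted_sets)

    def test_no_stable_genes_anywhere_is_an_error(self):
        # constant matrix: every gene tied, nothing is stable
        expr = pd.DataFrame(np.ones((10, 12)),
                            index=[f"G{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(12)])
        pheno = labels(6, 6, expr.columns)
        with pytest.raises(ValueError, match="stable"):
            train_signature_model(expr, pheno, {"S": list(expr.index)},
                                  n_g_grid=(3,), n_f_grid=(3,), b=10, seed=0)


class TestLoocv:
    def test_one_score_per_sample_in_unit_interval(self, small_study):
        s = small_study
        scores = loocv(s["bulk"], s["phenotype"], s["gene_sets"],
                       n_g_grid=(3,), n_f_grid=(3,), b=20, seed=1,
                       tuning=FAST_TUNING)
        assert list(scores.index) == list(s["bulk"].columns)
        assert scores.between(0, 1).all()

    def test_held_out_label_never_influences_its_score(self, small_study):
        # flipping the held-out sample's outcome must leave its
        # out-of-fold score bit-identical
        s = small_study
        target = s["bulk"].columns[0]
        kwargs = dict(n_g_grid=(3,), n_f_grid=(3,), b=15, seed=2,
                      tuning=FAST_TUNING)
        cols = list(s["bulk"].columns[:6]) + list(s["bulk"].columns[10:16])
        sub = s["bulk"][cols]
        pheno = s["phenotype"].loc[sub.columns]
        baseline = loocv(sub, pheno, s["gene_sets"], **kwargs)
        flipped = pheno.copy()
        flipped[target] = N if flipped[target] == E else E
        perturbed = loocv(sub, flipped, s["gene_sets"], **kwargs)
        assert perturbed[target] == baseline[target]


class TestRocAucCi:
    def test_perfect_ranking(self):
        scores = pd.Series([0.9, 0.8, 0.2, 0.1], index=list("abcd"))
        auc, lo, hi = roc_auc_ci(scores, labels(2, 2, list("abcd")))
        assert auc == 1.0 and 0 <= lo <= hi <= 1

    def test_constant_scores_give_half(self):
        scores = pd.Series([0.5] * 6, index=list("abcdef"))
        auc, lo, hi = roc_auc_ci(scores, labels(3, 3, list("abcdef")))
        assert auc == 0.5

    def test_point_estimate_matches_mann_whitney(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(14)]
        scores = pd.Series(rng.uniform(size=14), index=idx)
        pheno = labels(6, 8, idx)
        auc, _, _ = roc_auc_ci(scores, pheno)
        assert auc == pytest.approx(auc_mann_whitney(scores.values, pheno.values))


class TestConfusionAtCutoff:
    def test_published_sensitivity_interval_shape(self):
        # 14 of 19 early-relapse cases above the 0.5 cutoff
        idx = [f"s{i}" for i in range(39)]
        scores = pd.Series(np.r_[np.full(14, 0.9), np.full(5, 0.1),
                                 np.full(4, 0.9), np.full(16, 0.1)],
                           index=idx)
        out = confusion_at_cutoff(scores, labels(19, 20, idx))
        assert out["sensitivity"] == pytest.approx(14 / 19)
        assert out["sensitivity_ci"] == pytest.approx((0.488, 0.908), abs=1e-3)
        assert out["specificity"] == pytest.approx(16 / 20)
        assert out["specificity_ci"] == pytest.approx((0.563, 0.943), abs=1e-3)

    def test_all_correct(self):
        idx = list("abcd")
        scores = pd.Series([0.9, 0.8, 0.1, 0.2], index=idx)
        out = confusion_at_cutoff(scores, labels(2, 2, idx))
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_score_exactly_at_cutoff_is_called_negative(self):
        idx = list("ab")
        scores = pd.Series([0.5, 0.5], index=idx)
        out = confusion_at_cutoff(scores, labels(1, 1, idx))
        assert out["sensitivity"] == 0.0 and out["specificity"] == 1.0


class TestCombineScores:
    def test_arithmetic_mean(self):
        a = pd.Series([0.2, 0.8], index=["s1", "s2"])
        b = pd.Series([0.4, 0.6], index=["s1", "s2"])
        assert combine_scores(a, b).tolist() == pytest.approx([0.3, 0.7])

    def test_identical_sets_are_identity(self):
        a = pd.Series([0.1, 0.9, 0.4], index=list("abc"))
        assert combine_scores(a, a.copy()).tolist() == a.tolist()

    def test_unmatched_samples_excluded_with_warning(self):
        a = pd.Series([0.2, 0.8, 0.5], index=["s1", "s2", "s3"])
        b = pd.Series([0.4, 0.6], index=["s1", "s2"])
        with pytest.warns(UserWarning, match="s3"):
            combined = combine_scores(a, b)
        assert list(combined.index) == ["s1", "s2"]

    def test_disjoint_sets_rejected(self):
        a = pd.Series([0.2], index=["s1"])
        b = pd.Series([0.4], index=["s2"])
        with pytest.raises(ValueError):
            combine_scores(a, b)

    def test_averaging_independent_scores_raises_auc_in_expectation(self):
        # two conditionally independent noisy scores of equal individual
        # AUC ~0.85: their average separates the classes better
        rng = np.random.default_rng(123)
        n1, n0, reps = 18, 18, 120
        idx = [f"s{i}" for i in range(n1 + n0)]
        pheno = labels(n1, n0, idx)
        gain_a, gain_b = [], []
        for _ in range(reps):
            truth = np.r_[np.ones(n1), np.zeros(n0)]
            a = pd.Series(truth * 1.47 + rng.normal(size=n1 + n0), index=idx)
            b = pd.Series(truth * 1.47 + rng.normal(size=n1 + n0), index=idx)
            auc_a = auc_mann_whitney(a.values, pheno.values)
            auc_b = auc_mann_whitney(b.values, pheno.values)
            auc_c = auc_mann_whitney(combine_scores(a, b).values, pheno.values)
            gain_a.append(auc_c - auc_a)
            gain_b.append(auc_c - auc_b)
        assert np.mean(gain_a) > 0 and np.mean(gain_b) > 0


class TestScoreAgreement:
    def test_identical_scores(self):
        a = pd.Series([0.1, 0.6, 0.9], index=list("abc"))
        assert score_agreement(a, a.copy()) == (1.0, 1.0, 1.0)

    def test_anti_correlated_scores(self):
        a = pd.Series([0.1, 0.4, 0.9], index=list("abc"))
        b = 1.0 - a
        pearson, spearman, _ = score_agreement(a, b)
        assert pearson == pytest.approx(-1.0)
        assert spearman == pytest.approx(-1.0)

    def test_chance_level_kappa_is_zero(self):
        # observed agreement 0.5 equals chance agreement 0.5
        a = pd.Series([0.9, 0.9, 0.1, 0.1], index=list("abcd"))
        b = pd.Series([0.9, 0.1, 0.9, 0.1], index=list("abcd"))
        _, _, kappa = score_agreement(a, b)
        assert kappa == pytest.approx(0.0)

    def test_zero_variance_flagged_not_zeroed(self):
        a = pd.Series([0.4] * 4, index=list("abcd"))
        b = pd.Series([0.1, 0.2, 0.9, 0.8], index=list("abcd"))
        with pytest.warns(UserWarning, match="zero-variance"):
            pearson, spearman, _ = score_agreement(a, b)
        assert np.isnan(pearson) and np.isnan(spearman)

    def test_too_few_samples_rejected(self):
        a = pd.Series([0.1, 0.9], index=list("ab"))
        with pytest.raises(ValueError):
            score_agreement(a, a)


class TestEvaluateScores:
    def test_report_fields_consistent(self):
        idx = [f"s{i}" for i in range(10)]
        scores = pd.Series(np.linspace(0.05, 0.95, 10)[::-1], index=idx)
        report = evaluate_scores(scores, labels(5, 5, idx))
        d = report.to_dict()
        assert d["auc"] == 1.0
        assert 0 <= d["auc_ci"][0] <= d["auc_ci"][1] <= 1
        assert 0 <= d["sensitivity_ci"][0] <= d["sensitivity_ci"][1] <= 1
        assert d["n_early"] == 5 and d["n_no"] == 5
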