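"""Holdout/CV evaluation protocols, fusion, paired tests, Shapley values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodaudit import modeling as mdl


def _dataset(X, y, sex=None, subjects=None, prefix="s"):
    n = X.shape[0]
    sex = sex if sex is not None else np.array(["F", "M"] * (n // 2) + ["F"] * (n % 2))
    subjects = subjects if subjects is not None else [f"{prefix}{i}" for i in range(n)]
    frame = pd.DataFrame(X, index=subjects,
                         columns=[f"f{j}" for j in range(X.shape[1])])
    return mdl.Dataset(X=frame, y=np.asarray(y), sex=np.asarray(sex),
                       subject_ids=np.asarray(subjects))


class TestHoldout:
    def test_separable_feature_gives_perfect_metrics(self, rng):
        y_tr = np.array([0, 1] * 30)
        y_te = np.array([0, 1] * 15)
        X_tr = np.column_stack([y_tr + 0.01 * rng.normal(size=60),
                                rng.normal(size=60)])
        X_te = np.column_stack([y_te + 0.01 * rng.normal(size=30),
                                rng.normal(size=30)])
        train = _dataset(X_tr, y_tr, prefix="tr")
        test = _dataset(X_te, y_te, prefix="te")
        spec = mdl.ModelSpec("logistic", grid={"model__C": [1.0]})
        m = mdl.fit_eval_holdout(train, test, spec)
        assert m.auc == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.accuracy_female == 1.0 and m.accuracy_male == 1.0

    def test_metrics_match_confusion_matrix_oracle(self, rng):
        # 20-sample toy scored by hand-tabulated confusion arithmetic
        y_tr = np.array([0, 1] * 20)
        X_tr = np.column_stack([y_tr + 0.8 * rng.normal(size=40)])
        y_te = np.array([0] * 10 + [1] * 10)
        X_te = np.column_stack([y_te + 0.8 * rng.normal(size=20)])
        sex_te = np.array(["F"] * 5 + ["M"] * 5 + ["F"] * 5 + ["M"] * 5)
        train = _dataset(X_tr, y_tr, prefix="tr")
        test = _dataset(X_te, y_te, sex=sex_te, prefix="te")
        spec = mdl.ModelSpec("logistic", grid={"model__C": [1.0]})
        m = mdl.fit_eval_holdout(train, test, spec)

        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        pipe = make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=5000))
        pipe.fit(X_tr, y_tr)
        s = pipe.predict_proba(X_te)[:, 1]
        hard = (s >= 0.5).astype(int)
        tp = ((hard == 1) & (y_te == 1)).sum()
        tn = ((hard == 0) & (y_te == 0)).sum()
        assert m.sensitivity == pytest.approx(tp / 10)
        assert m.specificity == pytest.approx(tn / 10)
        ranks = stats.rankdata(s)
        auc = (ranks[y_te == 1].sum() - 10 * 11 / 2) / 100
        assert m.auc == pytest.approx(auc)

    def test_subject_leakage_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        d1 = _dataset(X, y, prefix="a")
        d2 = _dataset(X, y, prefix="a")
        with pytest.raises(ValueError, match="leakage"):
            mdl.fit_eval_holdout(d1, d2, mdl.ModelSpec("logistic"))


class TestRepeatedCV:
    def test_fold_count_and_stratification(self, rng):
        n = 120
        y = np.array([0, 1] * (n // 2))
        sex = np.array((["F"] * 2 + ["M"] * 2) * (n // 4))
        X = rng.normal(size=(n, 3))
        data = _dataset(X, y, sex=sex)
        proto = mdl.EvalProtocol(n_repeats=2, k=5, seed=0)
        spec = mdl.ModelSpec("logistic", grid={"model__C": [1.0]})
        m = mdl.repeated_cv_eval(data, spec, proto)
        assert len(m.per_fold) == 10
        # stratification: every outer fold preserves diagnosis x sex
        # proportions within one sample per stratum
        from sklearn.model_selection import StratifiedKFold
        strata = np.char.add(y.astype(str), sex)
        for rep in range(2):
            skf = StratifiedKFold(5, shuffle=True, random_state=rep)
            for _, te in skf.split(X, strata):
                counts = pd.Series(strata[te]).value_counts()
                for s, c in counts.items():
                    expected = (strata == s).sum() / 5
                    assert abs(c - expected) <= 1

    def test_randomized_labels_near_chance(self, rng):
        n = 100
        y = rng.permutation([0] * 50 + [1] * 50)
        X = rng.normal(size=(n, 5))
        data = _dataset(X, y)
        spec = mdl.ModelSpec("logistic", grid={"model__C": [1.0]})
        m = mdl.repeated_cv_eval(data, spec,
                                 mdl.EvalProtocol(n_repeats=2, k=5, seed=1))
        assert abs(m.auc - 0.5) < 0.1

    def test_small_stratum_rejected(self, rng):
        y = np.array([0] * 8 + [1] * 2)
        data = _dataset(rng.normal(size=(10, 2)), y, sex=np.array(["F"] * 10))
        with pytest.raises(ValueError, match="smaller than k"):
            mdl.repeated_cv_eval(data, mdl.ModelSpec("logistic"),
                                 mdl.EvalProtocol(n_repeats=1, k=5))


class TestFusion:
    def test_width_addition_and_prefixes(self, rng):
        ids = [f"s{i}" for i in range(10)]
        a = pd.DataFrame(rng.normal(size=(10, 120)), index=ids)
        b = pd.DataFrame(rng.normal(size=(10, 136)), index=ids)
        fused = mdl.fuse_blocks({"rna": a, "mri": b})
        assert fused.shape == (10, 256)
        assert fused.columns[0].startswith("rna__")
        assert fused.columns[-1].startswith("mri__")

    def test_self_fusion_distinct_names(self, rng):
        ids = [f"s{i}" for i in range(4)]
        a = pd.DataFrame(rng.normal(size=(4, 3)), index=ids, columns=list("xyz"))
        fused = mdl.fuse_blocks({"b1": a, "b2": a})
        assert len(set(fused.columns)) == 6

    def test_mismatched_ids_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(3, 2)), index=["s1", "s2", "s3"])
        b = pd.DataFrame(rng.normal(size=(3, 2)), index=["s1", "s2", "s4"])
        with pytest.raises(ValueError, match="sample ids"):
            mdl.fuse_blocks({"a": a, "b": b})


class TestCompareFoldAucs:
    def test_identical_p_one(self):
        a = np.linspace(0.6, 0.9, 250)
        stat, p = mdl.compare_fold_aucs(a, a)
        assert p == 1.0

    def test_constant_shift_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.6, 0.9, 250)
        stat, p = mdl.compare_fold_aucs(a + 0.01, a)
        assert p < 0.001
        ref_stat, ref_p = stats.wilcoxon(a + 0.01, a)
        assert p == pytest.approx(ref_p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            mdl.compare_fold_aucs([0.5], [0.5, 0.6])


class TestShapley:
    def _linear_model(self, w, b=0.0):
        class Lin:
            def decision_function(self, X):
                return X @ w + b
        return Lin()

    def test_linear_closed_form_oracle(self, rng):
        # for an additive scorer, Shapley value of feature j is exactly
        # w_j * (x_j - baseline_j), independent of the permutation sample
        d = 5
        w = rng.normal(size=d)
        model = self._linear_model(w, b=0.3)
        Xte = pd.DataFrame(rng.normal(size=(6, d)),
                           columns=[f"f{j}" for j in range(d)])
        baseline = pd.Series(rng.normal(size=d), index=Xte.columns)
        res = mdl.shapley_importance(model, Xte, baseline, n_permutations=20, seed=0)
        expected = (Xte - baseline) * w
        np.testing.assert_allclose(res.values.to_numpy(), expected.to_numpy(),
                                   atol=1e-10)

    def test_efficiency_property(self, rng):
        w = rng.normal(size=4)
        model = self._linear_model(w, b=-0.2)
        Xte = pd.DataFrame(rng.normal(size=(3, 4)),
                           columns=[f"f{j}" for j in range(4)])
        baseline = pd.Series(np.zeros(4), index=Xte.columns)
        res = mdl.shapley_importance(model, Xte, baseline, n_permutations=10, seed=1)
        recon = res.values.sum(axis=1) + res.base_value
        scores = model.decision_function(Xte.to_numpy())
        np.testing.assert_allclose(recon, scores, atol=1e-10)

    def test_inert_feature_zero_importance(self, rng):
        w = np.array([1.0, 0.0, -2.0])
        model = self._linear_model(w)
        Xte = pd.DataFrame(rng.normal(size=(4, 3)), columns=["a", "b", "c"])
        res = mdl.shapley_importance(model, Xte, pd.Series(np.zeros(3),
                                                           index=Xte.columns),
                                     n_permutations=200, seed=2)
        assert res.mean_abs["b"] < 1e-3
        assert list(res.mean_abs.index[:1])[0] in ("a", "c")

    def test_invalid_permutation_count_rejected(self, rng):
        model = self._linear_model(np.ones(2))
        Xte = pd.DataFrame(rng.normal(size=(1, 2)))
        with pytest.raises(ValueError, match="n_permutations"):
            mdl.shapley_importance(model, Xte, np.zeros(2), n_permutations=0)


class TestMetricEdgeCases:
    def test_perfect_and_antiperfect_auc(self):
        from bloodaudit.audit import _auc_rank
        y = np.array([0, 0, 1, 1])
        assert _auc_rank(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert _auc_rank(np.array([0.9, 0.8, 0.2, 0.1]), y) == 0.0

    def test_fusion_beats_unimodal_on_complementary_signal(self, rng):
        # RNA and MRI carry independent halves of the class signal
        n = 200
        y = np.array([0, 1] * (n // 2))
        rna = pd.DataFrame(
            np.column_stack([y + 1.5 * rng.normal(size=n) for _ in range(4)]),
            index=[f"s{i}" for i in range(n)])
        rna.columns = [f"r{j}" for j in range(4)]
        mri = pd.DataFrame(
            np.column_stack([y + 1.5 * rng.normal(size=n) for _ in range(4)]),
            index=rna.index)
        mri.columns = [f"m{j}" for j in range(4)]
        fused = mdl.fuse_blocks({"rna": rna, "mri": mri})
        spec = mdl.ModelSpec("logistic", grid={"model__C": [1.0]})
        proto = mdl.EvalProtocol(n_repeats=2, k=5, seed=4)
        results = {}
        for name, block in [("rna", rna), ("mri", mri), ("fused", fused)]:
            data = mdl.Dataset(X=block, y=y,
                               sex=np.array(["F", "M"] * (n // 2)),
                               subject_ids=np.array(block.index))
            results[name] = mdl.repeated_cv_eval(data, spec, proto)
        best_uni = max(results["rna"].auc, results["mri"].auc)
        assert results["fused"].auc >= best_uni - 0.005
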