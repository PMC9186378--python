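import itertools

import numpy as np
import pandas as pd
import pytest

from tammune import predict, synth
from tammune.predict import MlpModel, _loss_and_grads


def make_feature_table(n=120, seed=0, separable=True, n_features=7):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    if separable:
        w = rng.uniform(1.5, 3.0, n_features)
        y = (X @ w + 0.3 * rng.normal(size=n) > 0).astype(int)
    else:
        y = rng.integers(0, 2, n)
    cols = [f"f{i}" for i in range(n_features)]
    ft = pd.DataFrame(X, columns=cols, index=[f"s{i}" for i in range(n)])
    ft = (ft - ft.mean()) / ft.std(ddof=0)
    ft["response"] = y
    return ft


class TestBuildFeatures:
    def test_seven_features_from_generator(self, bulk_cohort):
        ft = predict.build_features(
            bulk_cohort.expression, bulk_cohort.true_fractions, bulk_cohort.response
        )
        assert list(ft.columns)[:-1] == list(predict.FEATURE_COLUMNS)
        np.testing.assert_allclose(ft.drop(columns="response").mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(ft.drop(columns="response").std(ddof=0), 1.0, atol=1e-9)

    def test_hot_samples_have_higher_chemokine_features(self, bulk_cohort):
        ft = predict.build_features(
            bulk_cohort.expression, bulk_cohort.true_fractions, bulk_cohort.response
        )
        hot = (bulk_cohort.hot_labels == "hot").to_numpy()
        for gene in synth.CHEMOKINES:
            assert ft.loc[hot, gene].mean() > ft.loc[~hot, gene].mean()

    def test_contract_errors(self, bulk_cohort):
        with pytest.raises(ValueError, match="missing from fractions"):
            predict.build_features(
                bulk_cohort.expression,
                bulk_cohort.true_fractions.iloc[:-3],
                bulk_cohort.response,
            )
        with pytest.raises(ValueError, match="cell-type column"):
            predict.build_features(
                bulk_cohort.expression,
                bulk_cohort.true_fractions.drop(columns="Macrophages.M1"),
                bulk_cohort.response,
            )

    def test_constant_feature_rejected_with_hint(self, bulk_cohort):
        frac = bulk_cohort.true_fractions.copy()
        frac["Macrophages.M1"] = 0.25
        with pytest.raises(ValueError, match="constant feature"):
            predict.build_features(bulk_cohort.expression, frac, bulk_cohort.response)


class TestTrainMlp:
    def test_architecture_and_determinism(self):
        ft = make_feature_table()
        m1 = predict.train_mlp(ft, epochs=50, seed=4)
        m2 = predict.train_mlp(ft, epochs=50, seed=4)
        assert m1.layer_sizes == [7, 20, 5, 1]
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_gradient_matches_finite_differences(self):
        """Analytic backprop vs central differences, dropout off."""
        ft = make_feature_table(n=40, seed=1)
        model = predict.train_mlp(ft, epochs=1, dropout_rate=0.0, seed=2)
        X = ft.drop(columns="response").to_numpy()
        y = ft["response"].to_numpy(dtype=float)
        _, gW, gb = _loss_and_grads(model, X, y, dropout=False)
        rng = np.random.default_rng(0)
        eps = 1e-5
        worst = 0.0
        for li in range(3):
            for arr, grad in ((model.weights[li], gW[li]), (model.biases[li], gb[li])):
                flat = arr.reshape(-1)
                for idx in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp, _, _ = _loss_and_grads(model, X, y, dropout=False)
                    flat[idx] = orig - eps
                    lm, _, _ = _loss_and_grads(model, X, y, dropout=False)
                    flat[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    g = grad.reshape(-1)[idx]
                    worst = max(worst, abs(num - g) / max(1e-8, abs(num) + abs(g)))
        assert worst < 1e-4

    def test_loss_non_increasing_without_dropout(self):
        ft = make_feature_table(n=80, seed=3)
        model = predict.train_mlp(ft, lr=0.05, epochs=300, dropout_rate=0.0, seed=1)
        trace = np.array(model.loss_trace)
        assert (np.diff(trace) <= 1e-10).all()

    def test_separable_features_reach_high_training_auc(self):
        ft = make_feature_table(n=200, seed=5, separable=True)
        model = predict.train_mlp(ft, seed=6)
        res = predict.evaluate(predict.predict_proba(model, ft), ft["response"])
        assert res.auc >= 0.95

    def test_shuffled_labels_are_uninformative(self):
        """Held-out AUC under label shuffling centers on chance level."""
        rng = np.random.default_rng(7)
        aucs = []
        for s in range(10):
            ft = make_feature_table(n=120, seed=100 + s, separable=True)
            shuffled = ft.copy()
            shuffled["response"] = rng.permutation(shuffled["response"].to_numpy())
            train, test = shuffled.iloc[:80], shuffled.iloc[80:]
            if test["response"].nunique() < 2 or train["response"].nunique() < 2:
                continue
            model = predict.train_mlp(train, epochs=500, seed=s)
            res = predict.evaluate(
                predict.predict_proba(model, test), test["response"]
            )
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_input_contracts(self):
        ft = make_feature_table(n=30)
        single = ft.copy()
        single["response"] = 1
        with pytest.raises(ValueError, match="single class"):
            predict.train_mlp(single)
        with pytest.raises(ValueError, match=">= 20 samples"):
            predict.train_mlp(ft.iloc[:10])


class TestPredictProba:
    def test_zero_network_outputs_half(self):
        ft = make_feature_table(n=30)
        model = predict.train_mlp(ft, epochs=1, seed=0)
        for w in model.weights:
            w[:] = 0.0
        for b in model.biases:
            b[:] = 0.0
        proba = predict.predict_proba(model, ft)
        np.testing.assert_allclose(proba, 0.5)

    def test_monotone_in_input_with_nonnegative_weights(self):
        ft = make_feature_table(n=25)
        model = predict.train_mlp(ft, epochs=1, seed=0)
        for w in model.weights:
            np.abs(w, out=w)
        base = predict.predict_proba(model, ft)
        bumped = ft.copy()
        bumped["f0"] = bumped["f0"] + 1.0
        up = predict.predict_proba(model, bumped)
        assert (up.to_numpy() >= base.to_numpy() - 1e-12).all()

    def test_save_load_round_trip_is_bit_exact(self, tmp_path):
        ft = make_feature_table(n=60, seed=9)
        model = predict.train_mlp(ft, epochs=200, seed=10)
        before = predict.predict_proba(model, ft)
        path = tmp_path / "model.json"
        model.save(path)
        reloaded = MlpModel.load(path)
        after = predict.predict_proba(reloaded, ft)
        np.testing.assert_array_equal(before.to_numpy(), after.to_numpy())

    def test_schema_mismatch_rejected(self):
        ft = make_feature_table(n=30)
        model = predict.train_mlp(ft, epochs=1, seed=0)
        renamed = ft.rename(columns={"f0": "other"})
        with pytest.raises(ValueError, match="do not match"):
            predict.predict_proba(model, renamed)


class TestEvaluate:
    @staticmethod
    def pair_count_auc(scores, labels):
        """P(score_pos > score_neg) + 0.5 P(tie) by exhaustive pairs."""
        pos = [s for s, y in zip(scores, labels) if y == 1]
        neg = [s for s, y in zip(scores, labels) if y == 0]
        wins = ties = 0
        for sp, sn in itertools.product(pos, neg):
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
        return (wins + 0.5 * ties) / (len(pos) * len(neg))

    def test_perfect_separation(self):
        p = pd.Series([0.9, 0.8, 0.2, 0.1], index=list("abcd"))
        y = pd.Series([1, 1, 0, 0], index=list("abcd"))
        res = predict.evaluate(p, y)
        assert res.auc == 1.0
        assert res.confusion.loc["pred_pos", "true_pos_class"] == 2
        assert res.confusion.loc["pred_neg", "true_neg_class"] == 2

    def test_matches_pair_counting_on_eight_sample_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            scores = rng.choice([0.1, 0.3, 0.5, 0.5, 0.7, 0.9], size=8)
            labels = rng.integers(0, 2, 8)
            if labels.sum() in (0, 8):
                continue
            idx = [f"s{i}" for i in range(8)]
            res = predict.evaluate(pd.Series(scores, index=idx), pd.Series(labels, index=idx))
            assert res.auc == pytest.approx(self.pair_count_auc(scores, labels))

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(13)
        p = pd.Series(rng.uniform(size=1000), index=[f"s{i}" for i in range(1000)])
        y = pd.Series(rng.integers(0, 2, 1000), index=p.index)
        res = predict.evaluate(p, y)
        assert abs(res.auc - 0.5) < 0.05

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(17)
        p = pd.Series(rng.uniform(size=50), index=[f"s{i}" for i in range(50)])
        y = pd.Series(rng.integers(0, 2, 50), index=p.index)
        a = predict.evaluate(p, y).auc
        b = predict.evaluate(p ** 3, y).auc
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        p = pd.Series([0.1, 0.9], index=["a", "b"])
        with pytest.raises(ValueError, match="both classes"):
            predict.evaluate(p, pd.Series([1, 1], index=["a", "b"]))
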