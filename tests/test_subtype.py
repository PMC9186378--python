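import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tammune import subtype, synth
from tammune.matrix import ExpressionMatrix

from conftest import best_permutation_agreement


class TestConsensusCluster:
    def test_two_point_masses_give_block_consensus(self):
        X = pd.DataFrame(
            np.vstack([np.zeros((20, 3)), np.ones((20, 3)) * 10]),
            index=[f"s{i}" for i in range(40)],
        )
        res = subtype.consensus_cluster(X, k=2, reps=50, seed=1)
        C = res.consensus_matrix.to_numpy()
        np.testing.assert_allclose(C[:20, :20], 1.0)
        np.testing.assert_allclose(C[20:, 20:], 1.0)
        np.testing.assert_allclose(C[:20, 20:], 0.0)
        assert res.pac_score == 0.0
        labs = res.labels.to_numpy()
        assert len(set(labs[:20])) == 1 and len(set(labs[20:])) == 1
        assert labs[0] != labs[-1]

    def test_separated_gaussian_blobs_recovered(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (50, 4)), rng.normal(6, 1, (50, 4))])
        truth = np.repeat([0, 1], 50)
        res = subtype.consensus_cluster(pd.DataFrame(X), k=2, reps=100, seed=2)
        assert adjusted_rand_score(truth, res.labels) >= 0.99

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        a = subtype.consensus_cluster(X, k=3, reps=40, seed=5)
        b = subtype.consensus_cluster(X, k=3, reps=40, seed=5)
        pd.testing.assert_series_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(a.consensus_matrix, b.consensus_matrix)

    def test_consensus_matrix_is_valid(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(24, 4)))
        res = subtype.consensus_cluster(X, k=2, reps=30, seed=0)
        C = res.consensus_matrix.to_numpy()
        assert ((C >= 0) & (C <= 1)).all()
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_more_reps_stabilize_pac(self):
        """Monte-Carlo spread of PAC shrinks when reps grow 50 -> 500."""
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(40, 4)))  # structureless: PAC noisy
        spread = {}
        for reps in (50, 500):
            pacs = [
                subtype.consensus_cluster(X, k=2, reps=reps, seed=s).pac_score
                for s in range(5)
            ]
            spread[reps] = np.std(pacs)
        assert spread[500] < spread[50]

    def test_input_contracts(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="k must lie"):
            subtype.consensus_cluster(X, k=1)
        with pytest.raises(ValueError, match="k must lie"):
            subtype.consensus_cluster(X, k=6)
        with pytest.raises(ValueError, match="zero-variance"):
            subtype.consensus_cluster(pd.DataFrame(np.ones((10, 3))), k=2)


class TestTwoStepSubtype:
    def test_recovers_planted_structure(self, subtype_cohort):
        labels = subtype.two_step_subtype(
            subtype_cohort.true_fractions,
            subtype_cohort.expression,
            subtype_cohort.early_genes,
            seed=11,
            reps=100,
        )
        assert best_permutation_agreement(labels, subtype_cohort.subtypes) >= 0.9

    def test_partitions_all_samples(self, subtype_cohort):
        labels = subtype.two_step_subtype(
            subtype_cohort.true_fractions,
            subtype_cohort.expression,
            subtype_cohort.early_genes,
            seed=11,
            reps=50,
        )
        counts = labels.value_counts()
        assert counts.sum() == len(subtype_cohort.true_fractions)
        assert set(counts.index) <= {"A1", "A2", "A3", "B"}

    def test_b_removal_leaves_a_labels_unchanged(self, subtype_cohort):
        """Step 2 depends only on the A samples: dropping the cold (B)
        samples and rerunning with the A/B split given reproduces the
        A1/A2/A3 labels exactly."""
        full = subtype.two_step_subtype(
            subtype_cohort.true_fractions, subtype_cohort.expression,
            subtype_cohort.early_genes, seed=11, reps=100,
        )
        a_samples = list(full.index[full != "B"])
        rerun = subtype.two_step_subtype(
            subtype_cohort.true_fractions.loc[a_samples],
            subtype_cohort.expression.subset(samples=a_samples),
            subtype_cohort.early_genes, seed=11, reps=100,
            ab_labels=pd.Series("A", index=a_samples),
        )
        assert (rerun == full.loc[a_samples]).all()

    def test_identical_samples_rejected(self):
        frac = pd.DataFrame(
            np.tile([0.5, 0.5], (20, 1)), columns=["T.cells.CD8", "Macrophages.M1"],
            index=[f"s{i}" for i in range(20)],
        )
        expr = ExpressionMatrix(
            pd.DataFrame(np.ones((4, 20)), index=list("abcd"), columns=frac.index)
        )
        with pytest.raises(ValueError, match="zero-variance"):
            subtype.two_step_subtype(frac, expr, ["a", "b"], seed=0, reps=10)

    def test_sample_mismatch_rejected(self, subtype_cohort):
        with pytest.raises(ValueError, match="share"):
            subtype.two_step_subtype(
                subtype_cohort.true_fractions.iloc[:-5],
                subtype_cohort.expression,
                subtype_cohort.early_genes,
            )


class TestLogrank:
    @staticmethod
    def risk_table_oracle(time, event, group):
        """Literal observed-minus-expected log-rank computation."""
        times = sorted(set(t for t, e in zip(time, event) if e))
        O1 = E1 = V = 0.0
        for tt in times:
            at_risk = [(g, t, e) for g, t, e in zip(group, time, event) if t >= tt]
            n = len(at_risk)
            n1 = sum(1 for g, _, _ in at_risk if g == 1)
            d = sum(1 for _, t, e in at_risk if t == tt and e)
            d1 = sum(1 for g, t, e in at_risk if g == 1 and t == tt and e)
            O1 += d1
            E1 += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        return (O1 - E1) ** 2 / V

    def test_identical_groups_are_null(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        surv = pd.DataFrame(
            {"time": times * 2, "event": [1] * 10},
            index=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series(["x"] * 5 + ["y"] * 5, index=surv.index)
        chi2, p = subtype.logrank(surv, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_risk_table_oracle_on_worked_fixture(self):
        time = [2.0, 3.0, 5.0, 7.0, 11.0, 1.0, 4.0, 6.0, 8.0, 9.0]
        event = [1, 0, 1, 1, 0, 1, 1, 1, 0, 1]
        group = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        surv = pd.DataFrame({"time": time, "event": event},
                            index=[f"s{i}" for i in range(10)])
        labels = pd.Series(["a" if g else "b" for g in group], index=surv.index)
        chi2, _ = subtype.logrank(surv, labels)
        assert chi2 == pytest.approx(self.risk_table_oracle(time, event, group), rel=1e-6)

    def test_power_under_hazard_ratio_three(self):
        rng = np.random.default_rng(6)
        t1 = rng.exponential(1.0, 100)
        t2 = rng.exponential(3.0, 100)
        surv = pd.DataFrame(
            {"time": np.concatenate([t1, t2]), "event": np.ones(200, dtype=int)},
            index=[f"s{i}" for i in range(200)],
        )
        labels = pd.Series(["fast"] * 100 + ["slow"] * 100, index=surv.index)
        _, p = subtype.logrank(surv, labels)
        assert p < 0.01

    def test_label_swap_symmetry(self, bulk_cohort):
        chi2_a, p_a = subtype.logrank(bulk_cohort.survival, bulk_cohort.hot_labels)
        swapped = bulk_cohort.hot_labels.map({"hot": "cold", "cold": "hot"})
        chi2_b, p_b = subtype.logrank(bulk_cohort.survival, swapped)
        assert chi2_a == pytest.approx(chi2_b)
        assert p_a == pytest.approx(p_b)

    def test_planted_hazard_ratio_detected(self, bulk_cohort):
        chi2, p = subtype.logrank(bulk_cohort.survival, bulk_cohort.hot_labels)
        assert p < 0.05

    def test_input_contracts(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="2 non-empty groups"):
            subtype.logrank(surv, pd.Series(["x", "x"], index=["a", "b"]))
        with pytest.raises(ValueError, match="at least one event"):
            subtype.logrank(
                pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]}, index=["a", "b"]),
                pd.Series(["x", "y"], index=["a", "b"]),
            )


def test_km_curve_is_monotone_step_function(bulk_cohort):
    curve = subtype.km_curve(bulk_cohort.survival)
    assert (np.diff(curve["survival"]) <= 1e-12).all()
    assert curve["survival"].iloc[0] <= 1.0
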