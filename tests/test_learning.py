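"""Cross-validation planning, classifier training, descriptor selection, and
the enrichment objective."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from tmcontact import learning
from tmcontact.learning import (
    ANNMember,
    CrossValidationPlan,
    ModelEnsemble,
    PlanningError,
    TrainingConfig,
    TrainingError,
    _ANN,
)


class TestCvPlan:
    ids = [f"P{k:02d}" for k in range(25)]

    def test_each_protein_independent_exactly_once(self):
        plan = learning.make_cv_plan(self.ids, seed=3)
        seen = [p for fold in plan.folds for p in fold["independent"]]
        assert sorted(seen) == sorted(self.ids)

    def test_roles_disjoint_within_fold(self):
        plan = learning.make_cv_plan(self.ids, seed=3)
        for fold in plan.folds:
            all_ids = fold["train"] + fold["monitor"] + fold["independent"]
            assert len(all_ids) == len(set(all_ids)) == 25

    def test_linked_pair_always_co_assigned(self):
        linked = [("P03", "P17"), ("P04", "P11")]
        plan = learning.make_cv_plan(self.ids, linked, seed=5)
        for fold in plan.folds:
            for a, b in linked:
                for role in ("train", "monitor", "independent"):
                    assert (a in fold[role]) == (b in fold[role])

    def test_deterministic_under_seed(self):
        assert learning.make_cv_plan(self.ids, seed=9).folds == \
            learning.make_cv_plan(self.ids, seed=9).folds

    def test_unsplittable_counts_rejected(self):
        with pytest.raises(PlanningError):
            learning.make_cv_plan(self.ids[:24], seed=0)

    def test_oversized_linked_group_rejected(self):
        linked = [(f"P{k:02d}", f"P{k+1:02d}") for k in range(0, 6)]
        with pytest.raises(PlanningError):
            learning.make_cv_plan(self.ids, linked, seed=0)


def tiny_dataset(rows_per_protein=6, n_proteins=5, seed=0, n_features=3):
    rng = np.random.default_rng(seed)
    n = rows_per_protein * n_proteins
    X = rng.normal(size=(n, n_features))
    y = (X[:, 0] > 0).astype(float)
    y[0] = 1.0
    y[1] = 0.0  # both classes everywhere
    df = pd.DataFrame({
        "protein_id": np.repeat([f"Q{k}" for k in range(n_proteins)], rows_per_protein),
        "i": np.arange(n), "j": np.arange(n) + 12,
    })
    for k in range(n_features):
        df[f"x{k}"] = X[:, k]
    df["label"] = y
    return df


class TestTrainEnsemble:
    def test_small_nodes_stay_leaves(self):
        # each fold trains on 3 proteins x 6 rows = 18 < 20 points
        df = tiny_dataset()
        plan = learning.make_cv_plan(sorted(df["protein_id"].unique()), seed=1)
        ens = learning.train_ensemble(df, plan, "dt", TrainingConfig(seed=1))
        for member in ens.members:
            assert member.tree.tree_.node_count == 1
        relaxed = learning.train_ensemble(
            df, plan, "dt", TrainingConfig(seed=1, min_node_size=2)
        )
        assert any(m.tree.tree_.node_count > 1 for m in relaxed.members)

    def test_single_class_fold_rejected(self):
        df = tiny_dataset()
        df["label"] = 1.0
        plan = learning.make_cv_plan(sorted(df["protein_id"].unique()), seed=1)
        with pytest.raises(TrainingError):
            learning.train_ensemble(df, plan, "dt", TrainingConfig(seed=1))

    def test_training_is_deterministic(self):
        df = tiny_dataset(rows_per_protein=20)
        plan = learning.make_cv_plan(sorted(df["protein_id"].unique()), seed=2)
        cfg = TrainingConfig(seed=4, max_epochs=40, patience=40)
        for kind in ("dt", "ann"):
            a = learning.train_ensemble(df, plan, kind, cfg)
            b = learning.train_ensemble(df, plan, kind, cfg)
            X = df[a.feature_names]
            assert np.array_equal(learning.predict(a, X), learning.predict(b, X))

    @pytest.mark.parametrize("kind", ["dt", "ann"])
    def test_separable_features_reach_high_heldout_auc(
        self, kind, separable_dataset, trained_ensembles
    ):
        df = separable_dataset["data"]
        scored = learning.predict_independent(trained_ensembles[kind], df)
        merged = scored.merge(df[["protein_id", "i", "j", "label"]], on=["protein_id", "i", "j"])
        assert roc_auc_score(merged["label"], merged["propensity"]) > 0.95


class FixedMember:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.value)


class TestPredict:
    def make_ensemble(self, values):
        plan = CrossValidationPlan(
            folds=[{"train": [], "monitor": [], "independent": []} for _ in values],
            seed=0,
        )
        return ModelEnsemble(
            members=[FixedMember(v) for v in values],
            model_kind="dt",
            feature_names=["a", "b"],
            config=TrainingConfig(),
            plan=plan,
        )

    def test_mean_of_members(self):
        X = np.zeros((4, 2))
        ens = self.make_ensemble([1, 1, 1, 1, 1])
        assert np.allclose(learning.predict(ens, X), 1.0)
        ens = self.make_ensemble([0, 0, 0, 0, 1])
        assert np.allclose(learning.predict(ens, X), 0.2)

    def test_member_permutation_invariant(self):
        X = np.zeros((3, 2))
        a = self.make_ensemble([0.1, 0.5, 0.9, 0.3, 0.7])
        b = self.make_ensemble([0.7, 0.3, 0.9, 0.5, 0.1])
        assert np.allclose(learning.predict(a, X), learning.predict(b, X))

    def test_schema_mismatch_names_missing_columns(self):
        ens = self.make_ensemble([0.5] * 5)
        with pytest.raises(ValueError, match="missing columns.*'b'"):
            learning.predict(ens, pd.DataFrame({"a": [1.0]}))


class TestFeatureRanking:
    def test_label_copy_feature_is_perfect(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=50).astype(float)
        df = pd.DataFrame({"protein_id": "P", "i": 0, "j": 12,
                           "copy": y, "label": y})
        out = learning.rank_features_f1_infogain(df, ["copy"])
        p = y.mean()
        expected_entropy = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        assert out.loc[0, "f1"] == pytest.approx(1.0)
        assert out.loc[0, "info_gain"] == pytest.approx(expected_entropy)

    def test_constant_feature_zero_gain(self):
        df = pd.DataFrame({"protein_id": "P", "i": 0, "j": 12,
                           "const": 1.0, "label": [0.0, 1.0] * 10})
        out = learning.rank_features_f1_infogain(df, ["const"])
        assert out.loc[0, "info_gain"] == 0.0

    def test_toy_table_matches_threshold_enumeration(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = rng.integers(0, 2, size=20).astype(float)
        df = pd.DataFrame({"protein_id": "P", "i": 0, "j": 12, "x": x, "label": y})
        out = learning.rank_features_f1_infogain(df, ["x"])

        def entropy(v):
            if len(v) == 0:
                return 0.0
            p = v.mean()
            return -sum(q * np.log2(q) for q in (p, 1 - p) if q > 0)

        # brute-force enumeration over thresholds and directions
        best_f1, best_gain = -1.0, None
        xs = np.sort(np.unique(x))
        for thr in (xs[:-1] + xs[1:]) / 2:
            for direction in ("gt", "lt"):
                pred = x > thr if direction == "gt" else x < thr
                tp = float(np.sum(pred & (y == 1)))
                if pred.sum() == 0 or y.sum() == 0:
                    f1 = 0.0
                else:
                    prec, rec = tp / pred.sum(), tp / y.sum()
                    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
                if f1 > best_f1:
                    below = y[x <= thr]
                    above = y[x > thr]
                    gain = entropy(y) - (
                        len(below) / 20 * entropy(below) + len(above) / 20 * entropy(above)
                    )
                    best_f1, best_gain = f1, gain
        assert out.loc[0, "f1"] == pytest.approx(best_f1)
        assert out.loc[0, "info_gain"] == pytest.approx(best_gain)


class TestInputSensitivity:
    def test_ignored_feature_has_zero_sensitivity(self):
        df = tiny_dataset(rows_per_protein=30, n_features=3)
        plan = learning.make_cv_plan(sorted(df["protein_id"].unique()), seed=1)
        cfg = TrainingConfig(seed=1, min_node_size=2)
        # depth-1 stumps can use at most one feature
        ens = learning.train_ensemble(df, plan, "dt", cfg)
        for m in ens.members:
            m.tree.max_depth = 1
        sens = learning.input_sensitivities(ens, df)
        used = {
            f for m in ens.members
            for f in np.array(ens.feature_names)[
                [k for k in m.tree.tree_.feature if k >= 0]
            ]
        }
        for feature in ens.feature_names:
            if feature not in used:
                assert sens[feature] == 0.0

    def test_sensitivity_tracks_weight_magnitude(self):
        # single-hidden-unit network in its near-linear regime
        net = _ANN(n_in=3, n_hidden=1, seed=0)
        net.W1 = np.array([[0.3], [0.1], [-0.6]])
        net.b1 = np.zeros(1)
        net.W2 = np.array([0.5])
        net.b2 = 0.0
        member = ANNMember(net, mean=np.zeros(3), scale=np.ones(3))
        plan = CrossValidationPlan(
            folds=[{"train": [], "monitor": ["P"], "independent": []}], seed=0
        )
        ens = ModelEnsemble([member], "ann", ["a", "b", "c"], TrainingConfig(), plan)
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(scale=0.05, size=(200, 3)), columns=["a", "b", "c"])
        df["protein_id"] = "P"
        df["i"] = 0
        df["j"] = 12
        df["label"] = 0.5
        sens = learning.input_sensitivities(ens, df)
        assert sens["c"] > sens["a"] > sens["b"]

    def test_prune_schedule_never_removes_more_than_half(self):
        df = tiny_dataset(rows_per_protein=30, n_features=8)
        plan = learning.make_cv_plan(sorted(df["protein_id"].unique()), seed=1)
        with pytest.raises(ValueError, match="more than half"):
            learning.input_sensitivity_prune(
                df, plan, "dt", TrainingConfig(seed=1), schedule=[3]
            )

    def test_prune_stages_are_nested(self):
        df = tiny_dataset(rows_per_protein=30, n_features=8)
        plan = learning.make_cv_plan(sorted(df["protein_id"].unique()), seed=1)
        stages = learning.input_sensitivity_prune(
            df, plan, "dt", TrainingConfig(seed=1, min_node_size=5), schedule=[6, 4]
        )
        sets = [set(s["features"]) for s in stages]
        assert len(sets[0]) == 8 and len(sets[1]) == 6 and len(sets[2]) == 4
        assert sets[2] <= sets[1] <= sets[0]


class TestAnnWeightScores:
    def make_ensemble(self, nets):
        members = [ANNMember(n, np.zeros(n.W1.shape[0]), np.ones(n.W1.shape[0])) for n in nets]
        plan = CrossValidationPlan(
            folds=[{"train": [], "monitor": [], "independent": []} for _ in nets], seed=0
        )
        return ModelEnsemble(members, "ann", ["a", "b"], TrainingConfig(), plan)

    def fixed_net(self, w11, w21, v):
        net = _ANN(2, 1, seed=0)
        net.W1 = np.array([[w11], [w21]], dtype=float)
        net.b1 = np.zeros(1)
        net.W2 = np.array([v], dtype=float)
        net.b2 = 0.0
        return net

    def test_zero_weight_input_scores_zero(self):
        ens = self.make_ensemble([self.fixed_net(1.0, 0.0, 1.0)])
        out = learning.ann_weight_scores(ens).set_index("feature")
        assert out.loc["b", "score"] == 0.0
        assert out.loc["b", "mean_derivative"] == 0.0

    def test_derivative_matches_chain_rule(self):
        w11, w21, v = 0.8, -0.4, 1.2
        ens = self.make_ensemble([self.fixed_net(w11, w21, v)])
        out = learning.ann_weight_scores(ens).set_index("feature")
        h = expit(0.0)
        y = expit(h * v)
        for name, w in (("a", w11), ("b", w21)):
            expect = y * (1 - y) * v * h * (1 - h) * w
            assert out.loc[name, "mean_derivative"] == pytest.approx(expect)

    def test_consistency_flags_sign_agreement(self):
        nets = [self.fixed_net(0.5, -0.5, 1.0), self.fixed_net(0.9, 0.5, 1.0)]
        out = learning.ann_weight_scores(self.make_ensemble(nets)).set_index("feature")
        assert bool(out.loc["a", "consistent"])
        assert not bool(out.loc["b", "consistent"])

    def test_dt_ensemble_unsupported(self, trained_ensembles):
        with pytest.raises(TypeError):
            learning.ann_weight_scores(trained_ensembles["dt"])


class TestEnrichmentObjective:
    def test_perfect_ranking_at_two_percent_base_rate(self):
        n = 100_000
        y = np.zeros(n)
        y[: n // 50] = 1.0  # 2% positives
        scores = -np.arange(n, dtype=float)  # descending with label order
        avg_enr, integral = learning.enrichment_objective(scores, y)
        assert integral == pytest.approx(0.0054)
        assert avg_enr == pytest.approx(50.0)

    def test_random_ranking_enrichment_near_one(self):
        rng = np.random.default_rng(15)
        n = 200_000
        y = (rng.random(n) < 0.05).astype(float)
        scores = rng.random(n)
        avg_enr, _ = learning.enrichment_objective(scores, y)
        assert avg_enr == pytest.approx(1.0, abs=0.25)

    def test_toy_curve_matches_cumulative_scan(self):
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0, 0, 0], dtype=float)
        scores = np.array([9, 8, 7, 6, 5, 4, 3, 2, 1, 0], dtype=float)
        f, prec = learning.precision_fpp_curve(scores, y, (0.1, 1.0), n_grid=10)
        for fk, pk in zip(f, prec):
            k = int(np.ceil(fk * 10))
            assert pk == pytest.approx(y[:k].sum() / k)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            learning.enrichment_objective([1.0], [1.0], (0.0, 0.5))
        with pytest.raises(ValueError):
            learning.enrichment_objective([1.0], [1.0], (0.1, 1.5))


def test_bundle_round_trip(tmp_path, trained_ensembles, separable_dataset):
    ens = trained_ensembles["dt"]
    learning.save_ensemble(ens, tmp_path / "bundle")
    again = learning.load_ensemble(tmp_path / "bundle")
    X = separable_dataset["data"][ens.feature_names].head(50)
    assert np.allclose(learning.predict(ens, X), learning.predict(again, X))
    assert again.feature_names == ens.feature_names
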