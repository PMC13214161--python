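import warnings

import numpy as np
import pytest
from scipy.stats import kendalltau

from tsponet.classify import (ClassifierConfig, binary_disease_classifier,
                              chance_ap, coefficient_overlap,
                              multiclass_classifier, nuisance_classifier,
                              regional_importance)
from tsponet.harmonize import fit_confound_model, residualize
from tsponet.simulate import simulate_edge_cohort

FAST = ClassifierConfig(n_repeats=1, n_folds=4, n_boot=100, seed=0,
                        c_grid=(1e-2, 1.0, 1e2), knn_grid=(3, 5),
                        l1_ratio_grid=(0.5,), svm_kernels=("linear",))


def _residualized_cohort(disease="MS", delta=0.12, noise=0.03, n=25, seed=4,
                         **kwargs):
    edges, cov, truth = simulate_edge_cohort(
        n_per_group={"HC": n, disease: n}, atlas=20,
        disease_effects={disease: ([2, 5, 8], delta)}, noise_sd=noise,
        seed=seed, **kwargs)
    model = fit_confound_model(edges, cov, hc_only=True,
                               terms=("sex", "genotype", "age",
                                      "dose_over_weight"))
    return residualize(edges, model, cov), cov


class TestOneVsAllAssembly:
    def _frame(self):
        import pandas as pd
        rows = ([("PBR28", "HC")] * 3 + [("PBR28", "TBI")] * 2
                + [("PBR28", "SCZ")] * 2 + [("DPA714", "HC")] * 3
                + [("DPA714", "FEP")] * 2 + [("PK11195", "HC")] * 2
                + [("PK11195", "DEP")] * 2)
        return pd.DataFrame(rows, columns=["tracer", "group"])

    def test_same_tracer_controls_and_pooled_psychosis(self):
        from tsponet.classify import one_vs_all_tasks
        frame = self._frame()
        tasks = one_vs_all_tasks(frame)
        assert set(tasks) == {"TBI", "DEP", "FEP+SCZ"}
        # TBI against PBR28 controls only
        tbi = frame[tasks["TBI"]]
        assert set(tbi["tracer"]) == {"PBR28"}
        assert set(tbi["group"]) == {"HC", "TBI"}
        # psychosis pooled across both second-generation tracers
        psy = frame[tasks["FEP+SCZ"]]
        assert set(psy["group"]) == {"HC", "SCZ", "FEP"}
        assert set(psy["tracer"]) == {"PBR28", "DPA714"}
        # PK11195 controls appear only in the DEP task
        dep = frame[tasks["DEP"]]
        assert set(dep["tracer"]) == {"PK11195"}

    def test_no_disease_rejected(self):
        import pandas as pd
        from tsponet.classify import one_vs_all_tasks
        with pytest.raises(ValueError, match="no disease"):
            one_vs_all_tasks(pd.DataFrame({"tracer": ["a"], "group": ["HC"]}))


class TestChanceAp:
    def test_prevalence_examples(self):
        y = np.r_[np.ones(74), np.zeros(68)]
        assert chance_ap(y) == pytest.approx(74 / 142)
        assert round(chance_ap(y), 2) == 0.52
        assert chance_ap([0, 1, 0, 1]) == 0.5
        assert chance_ap([1, 1, 1]) == 1.0

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError):
            chance_ap([])
        with pytest.raises(ValueError):
            chance_ap([0, 0])


class TestBinaryClassifier:
    def test_separable_cohort_perfect(self):
        resid, cov = _residualized_cohort(delta=0.15, noise=0.01)
        y = (cov["group"] == "MS").to_numpy(int)
        rep = binary_disease_classifier(resid, y, FAST)
        assert rep.test_ap == pytest.approx(1.0, abs=1e-9)
        assert rep.test_auc == pytest.approx(1.0, abs=1e-9)
        assert rep.test_ap > rep.chance_ap

    def test_shuffled_labels_near_chance(self):
        resid, cov = _residualized_cohort(delta=0.15, noise=0.01)
        rng = np.random.default_rng(7)
        y = rng.permutation((cov["group"] == "MS").to_numpy(int))
        rep = binary_disease_classifier(resid, y, FAST)
        assert rep.ap_ci[0] <= rep.chance_ap + 0.15
        assert rep.test_ap < 0.95

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="one class"):
            binary_disease_classifier(rng.random((10, 5)), np.zeros(10), FAST)

    def test_seeded_determinism(self):
        resid, cov = _residualized_cohort()
        y = (cov["group"] == "MS").to_numpy(int)
        a = binary_disease_classifier(resid, y, FAST)
        b = binary_disease_classifier(resid, y, FAST)
        assert a.test_ap == b.test_ap and a.ap_ci == b.ap_ci
        np.testing.assert_array_equal(a.coef, b.coef)


class TestRegionalImportance:
    def test_three_roi_toy(self):
        df = regional_importance([0.5, -0.25, 0.0], 3)
        scores = df.set_index("roi")["importance"]
        assert scores["roi_0"] == pytest.approx(0.75)
        assert scores["roi_1"] == pytest.approx(0.5)
        assert scores["roi_2"] == pytest.approx(0.25)
        assert list(df["top3"]) == [True, True, True]

    def test_zero_coefficients(self):
        assert (regional_importance(np.zeros(190), 20)["importance"] == 0).all()

    def test_conservation(self, rng):
        beta = rng.normal(size=190)
        df = regional_importance(beta, 20)
        assert df["importance"].sum() == pytest.approx(2 * np.abs(beta).sum())

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            regional_importance(np.zeros(10), 20)


class TestCoefficientOverlap:
    def test_self_and_reversal(self, rng):
        v = rng.normal(size=50)
        df = coefficient_overlap({"a": v, "b": v, "c": v[np.argsort(v)][::-1][np.argsort(np.argsort(v))]})
        tab = df.set_index(["task_a", "task_b"])["tau"]
        assert tab[("a", "b")] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        v = np.arange(10.0)
        df = coefficient_overlap({"a": v, "b": v[::-1]})
        assert df["tau"].iloc[0] == pytest.approx(-1.0)

    def test_brute_force_pair_counting_oracle(self, rng):
        """tau-b from concordant/discordant pair counting on a length-10
        vector pair equals the library computation."""
        x, y = rng.normal(size=10), rng.normal(size=10)
        conc = disc = 0
        for i in range(10):
            for j in range(i + 1, 10):
                s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                conc += s > 0
                disc += s < 0
        expected = (conc - disc) / (10 * 9 / 2)   # no ties in random floats
        df = coefficient_overlap({"a": x, "b": y})
        assert df["tau"].iloc[0] == pytest.approx(expected)
        assert df["tau"].iloc[0] == pytest.approx(kendalltau(x, y).statistic)

    def test_random_long_vectors_small_tau(self, rng):
        df = coefficient_overlap({"a": rng.normal(size=3741),
                                  "b": rng.normal(size=3741)})
        assert abs(df["tau"].iloc[0]) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            coefficient_overlap({"a": np.ones(5), "b": np.arange(5.0)})

    def test_bonferroni_over_pairs(self, rng):
        vs = {k: rng.normal(size=30) for k in "abc"}
        df = coefficient_overlap(vs)
        assert len(df) == 3
        np.testing.assert_allclose(df["p_bonferroni"],
                                   np.minimum(1.0, df["p"] * 3))


class TestMulticlass:
    def test_separated_groups_perfect(self):
        edges, cov, _ = simulate_edge_cohort(
            n_per_group={"MS": 15, "TBI": 15, "DEP": 15}, atlas=15,
            group_signature_sd=0.15, noise_sd=0.02, seed=6)
        rep = multiclass_classifier(edges, cov["group"].to_numpy(), FAST)
        assert rep.balanced_accuracy == 1.0

    def test_balanced_accuracy_equals_mean_recall(self):
        edges, cov, _ = simulate_edge_cohort(
            n_per_group={"MS": 12, "TBI": 12, "DEP": 12}, atlas=10,
            group_signature_sd=0.05, noise_sd=0.05, seed=8)
        rep = multiclass_classifier(edges, cov["group"].to_numpy(), FAST)
        assert rep.balanced_accuracy == pytest.approx(
            float(np.mean(rep.per_class_recall)))

    def test_shuffled_labels_near_chance(self):
        edges, cov, _ = simulate_edge_cohort(
            n_per_group={"MS": 15, "TBI": 15, "DEP": 15}, atlas=10,
            group_signature_sd=0.15, noise_sd=0.02, seed=9)
        rng = np.random.default_rng(1)
        y = rng.permutation(cov["group"].to_numpy())
        rep = multiclass_classifier(edges, y, FAST)
        assert rep.ci[0] <= 1 / 3 + 0.2

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            multiclass_classifier(rng.random((10, 5)), ["MS"] * 10, FAST)


class TestNuisanceClassifier:
    def test_planted_batch_effect_decodable(self):
        edges, cov, _ = simulate_edge_cohort(
            n_per_group={"HC": 40}, atlas=15, batches=("A", "B"),
            batch_offsets={"A": 0.0, "B": 0.06}, noise_sd=0.01, seed=3)
        rep = nuisance_classifier(edges, cov["batch"].to_numpy(), "batch", FAST)
        assert rep.best_balanced_accuracy >= 0.9
        assert set(rep.results.index) == {"logistic_elasticnet", "knn",
                                          "svm_linear"}

    def test_residualization_removes_batch_signal(self):
        edges, cov, _ = simulate_edge_cohort(
            n_per_group={"HC": 40}, atlas=15, batches=("A", "B"),
            batch_offsets={"A": 0.0, "B": 0.06}, noise_sd=0.01, seed=3)
        model = fit_confound_model(edges, cov, hc_only=True)
        resid = residualize(edges, model, cov)
        rep = nuisance_classifier(resid, cov["batch"].to_numpy(), "batch", FAST)
        assert rep.best_ci[0] <= 0.5 <= rep.best_ci[1]

    def test_single_level_rejected(self, rng):
        with pytest.raises(ValueError, match="2 levels"):
            nuisance_classifier(rng.random((10, 5)), ["A"] * 10, "batch", FAST)
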