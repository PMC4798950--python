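"""Assessment machinery: plurality scoring, coverage histograms, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from phenolearn.evaluation import (
    CoverageHistogram,
    fit_coverage_regression,
    generalize_to_novel,
    nn_plurality_assess,
    perturbation_degree,
    predict_accuracy_from_coverage,
    quad_histogram,
    simulate_random_baseline,
)
from phenolearn.learner import build_model
from phenolearn.simspace import make_ground_truth


class TestCoverageHistogram:
    def test_from_counts_normalizes(self):
        h = CoverageHistogram.from_counts([1529, 575, 164, 36, 0])
        assert h.b == 2304
        assert h.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_negative_or_mismatched(self):
        with pytest.raises(ValueError):
            CoverageHistogram(counts=np.array([1, 2, 3, 4, -1]), b=9)
        with pytest.raises(ValueError):
            CoverageHistogram(counts=np.array([1, 0, 0, 0, 0]), b=5)

    def test_no_experiments_all_mass_in_bin_zero(self, small_space):
        space, _ = small_space
        h = quad_histogram([], space)
        assert h.fractions.tolist() == [1.0, 0, 0, 0, 0]

    def test_full_space_all_mass_in_bin_four(self, small_space):
        space, _ = small_space
        h = quad_histogram(space.all_experiments(), space)
        assert h.fractions.tolist() == [0, 0, 0, 0, 1.0]

    def test_counts_multiplicity_per_quad(self, small_space):
        space, _ = small_space
        lt0 = space.visible_target_map[space.visible_targets[0]]
        twins = [v for v, l in space.visible_target_map.items() if l == lt0]
        c = space.visible_conditions[0]
        h = quad_histogram([(twins[0], c), (twins[1], c)], space)
        assert h.counts[2] == 1  # one quad sampled twice
        assert h.counts[0] == space.n_quads - 1


class TestCoverageRegression:
    def _histograms(self, rng, n):
        H = rng.dirichlet(np.ones(5), size=n)
        return H

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        H = self._histograms(rng, 12)
        beta = np.array([0.4, 1.0, -0.5, 6.0, -20.0])
        fit = fit_coverage_regression(H, H @ beta)
        assert fit.beta == pytest.approx(beta, abs=1e-10)

    def test_noisy_recovery_within_standard_errors(self):
        rng = np.random.default_rng(1)
        beta = np.array([0.4, 1.0, -0.5, 6.0, -20.0])
        misses = 0
        for _ in range(50):
            H = self._histograms(rng, 30)
            y = H @ beta + rng.normal(0, 0.01, 30)
            fit = fit_coverage_regression(H, y)
            # standard errors from the OLS covariance
            XtX_inv = np.linalg.inv(H.T @ H)
            sigma2 = (fit.residuals**2).sum() / (30 - 5)
            se = np.sqrt(np.diag(XtX_inv) * sigma2)
            misses += (np.abs(fit.beta - beta) > 3 * se).any()
        assert misses <= 5

    def test_constant_histograms_flag_rank_deficiency(self):
        H = np.tile([0.5, 0.3, 0.1, 0.1, 0.0], (6, 1))
        with pytest.warns(UserWarning, match="rank deficient"):
            fit_coverage_regression(H, np.full(6, 0.7))

    def test_too_few_rounds_raise(self):
        with pytest.raises(ValueError):
            fit_coverage_regression(np.ones((4, 5)) / 5, np.ones(4))

    def test_prediction_is_dot_product(self):
        beta = np.array([0.42, 1.0, -0.57, 6.4, -21.0])
        assert predict_accuracy_from_coverage(beta, np.eye(5)[1]) == pytest.approx(1.0)
        assert predict_accuracy_from_coverage(np.zeros(5), np.eye(5)[0]) == 0.0


class TestRandomBaseline:
    def test_full_sampling_ends_in_bin_four(self, small_space):
        space, _ = small_space
        total = len(space.all_experiments())
        beta = np.eye(5)[4]  # reads out the bin-4 fraction
        df = simulate_random_baseline([total], space, beta, n_sims=3, seed=0)
        assert df["mean_estimated_accuracy"].iloc[-1] == pytest.approx(1.0)

    def test_bin_zero_expectation_matches_hypergeometric(self, small_space):
        space, _ = small_space
        z, b = 20, space.n_quads
        total = 4 * b
        # P(a given quad untouched after z draws without replacement)
        expected = comb(total - 4, z) / comb(total, z)
        beta = np.eye(5)[0]  # reads out the bin-0 fraction
        n_sims = 800
        df = simulate_random_baseline([z], space, beta, n_sims=n_sims, seed=1)
        sd = df["sd_estimated_accuracy"].iloc[0]
        assert abs(df["mean_estimated_accuracy"].iloc[0] - expected) < 3 * sd / np.sqrt(
            n_sims
        )

    def test_reproducible_under_seed(self, small_space):
        space, _ = small_space
        beta = np.array([0.4, 1.0, -0.5, 6.0, -20.0])
        a = simulate_random_baseline([5, 5], space, beta, n_sims=1, seed=3)
        b = simulate_random_baseline([5, 5], space, beta, n_sims=1, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_batches_raise(self, small_space):
        space, _ = small_space
        with pytest.raises(ValueError):
            simulate_random_baseline([1000], space, np.zeros(5), n_sims=1, seed=0)


class TestNNPluralityAssess:
    def test_one_dimensional_toy_against_exhaustive_distances(self):
        # observed: phenotype 0 at {0,1}, phenotype 1 at {10,11}, 2 at {20}
        observed = np.array([[0.0], [1.0], [10.0], [11.0], [20.0]])
        labels = np.array([0, 0, 1, 1, 2])
        heldout = {
            "x": np.array([[0.4], [0.6], [9.0]]),  # votes: 0, 0, 1 -> plurality 0
            "y": np.array([[15.0], [19.0]]),  # votes: 1 (15->11), 2 (19->20): tie
        }
        preds = {"x": 0, "y": 1}
        correct, acc, flagged = nn_plurality_assess(preds, observed, labels, heldout)
        assert correct == {"x": True, "y": False}  # strict plurality: tie fails
        assert acc == pytest.approx(0.5)
        assert flagged == []

    def test_unknown_prediction_counted_incorrect_and_flagged(self):
        observed = np.array([[0.0], [5.0]])
        labels = np.array([0, 1])
        correct, acc, flagged = nn_plurality_assess(
            {"u": None}, observed, labels, {"u": np.array([[0.1]])}
        )
        assert correct == {"u": False}
        assert flagged == ["u"]

    def test_all_images_nearest_predicted_phenotype_correct(self):
        observed = np.vstack([np.zeros((3, 2)), np.full((3, 2), 9.0)])
        labels = np.array([0, 0, 0, 1, 1, 1])
        held = {"h": np.full((4, 2), 8.5)}
        correct, acc, _ = nn_plurality_assess({"h": 1}, observed, labels, held)
        assert correct["h"] and acc == 1.0

    def test_empty_observed_pool_raises(self):
        with pytest.raises(ValueError):
            nn_plurality_assess({}, np.empty((0, 2)), [], {})


class TestGeneralizeToNovel:
    @pytest.fixture
    def model(self):
        ph = {(0, 0): 0, (0, 1): 2, (1, 0): 1, (1, 1): 3}
        return build_model(ph, targets=[0, 1], conditions=[0, 1], seed=0)

    def test_identical_features_inherit_reference_predictions(self, model):
        ref = {0: np.zeros((5, 2)), 1: np.full((5, 2), 4.0)}
        out = generalize_to_novel(model, {"nov": np.zeros((3, 2))}, ref)
        assert out["nov"]["matched_reference"] == 0
        assert out["nov"]["predictions"] == {0: 0, 1: 2}

    def test_equidistant_tie_goes_to_lowest_id(self, model):
        ref = {0: np.full((4, 2), -1.0), 1: np.full((4, 2), 1.0)}
        out = generalize_to_novel(model, {"nov": np.zeros((2, 2))}, ref)
        assert out["nov"]["matched_reference"] == 0
        assert out["nov"]["tied_references"] == [0, 1]

    def test_novel_clone_from_existing_group_recovers_truth(self):
        # draw a novel clone's vehicle data from a reference clone's phenotype
        space, truth = make_ground_truth(3, 3, 3, 3, 9, feature_dim=4,
                                         min_separation=10.0, seed=5)
        rng = np.random.default_rng(6)
        ph = {}
        for t in space.visible_targets:
            for c in space.visible_conditions:
                ph[(t, c)] = truth.phenotype_of_quad(*space.quad_of(t, c))
        model = build_model(ph, space.visible_targets, space.visible_conditions,
                            seed=0)
        vc = min(space.vehicle_condition_ids)
        ref = {}
        for t in space.visible_targets:
            pid = truth.phenotype_of_quad(*space.quad_of(t, vc))
            ref[t] = truth.phenotype_mean[pid] + rng.normal(0, 1, (20, 4))
        t0 = space.visible_targets[0]
        pid0 = truth.phenotype_of_quad(*space.quad_of(t0, vc))
        novel = truth.phenotype_mean[pid0] + rng.normal(0, 1, (20, 4))
        out = generalize_to_novel(model, {"nov": novel}, ref)
        matched = out["nov"]["matched_reference"]
        assert (
            space.visible_target_map[matched] == space.visible_target_map[t0]
            or truth.clone_group[space.visible_target_map[matched]]
            == truth.clone_group[space.visible_target_map[t0]]
        )
        hits = sum(
            out["nov"]["predictions"][c]
            == truth.phenotype_of_quad(*space.quad_of(t0, c))
            for c in space.visible_conditions
        )
        assert hits / len(space.visible_conditions) >= 0.95


class TestPerturbationDegree:
    def _table(self):
        rows = []
        means = {(0, 0): 0.0, (0, 1): 3.0, (1, 0): 1.0, (1, 1): 5.0}
        for (t, c), m in means.items():
            for i in range(4):
                rows.append({"visible_target": t, "visible_condition": c,
                             "f0": m, "f1": m})
        return pd.DataFrame(rows)

    def test_control_distance_is_zero(self):
        deg = perturbation_degree(self._table(), vehicle_condition=0)
        assert deg[0].tolist() == [0.0, 0.0]

    def test_hand_computed_distances(self):
        deg = perturbation_degree(self._table(), vehicle_condition=0)
        assert deg.loc[0, 1] == pytest.approx(3.0 * np.sqrt(2))
        assert deg.loc[1, 1] == pytest.approx(4.0 * np.sqrt(2))

    def test_group_normalization_range(self):
        deg = perturbation_degree(
            self._table(), vehicle_condition=0,
            clone_groups={0: 0, 1: 0}, normalize=True,
        )
        vals = deg.to_numpy(dtype=float)
        assert np.nanmax(vals) == pytest.approx(1.0)
        assert (vals[~np.isnan(vals)] >= 0).all()

    def test_missing_vehicle_raises(self):
        table = self._table()
        table = table[~((table.visible_target == 1) & (table.visible_condition == 0))]
        with pytest.raises(ValueError, match="vehicle"):
            perturbation_degree(table, vehicle_condition=0)
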