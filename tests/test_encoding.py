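import numpy as np
import pytest

from viscotact.encoding import (
    EncodingConfig,
    build_design_matrix,
    build_trial_data,
    fit_ridge_nested_cv,
    inclusion_filter,
    rank_predictors_permutation,
    reduced_topk_model,
    summarize_r2_fisher,
)


def synthetic_regression(n_trials=25, n_per=40, noise=0.0, seed=0, informative=(0,)):
    """Trial-structured design with y linear in the chosen base columns."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_trials * n_per, 6))
    groups = np.repeat(np.arange(n_trials), n_per)
    y = sum(X[:, j] for j in informative) + noise * rng.normal(size=len(X))
    return X, np.asarray(y), groups


class TestDesignMatrix:
    def test_model_class_column_counts(self):
        base = np.random.default_rng(0).normal(size=(30, 6))
        assert build_design_matrix(base, "pos")[0].shape[1] == 3
        assert build_design_matrix(base, "vel")[0].shape[1] == 3
        assert build_design_matrix(base, "pos+vel")[0].shape[1] == 6
        X, names = build_design_matrix(base, "2way")
        assert X.shape[1] == 21 and len(names) == 21

    def test_two_signal_analogue_has_expected_columns(self):
        # 1 position + 1 velocity: 2 base + C(2,2)=1 product = 3
        base = np.random.default_rng(0).normal(size=(10, 2))
        X, names = build_design_matrix(base, "2way", base_names=("P", "dP"))
        assert X.shape[1] == 3 and names == ["P", "dP", "P*dP"]

    def test_product_columns_are_actual_products(self):
        base = np.arange(12.0).reshape(2, 6)
        X, names = build_design_matrix(base, "2way")
        i = names.index("Px*dPz")
        assert np.allclose(X[:, i], base[:, 0] * base[:, 5])

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(np.zeros((4, 6)), "3way")


class TestNestedCV:
    def test_noiseless_linear_signal_recovered(self):
        X, y, groups = synthetic_regression(noise=0.0, informative=(0, 3))
        res = fit_ridge_nested_cv(X, y, groups, EncodingConfig(seed=0))
        assert res["cv_r2"] >= 0.99

    def test_independent_target_scores_near_zero(self):
        rng = np.random.default_rng(1)
        X, _, groups = synthetic_regression(seed=1)
        y = rng.normal(size=len(X))
        res = fit_ridge_nested_cv(X, y, groups, EncodingConfig(seed=0))
        assert res["cv_r2"] <= 0.05

    def test_degenerate_target_flagged(self):
        X, _, groups = synthetic_regression()
        res = fit_ridge_nested_cv(X, np.zeros(len(X)), groups, EncodingConfig(seed=0))
        assert res["degenerate"] and np.isnan(res["cv_r2"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_ridge_nested_cv(np.zeros((20, 3)), np.zeros(20), np.arange(20))

    def test_seeded_folds_reproducible(self):
        X, y, groups = synthetic_regression(noise=0.5)
        a = fit_ridge_nested_cv(X, y, groups, EncodingConfig(seed=4))
        b = fit_ridge_nested_cv(X, y, groups, EncodingConfig(seed=4))
        assert a["cv_r2"] == b["cv_r2"]


class TestPermutationImportance:
    def test_single_informative_column_ranks_first(self):
        X, y, groups = synthetic_regression(noise=0.3, informative=(2,))
        Xd, names = build_design_matrix(X, "pos+vel")
        ranking = rank_predictors_permutation(Xd, y, groups, names, EncodingConfig(seed=0))
        assert ranking.name.iloc[0] == "Pz"
        assert ranking.importance.iloc[0] > 0.5

    def test_pure_noise_column_has_near_zero_importance(self):
        X, y, groups = synthetic_regression(noise=0.3, informative=(0,))
        Xd, names = build_design_matrix(X, "pos+vel")
        ranking = rank_predictors_permutation(Xd, y, groups, names, EncodingConfig(seed=0))
        noise_cols = ranking[ranking.name != "Px"]
        assert np.all(np.abs(noise_cols.importance) < 0.05)

    def test_ranking_deterministic_given_seed(self):
        X, y, groups = synthetic_regression(noise=0.5, informative=(0, 4))
        Xd, names = build_design_matrix(X, "2way")
        cfg = EncodingConfig(seed=11, n_perm_repeats=3)
        a = rank_predictors_permutation(Xd, y, groups, names, cfg)
        b = rank_predictors_permutation(Xd, y, groups, names, cfg)
        assert list(a.name) == list(b.name)


class TestReducedModel:
    def test_top_all_columns_has_zero_drop(self):
        X, y, groups = synthetic_regression(noise=0.2, informative=(0, 1))
        Xd, names = build_design_matrix(X, "pos+vel")
        cfg = EncodingConfig(seed=0)
        full = fit_ridge_nested_cv(Xd, y, groups, cfg)
        ranking = rank_predictors_permutation(Xd, y, groups, names, cfg)
        red = reduced_topk_model(Xd, y, groups, names, ranking, k=6, config=cfg)
        assert red["cv_r2"] == pytest.approx(full["cv_r2"], abs=1e-9)

    def test_k_exceeding_columns_rejected(self):
        X, y, groups = synthetic_regression()
        Xd, names = build_design_matrix(X, "pos")
        ranking = rank_predictors_permutation(Xd, y, groups, names, EncodingConfig(seed=0))
        with pytest.raises(ValueError):
            reduced_topk_model(Xd, y, groups, names, ranking, k=10)

    def test_single_predictor_model_does_not_beat_full(self):
        X, y, groups = synthetic_regression(noise=0.2, informative=(0, 1, 5))
        Xd, names = build_design_matrix(X, "pos+vel")
        cfg = EncodingConfig(seed=0)
        full = fit_ridge_nested_cv(Xd, y, groups, cfg)
        ranking = rank_predictors_permutation(Xd, y, groups, names, cfg)
        red = reduced_topk_model(Xd, y, groups, names, ranking, k=1, config=cfg)
        assert red["cv_r2"] <= full["cv_r2"] + 0.05


class TestFisherAveraging:
    def test_equal_values_unchanged(self):
        assert summarize_r2_fisher([0.5, 0.5])["mean_r"] == pytest.approx(0.5)

    def test_mean_of_zero_and_point_eight(self):
        # tanh((atanh(0) + atanh(0.8)) / 2) = tanh(ln(3)/2) = 0.5 exactly
        assert summarize_r2_fisher([0.0, 0.8])["mean_r"] == pytest.approx(0.5, abs=1e-9)

    def test_r_equal_one_is_clipped_not_infinite(self):
        out = summarize_r2_fisher([1.0, 0.0])
        assert np.isfinite(out["mean_r"]) and 0 < out["mean_r"] < 1


class TestSessionIntegration:
    def test_inclusion_filter_rejects_silent_neurons(self, small_session):
        saved = small_session.spikes
        small_session.spikes = {nid: np.array([]) for nid in saved}
        try:
            assert not inclusion_filter(small_session, 0)
        finally:
            small_session.spikes = saved

    def test_inclusion_boundary_exactly_five_trials_with_two_spikes(self, small_session):
        trials = small_session.analysable("irregular")
        spikes = []
        for _, row in trials.iloc[:5].iterrows():
            spikes.extend([row.t_protraction + 0.01, row.t_protraction + 0.02])
        saved = small_session.spikes
        small_session.spikes = dict(saved)
        small_session.spikes[0] = np.array(sorted(spikes))
        try:
            assert inclusion_filter(small_session, 0)
        finally:
            small_session.spikes = saved

    def test_trial_design_shapes_and_grouping(self, small_session):
        nid = int(small_session.neurons.id.iloc[0])
        X, y, groups = build_trial_data(small_session, nid)
        assert X.shape == (25 * 325, 6)
        assert len(y) == len(groups) == len(X)
        assert len(np.unique(groups)) == 25


def test_permutation_importance_recovers_generative_effect_sizes():
    # for near-linear neurons the importance ranking should track the
    # standardized generative effect size |w| * SD(feature); raw weights are
    # not comparable across features whose variances differ by orders of
    # magnitude
    from scipy.stats import spearmanr

    from viscotact.afferents import (
        FEATURE_NAMES,
        N_FEATURES,
        AfferentModel,
        kinematic_features,
    )
    from viscotact.session import SessionConfig, generate_dataset

    rng = np.random.default_rng(17)
    models = [
        AfferentModel("SA1", rng.normal(0, 0.5, N_FEATURES), bias=2.0, gain=30.0)
        for _ in range(6)
    ]
    session = generate_dataset(SessionConfig(seed=4, n_fa1=0, n_sa1=6, n_sa2=0), models=models)
    cfg = EncodingConfig(seed=3)
    feats = kinematic_features(session.contactor.times, session.contactor.pos)
    feature_sd = dict(zip(FEATURE_NAMES, feats.std(axis=0)))
    rhos = []
    for nid in range(len(models)):
        base, y, groups = build_trial_data(session, nid, cfg, y_from_rate=True)
        X, names = build_design_matrix(base, "2way")
        ranking = rank_predictors_permutation(X, y, groups, names, cfg)
        imp = ranking.set_index("name").importance
        effect = dict(zip(FEATURE_NAMES, np.abs(models[nid].weights)))
        rho = spearmanr(
            [effect[n] * feature_sd[n] for n in names], [imp[n] for n in names]
        ).statistic
        rhos.append(rho)
    assert float(np.median(rhos)) > 0.6
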