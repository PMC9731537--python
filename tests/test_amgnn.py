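"""Episodic training machinery of the auto-metric GNN."""

import numpy as np
import pandas as pd
import pytest

from adrelabel.amgnn import (
    AMGNNClassifier,
    AmgnnConfig,
    EpisodeError,
    build_graph,
    forward,
    init_params,
    run_experiment,
    sample_episode,
    split_train_test,
    train,
)
from adrelabel.tables import LabelSet

SMALL = AmgnnConfig(iterations=20, batch_size=32, support_per_class=2)


@pytest.fixture(scope="module")
def cohort(processed_table, default_dataset):
    return processed_table, default_dataset.labels


class TestSplit:
    def test_80_20_split_sizes(self, cohort):
        table, labels = cohort
        train_pool, test_pool = split_train_test(table, labels, 0.8, seed=0)
        assert abs(len(train_pool) - 447) <= 1
        assert len(train_pool) + len(test_pool) == 559
        assert len(train_pool.intersection(test_pool)) == 0

    def test_split_is_stratified(self, cohort):
        table, labels = cohort
        train_pool, test_pool = split_train_test(table, labels, 0.8, seed=0)
        frac_test = labels.labels.loc[test_pool].value_counts(normalize=True)
        frac_all = labels.labels.value_counts(normalize=True)
        assert (frac_test - frac_all).abs().max() < 0.02

    def test_same_seed_identical_partition(self, cohort):
        table, labels = cohort
        a = split_train_test(table, labels, 0.8, seed=9)
        b = split_train_test(table, labels, 0.8, seed=9)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_tiny_balanced_cohort_splits_evenly(self, cohort):
        table, _ = cohort
        ids = table.sample_ids[:4]
        labels = LabelSet(pd.Series(["CN", "CN", "AD", "AD"], index=ids))
        sub = table.copy()
        sub.df = sub.df.loc[ids]
        a, b = split_train_test(sub, labels, 0.5, seed=0)
        assert len(a) == len(b) == 2
        assert set(labels.labels.loc[a]) == {"CN", "AD"}

    def test_class_with_one_sample_rejected(self, cohort):
        table, _ = cohort
        ids = table.sample_ids[:3]
        labels = LabelSet(pd.Series(["CN", "CN", "AD"], index=ids))
        sub = table.copy()
        sub.df = sub.df.loc[ids]
        with pytest.raises(ValueError, match="strat"):
            split_train_test(sub, labels, 0.5, seed=0)


class TestEpisodes:
    def test_one_shot_episode_arithmetic(self, cohort):
        table, labels = cohort
        config = AmgnnConfig(support_per_class=1)
        rng = np.random.default_rng(0)
        pool = table.sample_ids
        ep = sample_episode(table, labels, config, pool=pool, rng=rng)
        assert ep.support_mask.sum() == 3
        assert ep.query_mask.sum() == 61
        assert not (ep.support_mask & ep.query_mask).any()

    def test_test_pool_never_leaks_into_supports(self, cohort):
        table, labels = cohort
        train_pool, test_pool = split_train_test(table, labels, 0.8, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            ep = sample_episode(table, labels, AmgnnConfig(), pool=test_pool,
                                rng=rng, mode="test", train_pool=train_pool)
            supports = ep.sample_ids[ep.support_mask]
            assert not test_pool.isin(supports).any()

    def test_every_training_sample_eventually_queried(self, cohort):
        table, labels = cohort
        train_pool, _ = split_train_test(table, labels, 0.8, seed=0)
        rng = np.random.default_rng(0)
        seen: set = set()
        config = AmgnnConfig()
        for _ in range(1000):
            ep = sample_episode(table, labels, config, pool=train_pool, rng=rng)
            seen.update(ep.sample_ids[ep.query_mask].tolist())
            if len(seen) == len(train_pool):
                break
        assert seen == set(train_pool)

    def test_pool_too_small_raises(self, cohort):
        table, labels = cohort
        pool = table.sample_ids[:5]
        with pytest.raises(EpisodeError):
            sample_episode(table, labels, AmgnnConfig(), pool=pool,
                           rng=np.random.default_rng(0))


class TestGraph:
    def _episode(self, cohort, n=20, seed=0):
        table, labels = cohort
        rng = np.random.default_rng(seed)
        return sample_episode(table, labels, SMALL, pool=table.sample_ids,
                              rng=rng), rng

    def test_rows_sum_to_one_and_weights_nonnegative(self, cohort):
        ep, rng = self._episode(cohort)
        params = init_params(SMALL, len(cohort[0].feature_names), rng)
        w = build_graph(ep, params).data
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)
        assert (w >= 0).all()

    def test_identical_graph_features_maximal_at_initialization(self, cohort):
        ep, rng = self._episode(cohort)
        ep.graph_features[1] = ep.graph_features[0]  # twin nodes
        params = init_params(SMALL, len(cohort[0].feature_names), rng)
        w = build_graph(ep, params).data
        assert w[0, 1] == pytest.approx(w[0].max())

    def test_permutation_equivariance(self, cohort):
        ep, rng = self._episode(cohort)
        params = init_params(SMALL, len(cohort[0].feature_names), rng)
        w = build_graph(ep, params).data
        perm = rng.permutation(len(ep.sample_ids))
        ep.graph_features = ep.graph_features[perm]
        w_perm = build_graph(ep, params).data
        assert np.allclose(w_perm, w[np.ix_(perm, perm)], atol=1e-12)

    def test_edges_ignore_non_graph_features(self, cohort):
        ep, rng = self._episode(cohort)
        params = init_params(SMALL, len(cohort[0].feature_names), rng)
        w = build_graph(ep, params).data
        ep.node_features = ep.node_features + 100.0  # perturb non-graph features
        assert np.array_equal(build_graph(ep, params).data, w)

    def test_non_finite_graph_features_rejected(self, cohort):
        ep, rng = self._episode(cohort)
        ep.graph_features[0, 0] = np.nan
        params = init_params(SMALL, len(cohort[0].feature_names), rng)
        with pytest.raises(ValueError):
            build_graph(ep, params)


class TestForward:
    def test_scores_form_a_probability_simplex(self, cohort):
        table, labels = cohort
        rng = np.random.default_rng(0)
        ep = sample_episode(table, labels, SMALL, pool=table.sample_ids, rng=rng)
        params = init_params(SMALL, len(table.feature_names), rng)
        probs, _ = forward(ep, params)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_forward_deterministic_given_parameters(self, cohort):
        table, labels = cohort
        rng = np.random.default_rng(0)
        ep = sample_episode(table, labels, SMALL, pool=table.sample_ids, rng=rng)
        params = init_params(SMALL, len(table.feature_names),
                             np.random.default_rng(3))
        a, _ = forward(ep, params)
        b, _ = forward(ep, params)
        assert np.array_equal(a, b)


class TestTraining:
    def test_zero_iterations_returns_untrained_model_and_empty_log(self, cohort):
        table, labels = cohort
        config = AmgnnConfig(iterations=0)
        params, log = train(table, labels, table.sample_ids, config, seed=0)
        assert len(log) == 0
        assert "w1" in params

    def test_log_length_equals_iterations(self, cohort):
        table, labels = cohort
        params, log = train(table, labels, table.sample_ids, SMALL, seed=0)
        assert list(log["iteration"]) == list(range(1, 21))
        assert np.isfinite(log["loss"]).all()

    def test_same_seed_identical_final_parameters(self, cohort):
        table, labels = cohort
        p1, _ = train(table, labels, table.sample_ids, SMALL, seed=5)
        p2, _ = train(table, labels, table.sample_ids, SMALL, seed=5)
        for k in p1:
            assert np.array_equal(p1[k].data, p2[k].data)

    def test_invalid_config_rejected(self, cohort):
        with pytest.raises(ValueError):
            AmgnnConfig(batch_size=10, support_per_class=5).validate()


class TestExperiment:
    def test_single_repeat_has_no_t_test(self, cohort):
        table, labels = cohort
        out = run_experiment(table, labels, labels,
                             AmgnnConfig(iterations=5), n_repeats=1)
        assert "p_value" not in out.comparison
        assert len(out.per_repeat) == 1

    def test_identical_label_sets_give_zero_difference(self, cohort):
        """With labels_relabelled == labels_original both arms share seeds,
        so the per-repeat AUC pairs are exactly equal."""
        table, labels = cohort
        out = run_experiment(table, labels, labels,
                             AmgnnConfig(iterations=10), n_repeats=2)
        assert out.comparison["mean_difference"] == pytest.approx(0.0, abs=1e-12)
        assert out.comparison["p_value"] == pytest.approx(1.0)

    def test_fitted_classifier_summary_reports_metrics(self, cohort):
        table, labels = cohort
        clf = AMGNNClassifier(table, labels, AmgnnConfig(iterations=30))
        results = clf.fit(seed=0)
        text = results.summary()
        assert "macro one-vs-all AUC" in text
        report = results.evaluate()
        assert 0.0 <= report.macro_auc <= 1.0
        assert 0.0 <= report.balanced_accuracy <= 1.0
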