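"""Re-labelling rule, agreement statistic, and post-hoc group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from adrelabel.relabel import (
    cohen_kappa,
    identify_ad_cluster,
    posthoc_group_summary,
    relabel_ad_cluster,
    relabel_groups,
    welch_t_test,
)
from adrelabel.tables import ClusterAssignment, LabelSet

# Reference per-cluster diagnosis composition (the study conditions the
# generator defaults reproduce):
# (CN, MCI, AD) for the AD, Catchall, Female, Male and Young-FH clusters.
CLUSTER_COMPOSITION = [(6, 18, 26), (114, 32, 20), (96, 28, 7), (82, 44, 5),
                       (65, 15, 1)]


def build_cohort_from_composition():
    """559 labels plus cluster assignment laid out from the composition."""
    labels, assignment = [], []
    for c, (cn, mci, ad) in enumerate(CLUSTER_COMPOSITION):
        labels += ["CN"] * cn + ["MCI"] * mci + ["AD"] * ad
        assignment += [c] * (cn + mci + ad)
    idx = pd.Index([f"S{i:03d}" for i in range(len(labels))])
    return (LabelSet(pd.Series(labels, index=idx)),
            ClusterAssignment(pd.Series(assignment, index=idx), k=5))


class TestIdentifyAdCluster:
    def test_highest_ad_proportion_wins(self):
        labels, clusters = build_cohort_from_composition()
        assert identify_ad_cluster(clusters, labels) == 0  # 52% AD

    def test_single_cluster_trivially_selected(self):
        idx = pd.Index(["a", "b", "c"])
        labels = LabelSet(pd.Series(["CN", "AD", "MCI"], index=idx))
        clusters = ClusterAssignment(pd.Series([0, 0, 0], index=idx), k=1)
        assert identify_ad_cluster(clusters, labels) == 0

    def test_tie_resolves_to_lowest_index(self):
        idx = pd.Index(list("abcd"))
        labels = LabelSet(pd.Series(["AD", "CN", "AD", "CN"], index=idx))
        clusters = ClusterAssignment(pd.Series([0, 0, 1, 1], index=idx), k=2)
        assert identify_ad_cluster(clusters, labels) == 0

    def test_no_ad_cases_is_an_error(self):
        idx = pd.Index(["a", "b"])
        labels = LabelSet(pd.Series(["CN", "MCI"], index=idx))
        clusters = ClusterAssignment(pd.Series([0, 1], index=idx), k=2)
        with pytest.raises(ValueError, match="no AD"):
            identify_ad_cluster(clusters, labels)


class TestRelabel:
    def test_reference_composition_raises_ad_count_59_to_83(self):
        labels, clusters = build_cohort_from_composition()
        out = relabel_ad_cluster(labels, clusters, 0)
        assert int(out.relabel_mask.sum()) == 24
        assert out.counts()["AD"] == 83
        assert labels.counts()["AD"] == 59  # input untouched

    def test_pure_ad_cluster_changes_nothing_but_provenance(self):
        idx = pd.Index(["a", "b", "c"])
        labels = LabelSet(pd.Series(["AD", "AD", "CN"], index=idx))
        clusters = ClusterAssignment(pd.Series([0, 0, 1], index=idx), k=2)
        out = relabel_ad_cluster(labels, clusters, 0)
        assert out.provenance == "relabelled"
        assert not out.relabel_mask.any()
        assert (out.labels == labels.labels).all()

    def test_never_touches_ad_labels_anywhere(self):
        labels, clusters = build_cohort_from_composition()
        out = relabel_ad_cluster(labels, clusters, 0)
        was_ad = labels.labels == "AD"
        assert (out.labels[was_ad] == "AD").all()
        assert not out.relabel_mask[was_ad].any()
        # and only ever CN/MCI -> AD
        assert (out.labels[out.relabel_mask] == "AD").all()

    def test_out_of_range_cluster_index(self):
        labels, clusters = build_cohort_from_composition()
        with pytest.raises(IndexError):
            relabel_ad_cluster(labels, clusters, 9)


class TestCohenKappa:
    def test_identical_labelings_agree_perfectly(self):
        labels, _ = build_cohort_from_composition()
        assert cohen_kappa(labels, labels) == pytest.approx(1.0)

    def test_reference_relabelling_reproduces_0917(self):
        labels, clusters = build_cohort_from_composition()
        out = relabel_ad_cluster(labels, clusters, 0)
        assert cohen_kappa(labels, out) == pytest.approx(0.917, abs=5e-4)

    def test_perfect_disagreement_with_symmetric_marginals(self):
        a = pd.Series(["AD", "AD", "CN", "CN"])
        b = pd.Series(["CN", "CN", "AD", "AD"])
        assert cohen_kappa(a, b) == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self, rng):
        a = pd.Series(rng.choice(["CN", "MCI", "AD"], size=50))
        b = pd.Series(rng.choice(["CN", "MCI", "AD"], size=50))
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a))

    def test_matches_independent_reference_implementation(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(10):
            a = pd.Series(rng.choice(["CN", "MCI", "AD"], size=80))
            b = pd.Series(rng.choice(["CN", "MCI", "AD"], size=80))
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_constant_equal_labelings_return_one_by_convention(self):
        a = pd.Series(["AD", "AD", "AD"])
        assert cohen_kappa(a, a.copy()) == 1.0


class TestGroupSummary:
    def test_constant_group(self):
        df = pd.DataFrame({"f": [5.0, 5.0, 5.0]}, index=list("abc"))
        out = posthoc_group_summary(df, {"g": pd.Index(list("abc"))}, ["f"])
        row = out.iloc[0]
        assert row["mean"] == 5.0 and row["sd"] == 0.0 and row["n"] == 3

    def test_two_point_group(self):
        df = pd.DataFrame({"f": [1.0, 3.0]}, index=list("ab"))
        row = posthoc_group_summary(df, {"g": pd.Index(list("ab"))}, ["f"]).iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(np.sqrt(2.0))

    def test_singleton_group_sd_unavailable(self):
        df = pd.DataFrame({"f": [1.0, 2.0]}, index=list("ab"))
        row = posthoc_group_summary(df, {"g": pd.Index(["a"])}, ["f"]).iloc[0]
        assert row["n"] == 1 and np.isnan(row["sd"])

    def test_unknown_feature_rejected(self):
        df = pd.DataFrame({"f": [1.0]}, index=["a"])
        with pytest.raises(KeyError):
            posthoc_group_summary(df, {"g": pd.Index(["a"])}, ["nope"])

    def test_relabelled_group_tau_intermediate_on_synthetic_cohort(
            self, default_dataset, fitted):
        """The re-labelled cases' tau uptake sits between the non-AD cases
        and the AD cases that remained in the AD cluster."""
        groups = relabel_groups(default_dataset.labels,
                                fitted.labels_relabelled,
                                fitted.clusters, fitted.ad_cluster)
        remained_in_cluster = groups["remained_ad"].intersection(
            fitted.clusters.members(fitted.ad_cluster))
        groups = {**groups, "remained_ad_in_cluster": remained_in_cluster}
        out = posthoc_group_summary(default_dataset.table,
                                    groups, ["ctx.lh.inferiorparietal"])
        means = out.set_index("group")["mean"]
        assert (means["non_ad"] < means["cn_mci_to_ad"]
                < means["remained_ad_in_cluster"])

    def test_groups_partition_the_cohort(self, default_dataset, fitted):
        groups = relabel_groups(default_dataset.labels,
                                fitted.labels_relabelled,
                                fitted.clusters, fitted.ad_cluster)
        core = [groups["non_ad"], groups["cn_mci_to_ad"], groups["remained_ad"]]
        assert sum(len(g) for g in core) == 559
        assert len(core[0].intersection(core[1])) == 0
        assert groups["ad_outside_ad_cluster"].isin(groups["remained_ad"]).all()


class TestWelch:
    def test_identical_samples_give_t_zero_p_one(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_large_shift_detected(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert p < 0.01
        # closed form: diff 100, se = sqrt(1/3 + 1/3) with sample var 1
        assert t == pytest.approx(-100.0 / np.sqrt(2.0 / 3.0))

    def test_degenerate_equal_constants(self):
        t, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_type_one_error_calibrated_under_the_null(self):
        rng = np.random.default_rng(12345)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.normal(size=12)
            y = rng.normal(size=15)
            _, p = welch_t_test(x, y)
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestEndToEndRecovery:
    def test_relabelling_recovers_latent_labels_exactly(
            self, default_dataset, fitted):
        """When clustering isolates the latent AD cluster, promoting its
        CN/MCI members reproduces the latent ground truth exactly."""
        ds = default_dataset
        discovered = set(fitted.clusters.members(fitted.ad_cluster))
        latent = set(ds.latent_clusters.members(0))
        # clustering recovered the latent AD cluster's CN/MCI structure ...
        assert discovered >= latent
        # ... and therefore the re-labelling recovers the latent labels
        assert (fitted.labels_relabelled.labels == ds.latent_labels.labels).all()

    @given(st.integers(0, 4))
    def test_relabelling_only_increases_ad_count(self, cluster):
        labels, clusters = build_cohort_from_composition()
        out = relabel_ad_cluster(labels, clusters, cluster)
        assert out.counts()["AD"] >= labels.counts()["AD"]
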