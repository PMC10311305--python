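import numpy as np
import pytest

from cellbrf import (
    ClusterLabeling,
    balance,
    center_undersample,
    plan_balance,
    smote_oversample,
)
from cellbrf.metrics import ClassDistribution, balance_entropy

from conftest import make_matrix


def labeling_with_sizes(sizes):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return ClusterLabeling(labels=labels, n=len(sizes))


class TestPlanBalance:
    def test_roles_and_rates(self):
        plan = plan_balance(labeling_with_sizes([10, 30, 60]))
        assert plan.central_cluster == 1  # |30 - 33.3| smallest
        assert plan.role_of == {0: "rare", 1: "central", 2: "major"}
        assert plan.sampling_rate[0] == pytest.approx(3.0)

    def test_tie_breaks_toward_smaller_cluster(self):
        plan = plan_balance(labeling_with_sizes([20, 40]))  # h=30, tie
        assert plan.central_cluster == 0

    def test_single_cluster_degenerate(self):
        plan = plan_balance(labeling_with_sizes([17]))
        assert plan.central_cluster == 0
        assert plan.rare_clusters == [] and plan.major_clusters == []


class TestSmoteOversample:
    def test_synthetics_stay_in_parent_box(self, rng):
        data = rng.normal(5, 2, size=(8, 12))
        syn = smote_oversample(data, n_synthetic=1000, smote_k=5, seed=0)
        assert syn.shape == (8, 1000)
        lo, hi = data.min(axis=1), data.max(axis=1)
        assert (syn >= lo[:, None] - 1e-12).all()
        assert (syn <= hi[:, None] + 1e-12).all()

    def test_interpolation_endpoints_one_dimensional(self):
        # two 1-D cells at 2 and 5: synthetics lie on the segment [2, 5]
        data = np.array([[2.0, 5.0]])
        syn = smote_oversample(data, n_synthetic=200, smote_k=5, seed=1)
        assert (syn >= 2.0).all() and (syn <= 5.0).all()

    def test_exact_count_generated(self, rng):
        data = rng.normal(size=(4, 7))
        syn = smote_oversample(data, n_synthetic=13, smote_k=3, seed=2)
        assert syn.shape[1] == 13

    def test_singleton_cluster_duplicates_with_warning(self):
        data = np.array([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single cell"):
            syn = smote_oversample(data, n_synthetic=3, smote_k=5, seed=0)
        np.testing.assert_array_equal(syn, np.repeat(data, 3, axis=1))

    def test_deterministic(self, rng):
        data = rng.normal(size=(5, 9))
        a = smote_oversample(data, 20, smote_k=4, seed=9)
        b = smote_oversample(data, 20, smote_k=4, seed=9)
        np.testing.assert_array_equal(a, b)


class TestCenterUndersample:
    @pytest.mark.parametrize("t,expected", [(10, 8), (7, 5)])
    def test_floor_retention(self, rng, t, expected):
        data = rng.normal(size=(6, t))
        assert center_undersample(data, U=0.8, seed=0).size == expected

    def test_matches_centroid_distance_sort(self, rng):
        data = rng.normal(size=(5, 20))
        retained = center_undersample(data, U=0.8, seed=0)
        centroid = data.mean(axis=1)
        dists = [
            (float(np.sqrt(((data[:, j] - centroid) ** 2).sum())), j)
            for j in range(20)
        ]
        dists.sort()
        expected = [j for _, j in dists[:16]]
        assert list(retained) == expected

    def test_minimum_one_retained(self, rng):
        data = rng.normal(size=(3, 2))
        assert center_undersample(data, U=0.1, seed=0).size == 1


class TestBalance:
    def test_balanced_input_is_fixed_point(self, rng):
        m = make_matrix(np.abs(rng.normal(3, 1, (6, 90))), layer="lognorm")
        lab = labeling_with_sizes([30, 30, 30])
        plan = plan_balance(lab)
        out = balance(m, lab, plan, seed=0)
        np.testing.assert_array_equal(out.values, m.values)
        assert (out.provenance == "original").all()

    def test_target_sizes_10_30_60(self, rng):
        m = make_matrix(np.abs(rng.normal(3, 1, (6, 100))), layer="lognorm")
        lab = labeling_with_sizes([10, 30, 60])
        out = balance(m, lab, plan_balance(lab, U=0.8), seed=0)
        assert list(out.sizes) == [30, 30, 48]

    def test_synthetic_labels_are_rare_ids_and_central_kept(self, rng):
        m = make_matrix(np.abs(rng.normal(3, 1, (6, 100))), layer="lognorm")
        lab = labeling_with_sizes([10, 30, 60])
        plan = plan_balance(lab)
        out = balance(m, lab, plan, seed=0)
        syn_labels = out.labels[out.provenance == "synthetic"]
        assert set(syn_labels) <= set(plan.rare_clusters)
        n_central_kept = (
            (out.labels == plan.central_cluster)
            & (out.provenance == "original")
        ).sum()
        assert n_central_kept == 30

    def test_bit_reproducible(self, rng):
        m = make_matrix(np.abs(rng.normal(3, 1, (6, 100))), layer="lognorm")
        lab = labeling_with_sizes([10, 30, 60])
        plan = plan_balance(lab)
        a = balance(m, lab, plan, seed=5)
        b = balance(m, lab, plan, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_reduces_balance_entropy_on_random_configs(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(2, 5))
            sizes = rng.integers(5, 60, size=n)
            m = make_matrix(
                np.abs(rng.normal(3, 1, (5, int(sizes.sum())))), layer="lognorm"
            )
            lab = labeling_with_sizes(sizes)
            out = balance(m, lab, plan_balance(lab), seed=int(rng.integers(100)))
            be_in = balance_entropy(ClassDistribution(sizes))
            out_sizes = np.bincount(out.labels, minlength=n)
            be_out = balance_entropy(ClassDistribution(out_sizes))
            assert be_out <= be_in + 1e-12

    def test_mode_none_is_identity(self, rng):
        m = make_matrix(np.abs(rng.normal(3, 1, (6, 100))), layer="lognorm")
        lab = labeling_with_sizes([10, 30, 60])
        out = balance(m, lab, plan_balance(lab), seed=0, mode="none")
        np.testing.assert_array_equal(out.values, m.values)

    def test_mode_over_only_keeps_majors_whole(self, rng):
        m = make_matrix(np.abs(rng.normal(3, 1, (6, 100))), layer="lognorm")
        lab = labeling_with_sizes([10, 30, 60])
        out = balance(m, lab, plan_balance(lab), seed=0, mode="over_only")
        assert list(out.sizes) == [30, 30, 60]

    def test_post_balance_size_bounds(self, rng):
        m = make_matrix(np.abs(rng.normal(3, 1, (8, 150))), layer="lognorm")
        lab = labeling_with_sizes([15, 45, 90])
        plan = plan_balance(lab, U=0.8)
        out = balance(m, lab, plan, seed=1)
        t_central = 45
        sizes = out.sizes
        assert (sizes >= np.floor(0.8 * t_central)).all()
        for cl in plan.rare_clusters:
            assert sizes[cl] <= t_central
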