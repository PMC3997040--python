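"""Permutation p-values, clusters, the cluster-size null and FDR."""

import numpy as np
import pytest
from scipy import stats as sps

from fwmap.data import StatMap
from fwmap.simulate import SimulationParams, generate_dataset
from fwmap.stats import (ClusterSizeNull, CorrectionParams, NullEnsemble,
                         binarize, build_null_ensemble, cluster_null_edf,
                         extract_clusters, fdr_select, permute_labels,
                         run_corrected_pipeline, voxel_pvalues)


class TestPermuteLabels:
    def test_balance_preserved_in_every_permutation(self):
        labels = np.array([1] * 15 + [-1] * 15)
        perms = permute_labels(labels, 50, seed=1)
        assert ((perms == 1).sum(axis=1) == 15).all()

    def test_same_seed_reproducible(self):
        labels = np.array([1] * 5 + [-1] * 5)
        np.testing.assert_array_equal(permute_labels(labels, 20, seed=9),
                                      permute_labels(labels, 20, seed=9))

    def test_identity_and_duplicates_excluded(self):
        labels = np.array([1, 1, -1, -1])
        perms = permute_labels(labels, 5, seed=0)  # all 5 non-identity
        keys = {p.tobytes() for p in perms}
        assert len(keys) == 5
        assert labels.tobytes() not in keys

    def test_requesting_too_many_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            permute_labels(np.array([1, 1, -1, -1]), 6, seed=0)


def _ensemble(null_values, observed, kind="weight"):
    nvox = observed.size
    mask = np.ones((nvox, 1, 1), dtype=bool)
    return NullEnsemble(observed=observed, null=null_values, mask=mask,
                        kind=kind)


class TestVoxelPvalues:
    def test_observed_above_all_null(self):
        ens = _ensemble(np.arange(99, dtype=float)[:, None],
                        np.array([1000.0]))
        p_up, p_lo = ens.observed_pvalues()
        assert p_up[0] == pytest.approx(1 / 100)
        assert p_lo[0] == pytest.approx(1.0)

    def test_observed_below_all_null(self):
        ens = _ensemble(np.arange(99, dtype=float)[:, None],
                        np.array([-5.0]))
        p_up, _ = ens.observed_pvalues()
        assert p_up[0] == pytest.approx(1.0)

    def test_observed_at_median(self):
        ens = _ensemble(np.arange(99, dtype=float)[:, None], np.array([49.0]))
        p_up, _ = ens.observed_pvalues()
        assert p_up[0] == pytest.approx(0.51)  # ties count as exceeding

    def test_kind_mismatch_rejected(self):
        ens = _ensemble(np.zeros((10, 1)), np.zeros(1), kind="weight")
        obs = StatMap(values=np.full((1, 1, 1), 0.7), kind="accuracy")
        with pytest.raises(ValueError, match="kind"):
            voxel_pvalues(obs, ens, "one")

    def test_pvalues_never_zero(self, rng):
        ens = _ensemble(rng.normal(size=(200, 6)), rng.normal(size=6))
        p_up, p_lo = ens.observed_pvalues()
        assert (p_up > 0).all() and (p_lo > 0).all()


class TestBinarize:
    def test_all_p_one_is_empty(self):
        out = binarize(np.ones((3, 3, 3)), None, 0.05, "one")
        assert (out == 0).all()

    def test_alpha_one_marks_everything_one_sided(self):
        out = binarize(np.full((2, 2, 2), 0.9), None, 1.0, "one")
        assert (out == 1).all()

    def test_two_sided_threshold_is_alpha_over_two(self):
        p = np.full((1, 1, 1), 0.03)
        sign = np.ones((1, 1, 1), dtype=np.int8)
        assert binarize(p, sign, 0.05, "two")[0, 0, 0] == 0
        assert binarize(p, sign, 0.10, "two")[0, 0, 0] == 1

    def test_two_sided_keeps_sign(self):
        p = np.array([[[0.01, 0.01, 0.8]]])
        sign = np.array([[[1, -1, 1]]], dtype=np.int8)
        out = binarize(p, sign, 0.05, "two")
        np.testing.assert_array_equal(out.ravel(), [1, -1, 0])


def flood_fill_clusters(binary):
    """Brute-force 6-connectivity labelling by breadth-first search."""
    seen = np.zeros(binary.shape, dtype=bool)
    comps = []
    for start in np.argwhere(binary != 0):
        start = tuple(start)
        if seen[start]:
            continue
        val = binary[start]
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            v = queue.pop()
            comp.append(v)
            for ax in range(3):
                for d in (-1, 1):
                    nb = list(v)
                    nb[ax] += d
                    nb = tuple(nb)
                    if (0 <= nb[ax] < binary.shape[ax] and not seen[nb]
                            and binary[nb] == val):
                        seen[nb] = True
                        queue.append(nb)
        comps.append((int(val), len(comp)))
    return sorted(comps)


class TestExtractClusters:
    def test_single_voxel_cluster(self):
        m = np.zeros((4, 4, 4), dtype=np.int8)
        m[2, 2, 2] = 1
        table = extract_clusters(m)
        assert len(table) == 1 and table.clusters[0].size == 1

    def test_diagonal_voxels_do_not_join(self):
        m = np.zeros((4, 4, 4), dtype=np.int8)
        m[0, 0, 0] = 1
        m[1, 1, 0] = 1
        assert len(extract_clusters(m)) == 2

    def test_cube_is_one_cluster_of_eight(self):
        m = np.zeros((4, 4, 4), dtype=np.int8)
        m[1:3, 1:3, 1:3] = 1
        table = extract_clusters(m)
        assert len(table) == 1 and table.clusters[0].size == 8

    def test_opposite_signs_cluster_separately(self):
        m = np.zeros((4, 4, 4), dtype=np.int8)
        m[1, 1, 1] = 1
        m[1, 1, 2] = -1  # face-adjacent but opposite sign
        table = extract_clusters(m)
        assert len(table) == 2
        assert sorted(c.sign for c in table) == [-1, 1]

    def test_matches_flood_fill_on_random_maps(self, rng):
        for _ in range(25):
            m = np.zeros((10, 10, 10), dtype=np.int8)
            m.ravel()[rng.random(1000) < 0.25] = 1
            m.ravel()[rng.random(1000) < 0.10] = -1
            mine = sorted((c.sign, c.size) for c in extract_clusters(m))
            assert mine == flood_fill_clusters(m)


class TestClusterNull:
    def test_example_edf_counting(self):
        null = ClusterSizeNull(sizes=np.array([1, 1, 2]))
        assert null.pvalue(2)[0] == pytest.approx((1 + 1) / (3 + 1))

    def test_query_beyond_largest(self):
        null = ClusterSizeNull(sizes=np.array([1, 2, 3, 4]))
        assert null.pvalue(99)[0] == pytest.approx(1 / 5)

    def test_survival_function_non_increasing(self, rng):
        null = ClusterSizeNull(sizes=np.sort(rng.integers(1, 50, size=100)))
        p = null.pvalue(np.arange(1, 60))
        assert (np.diff(p) <= 0).all()

    def test_pooling_from_maps(self):
        a = np.zeros((3, 3, 3), dtype=np.int8)
        a[0, 0, 0] = 1
        b = np.zeros((3, 3, 3), dtype=np.int8)
        b[0, 0, :2] = -1
        null = cluster_null_edf([a, b])
        np.testing.assert_array_equal(null.sizes, [1, 2])


class TestFDRSelect:
    def test_hand_run_example(self):
        sig = fdr_select(np.array([0.001, 0.02, 0.5]), q=0.05)
        np.testing.assert_array_equal(sig, [True, True, False])

    def test_empty_and_all_ones(self):
        assert fdr_select(np.array([]), 0.05).size == 0
        assert not fdr_select(np.ones(5), 0.05).any()

    def test_matches_step_up_definition_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            q = 0.1
            # direct step-up: largest k with p_(k) <= k q / m
            order = np.argsort(p)
            m = p.size
            thresh = (np.arange(1, m + 1) * q) / m
            below = np.nonzero(p[order] <= thresh)[0]
            expected = np.zeros(m, dtype=bool)
            if below.size:
                expected[order[:below.max() + 1]] = True
            np.testing.assert_array_equal(fdr_select(p, q), expected)


class TestPipeline:
    def test_null_pvalues_uniform_under_exchangeability(self):
        # offset 0: the observed labelling is exchangeable with the
        # permutations, so voxel p-values are (discretely) uniform
        stack, _ = generate_dataset(
            SimulationParams(shape=(16, 8, 8), thicknesses=(1,), gaps=(2,),
                             offset=0.0, seed=21))
        ens = build_null_ensemble(stack, "fwm", None, n_perm=500, seed=22)
        p_up, _ = ens.observed_pvalues()
        assert sps.kstest(p_up, "uniform").pvalue > 0.001

    def test_full_pipeline_deterministic(self, small_sim):
        stack, _ = small_sim
        corr = CorrectionParams(alpha_vox=0.05, sidedness="two", n_perm=60,
                                seed=5)
        out1 = run_corrected_pipeline(stack, "fwm", None, corr)
        out2 = run_corrected_pipeline(stack, "fwm", None, corr)
        np.testing.assert_array_equal(out1[0].values, out2[0].values)
        np.testing.assert_array_equal(out1[2], out2[2])
        assert out1[1].to_dataframe().equals(out2[1].to_dataframe())

    def test_uncorrected_mode_stops_at_binarization(self, small_sim):
        stack, _ = small_sim
        corr = CorrectionParams(alpha_vox=0.05, sidedness="two", n_perm=60,
                                seed=5)
        _, table, sig = run_corrected_pipeline(stack, "fwm", None, corr,
                                               corrected=False)
        # every suprathreshold voxel is significant; table has no p-values
        assert (sig != 0).sum() == sum(c.size for c in table)
        assert np.isnan(table.pvalues).all()

    def test_corrected_detections_subset_of_uncorrected(self, small_sim):
        stack, _ = small_sim
        ens = build_null_ensemble(stack, "fwm", None, n_perm=80, seed=9)
        unc = ens.uncorrected(0.05, "two")
        _, sig, _ = ens.corrected(0.05, "two", 0.05)
        assert ((sig != 0) & (unc == 0)).sum() == 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CorrectionParams(alpha_vox=0.0)
        with pytest.raises(ValueError):
            CorrectionParams(q=1.5)
        with pytest.raises(ValueError):
            CorrectionParams(sidedness="three")
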