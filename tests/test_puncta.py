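"""Neuropil masking, blob detection, juxtaposition pairing and group stats."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import _oracles as oracles
from synaptomics import (
    ImageStack,
    PunctaSet,
    compare_groups,
    detect_spots,
    estimate_neuropil,
    generate_image_stack,
    pair_synapses,
    simulate_image_truth,
)
from synaptomics.puncta import (
    POST_DIAMETER_UM,
    PRE_DIAMETER_UM,
    DegenerateInputError,
    SynapseDensityRecord,
)
from synaptomics.synthetic.imaging import ImageGroundTruth

VOXEL = (0.2, 0.1, 0.1)


def puncta_at(points, diameter=PRE_DIAMETER_UM):
    return PunctaSet(centroids=np.asarray(points, float), diameter=diameter)


class TestNeuropil:
    def test_no_occluders_full_volume(self):
        truth = simulate_image_truth(n_pairs=3, n_unpaired_pre=0, n_unpaired_post=0,
                                     stack_shape=(10, 60, 60), seed=0)
        stack, _ = generate_image_stack(truth, snr=30, seed=1)
        exclusion, neuropil, vol = estimate_neuropil(stack)
        assert not exclusion.any()
        assert vol == pytest.approx(np.prod(np.array(truth.stack_shape) * np.array(VOXEL)))

    def test_sphere_exclusion_volume_matches_geometry(self):
        r = 1.5
        truth = ImageGroundTruth(
            pre_centroids=np.array([[1.0, 1.0, 1.0]]),
            post_centroids=np.array([[1.0, 1.2, 1.0]]),
            paired_indices=[(0, 0)],
            nucleus_blobs=[((3.0, 8.0, 8.0), r)],
            voxel_size=VOXEL, stack_shape=(30, 160, 160))
        stack, _ = generate_image_stack(truth, snr=40, seed=4)
        _, _, vol = estimate_neuropil(stack)
        full = np.prod(np.array(truth.stack_shape) * np.array(VOXEL))
        excluded = full - vol
        analytic = 4 / 3 * np.pi * r ** 3
        assert excluded == pytest.approx(analytic, rel=0.10)

    def test_growing_occluder_shrinks_neuropil(self):
        vols = []
        for r in (0.8, 1.2, 1.6):
            truth = ImageGroundTruth(
                pre_centroids=np.array([[1.0, 1.0, 1.0]]),
                post_centroids=np.array([[1.0, 1.2, 1.0]]),
                paired_indices=[(0, 0)],
                nucleus_blobs=[((3.0, 8.0, 8.0), r)],
                voxel_size=VOXEL, stack_shape=(30, 160, 160))
            stack, _ = generate_image_stack(truth, snr=40, seed=4)
            vols.append(estimate_neuropil(stack)[2])
        assert vols[0] > vols[1] > vols[2]

    def test_all_zero_post_channel_rejected(self):
        stack = ImageStack(channels={"pre": np.ones((5, 10, 10)),
                                     "post": np.zeros((5, 10, 10))},
                           voxel_size=VOXEL)
        with pytest.raises(DegenerateInputError):
            estimate_neuropil(stack)


class TestDetectSpots:
    def test_blank_channel_returns_empty(self):
        out = detect_spots(np.zeros((8, 40, 40)), PRE_DIAMETER_UM, VOXEL)
        assert len(out) == 0

    def test_noise_only_stack_returns_empty(self):
        truth = ImageGroundTruth(pre_centroids=np.empty((0, 3)),
                                 post_centroids=np.array([[1.0, 2.0, 2.0]]),
                                 paired_indices=[], voxel_size=VOXEL,
                                 stack_shape=(10, 60, 60))
        stack, _ = generate_image_stack(truth, snr=30, seed=2)
        out = detect_spots(stack.channels["pre"], PRE_DIAMETER_UM, VOXEL)
        assert len(out) == 0

    def test_planted_blobs_recovered_with_subvoxel_accuracy(self):
        """50 planted puncta at high SNR: >= 48 within 0.15 µm, no false
        positives."""
        truth = simulate_image_truth(n_pairs=50, n_unpaired_pre=0, n_unpaired_post=0,
                                     stack_shape=(16, 160, 160), seed=1)
        stack, _ = generate_image_stack(truth, snr=50, seed=2)
        for channel, diameter, centroids in (
                ("pre", PRE_DIAMETER_UM, truth.pre_centroids),
                ("post", POST_DIAMETER_UM, truth.post_centroids)):
            spots = detect_spots(stack.channels[channel], diameter, VOXEL)
            d, _ = cKDTree(centroids).query(spots.centroids)
            assert int((d <= 0.15).sum()) >= 48
            assert len(spots) <= len(centroids)  # no false positives

    def test_spot_inside_exclusion_mask_discarded(self):
        truth = simulate_image_truth(n_pairs=5, n_unpaired_pre=0, n_unpaired_post=0,
                                     stack_shape=(12, 80, 80), seed=3)
        stack, _ = generate_image_stack(truth, snr=40, seed=4)
        # mask out the voxel region around the first planted presynaptic spot
        mask = np.ones(truth.stack_shape, dtype=bool)
        c_vox = np.round(truth.pre_centroids[0] / np.array(VOXEL)).astype(int)
        lo = np.maximum(c_vox - 6, 0)
        hi = np.minimum(c_vox + 7, truth.stack_shape)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = False
        spots = detect_spots(stack.channels["pre"], PRE_DIAMETER_UM, VOXEL,
                             neuropil_mask=mask)
        d, _ = cKDTree(spots.centroids).query(truth.pre_centroids[0].reshape(1, 3))
        assert d[0] > 0.3  # the masked punctum is absent

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.ones((5, 10, 10)), 0.0, VOXEL)


class TestPairSynapses:
    def test_single_pair_inside_distance(self):
        pre = puncta_at([[2.0, 2.0, 2.0]])
        post = puncta_at([[2.0, 2.0, 2.4]], diameter=POST_DIAMETER_UM)
        pairs, rec = pair_synapses(pre, post, max_dist=0.5, neuropil_volume=100.0)
        assert rec.n_synapses == 1
        assert pairs[0][2] == pytest.approx(0.4)

    def test_single_pair_outside_distance(self):
        pre = puncta_at([[2.0, 2.0, 2.0]])
        post = puncta_at([[2.0, 2.0, 2.6]], diameter=POST_DIAMETER_UM)
        _, rec = pair_synapses(pre, post, max_dist=0.5, neuropil_volume=100.0)
        assert rec.n_synapses == 0

    def test_one_to_one_matching_cap(self):
        pre = puncta_at([[2.0, 2.0, 2.0], [2.0, 2.0, 2.2], [2.0, 2.2, 2.0]])
        post = puncta_at([[2.0, 2.1, 2.1]], diameter=POST_DIAMETER_UM)
        _, rec = pair_synapses(pre, post, max_dist=0.5, neuropil_volume=10.0)
        assert rec.n_synapses == 1

    def test_symmetric_in_roles(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 5, size=(30, 3))
        b = rng.uniform(0, 5, size=(25, 3))
        _, r1 = pair_synapses(puncta_at(a), puncta_at(b, POST_DIAMETER_UM),
                              neuropil_volume=10.0)
        _, r2 = pair_synapses(puncta_at(b), puncta_at(a, POST_DIAMETER_UM),
                              neuropil_volume=10.0)
        assert r1.n_synapses == r2.n_synapses

    def test_matches_greedy_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 4, size=(40, 3))
        b = rng.uniform(0, 4, size=(35, 3))
        pairs, rec = pair_synapses(puncta_at(a), puncta_at(b, POST_DIAMETER_UM),
                                   max_dist=0.5, neuropil_volume=10.0)
        expected = oracles.greedy_pairs([tuple(p) for p in a], [tuple(p) for p in b], 0.5)
        assert rec.n_synapses == len(expected)
        assert sorted((i, j) for i, j, _ in pairs) == sorted((i, j) for i, j, _ in expected)

    def test_shrinking_max_dist_never_adds_pairs(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 4, size=(30, 3))
        b = rng.uniform(0, 4, size=(30, 3))
        counts = []
        for d in (0.8, 0.5, 0.3, 0.1):
            _, rec = pair_synapses(puncta_at(a), puncta_at(b, POST_DIAMETER_UM),
                                   max_dist=d, neuropil_volume=10.0)
            counts.append(rec.n_synapses)
        assert counts == sorted(counts, reverse=True)

    def test_count_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            SynapseDensityRecord(n_pre=1, n_post=1, n_synapses=2,
                                 neuropil_volume=1.0, density=2.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pair_synapses(puncta_at([[1, 1, 1]]),
                          puncta_at([[1, 1, 1.1]], POST_DIAMETER_UM),
                          neuropil_volume=0.0)


class TestDensityRecovery:
    def test_end_to_end_density_within_ten_percent(self):
        """200 planted pairs, high SNR, no occluders: recovered synapse
        density within 10% of truth."""
        truth = simulate_image_truth(n_pairs=200, n_unpaired_pre=20,
                                     n_unpaired_post=20,
                                     stack_shape=(20, 256, 256), seed=5)
        stack, _ = generate_image_stack(truth, snr=40, seed=6)
        _, neuropil, vol = estimate_neuropil(stack)
        pre = detect_spots(stack.channels["pre"], PRE_DIAMETER_UM, VOXEL,
                           neuropil_mask=neuropil)
        post = detect_spots(stack.channels["post"], POST_DIAMETER_UM, VOXEL,
                            neuropil_mask=neuropil)
        _, rec = pair_synapses(pre, post, max_dist=0.5, neuropil_volume=vol)
        truth_density = len(truth.paired_indices) / vol
        assert rec.density == pytest.approx(truth_density, rel=0.10)


class TestCompareGroups:
    @staticmethod
    def records(pme, pse):
        return pd.DataFrame({"group": ["PME"] * len(pme) + ["PSE"] * len(pse),
                             "density": list(pme) + list(pse)})

    def test_identical_groups_give_t_zero(self):
        res = compare_groups(self.records([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
                             metric="density")
        assert res.t == pytest.approx(0.0)

    def test_matches_formula_oracle(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        res = compare_groups(self.records(a, b), metric="density", welch="never")
        t, df, p = oracles.student_t(a, b)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        res_w = compare_groups(self.records(a, b), metric="density", welch="always")
        t_w, df_w, p_w = oracles.welch_t(a, b)
        assert res_w.t == pytest.approx(t_w, abs=1e-12)
        assert res_w.df == pytest.approx(df_w, abs=1e-9)
        assert res_w.p_value == pytest.approx(p_w, abs=1e-12)

    def test_power_for_two_sd_shift(self):
        """PME > PSE by 2 pooled SDs at n = 8/8 has >= 95% power; the
        200-replicate estimate is allowed its 3-sigma binomial error."""
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            pse = rng.normal(1.0, 0.1, 8)
            pme = rng.normal(1.2, 0.1, 8)  # 2 SD shift
            res = compare_groups(self.records(pme, pse), metric="density")
            if res.p_value < 0.05:
                hits += 1
        mc_sigma = np.sqrt(0.95 * 0.05 / n_rep)
        assert hits / n_rep >= 0.95 - 3 * mc_sigma

    def test_outlier_flags_iqr_convention(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        res = compare_groups(self.records(vals, [1.0, 2.0, 3.0, 4.0, 5.0]),
                             metric="density", welch="always")
        pme_rows = res.descriptives[res.descriptives["group"] == "PME"]
        assert bool(pme_rows.loc[pme_rows["value"] == 100.0, "outlier"].iloc[0])
        # points inside [Q1, Q3] are never flagged
        inside = pme_rows[(pme_rows["value"] >= pme_rows["q1"])
                          & (pme_rows["value"] <= pme_rows["q3"])]
        assert not inside["outlier"].any()
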