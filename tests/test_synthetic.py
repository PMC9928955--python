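"""Generators: design invariants, planted effects, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from synaptomics import (
    OmicsGroundTruth,
    StudyDesign,
    differential_table,
    generate_annotation_db,
    generate_image_stack,
    generate_interaction_edges,
    generate_kinase_substrate_map,
    generate_omics_dataset,
    normalize_total_amount,
    simulate_image_truth,
    simulate_level,
)
from synaptomics.enrichment import AnnotationDB
from synaptomics.synthetic.design import ParameterError


class TestStudyDesign:
    def test_default_design_matches_study_layout(self):
        d = StudyDesign()
        assert d.regions == ("M1", "S1", "DLS", "DMS")
        assert d.n_samples == 16
        table = d.sample_table("M1")
        assert len(table) == 16
        counts = table.groupby(["group", "sex"]).size()
        assert (counts == 4).all()

    def test_sex_split_must_sum_to_group_size(self):
        with pytest.raises(ParameterError):
            StudyDesign(sex_split=(3, 4))

    def test_groups_are_fixed(self):
        with pytest.raises(ParameterError):
            StudyDesign(groups=("PME", "CTRL"))


class TestOmicsGenerator:
    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            OmicsGroundTruth(n_features=0)
        with pytest.raises(ParameterError):
            OmicsGroundTruth(frac_differential=1.5)
        with pytest.raises(ParameterError):
            OmicsGroundTruth(noise_sd=-0.1)

    def test_abundances_positive_and_shapes(self, small_design):
        truth = OmicsGroundTruth(n_features=100, seed=0)
        matrices, truth = simulate_level(small_design, truth)
        assert set(matrices) == set(small_design.regions)
        for m in matrices.values():
            assert m.values.shape == (100, 16)
            assert (m.values.to_numpy() > 0).all()

    def test_masks_disjoint_and_null_effects_zero(self, small_design):
        truth = OmicsGroundTruth(n_features=200, frac_differential=0.2, seed=3)
        _, truth = simulate_level(small_design, truth)
        assert not (truth.shared_mask & truth.unique_mask).any()
        nondiff = ~(truth.shared_mask | truth.unique_mask)
        assert (truth.effect_log2.to_numpy()[nondiff] == 0).all()
        for loading in truth.channel_loading.values():
            assert (loading > 0).all()

    def test_null_alpha_calibration(self, null_dataset):
        """With no planted effects the t-test false-positive rate is ~alpha."""
        matrices, _ = null_dataset
        table = differential_table(matrices["M1"])
        frac = (table.records["p_value"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_noiseless_planted_effect_doubles_group_mean(self, small_design):
        truth = OmicsGroundTruth(n_features=50, frac_differential=0.1,
                                 effect_size_log2=1.0, frac_shared=0.0,
                                 noise_sd=0.0, channel_loading_range=(1.0, 1.0),
                                 seed=2)
        matrices, truth = simulate_level(small_design, truth)
        # pick a feature planted in exactly one region
        planted = np.argwhere(truth.unique_mask).ravel()
        assert len(planted) > 0
        i = planted[0]
        regions_hit = truth.effect_log2.iloc[i]
        region = regions_hit[regions_hit != 0].index[0]
        for r in small_design.regions:
            m = matrices[r]
            pme = m.values.iloc[i][m.group_columns("PME")].mean()
            pse = m.values.iloc[i][m.group_columns("PSE")].mean()
            expected = 2.0 ** regions_hit[r]
            assert pme / pse == pytest.approx(expected, rel=1e-9)
        assert (regions_hit == 0).sum() == len(small_design.regions) - 1
        assert abs(regions_hit[region]) == 1.0

    def test_planted_effect_recovery_against_resimulation_oracle(self, small_design):
        """Pipeline sensitivity matches an independent re-simulation at the same seed."""
        truth = OmicsGroundTruth(n_features=1000, frac_differential=0.1,
                                 effect_size_log2=1.0, noise_sd=0.3, seed=1)
        matrices, truth = simulate_level(small_design, truth)
        table = differential_table(matrices["M1"])
        sig = table.records.set_index("feature_id")["significant"]

        # oracle: regenerate the model directly from the same seed and recompute
        truth2 = OmicsGroundTruth(n_features=1000, frac_differential=0.1,
                                  effect_size_log2=1.0, noise_sd=0.3, seed=1)
        matrices2, truth2 = simulate_level(small_design, truth2)
        pd.testing.assert_frame_equal(truth.effect_log2, truth2.effect_log2)
        planted = truth2.effect_log2["M1"] != 0
        sensitivity = sig[planted[planted].index].mean()
        assert sensitivity >= 0.8

    def test_determinism_bit_identical(self, small_design):
        t1 = OmicsGroundTruth(n_features=80, frac_differential=0.1, seed=9)
        t2 = OmicsGroundTruth(n_features=80, frac_differential=0.1, seed=9)
        m1, _ = simulate_level(small_design, t1)
        m2, _ = simulate_level(small_design, t2)
        for r in small_design.regions:
            pd.testing.assert_frame_equal(m1[r].values, m2[r].values)

    def test_pair_generation_round_trips_tsv(self, small_design, tmp_path):
        truth = OmicsGroundTruth(n_features=40, seed=4)
        matrices, _ = generate_omics_dataset(small_design, truth)
        prot, phos = matrices["M1"]
        assert phos.site_labels is not None
        path = tmp_path / "m1.tsv"
        prot.write_tsv(path)
        back = type(prot).read_tsv(path)
        assert back.region == "M1"
        np.testing.assert_allclose(back.values.to_numpy(), prot.values.to_numpy())


class TestKinaseMapGenerator:
    def test_empty_map(self):
        m = generate_kinase_substrate_map(0, 5, ["a", "b"])
        assert m.empty

    def test_construction_invariants(self):
        feats = [f"pS{i}" for i in range(20)]
        m = generate_kinase_substrate_map(2, 5, feats, seed=1)
        assert len(m) == 10
        assert set(m["substrate"]).issubset(feats)
        assert (m["networkin_score"] >= 0).all()
        assert set(m["source"]).issubset({"PSP", "NetworKIN"})

    def test_oversized_request_rejected(self):
        with pytest.raises(ParameterError):
            generate_kinase_substrate_map(1, 30, [f"s{i}" for i in range(10)])


class TestAnnotationGenerator:
    def test_unknown_category_rejected(self):
        with pytest.raises(ParameterError):
            generate_annotation_db(3, ["g1"], "WikiPathways")

    def test_gmt_round_trip(self, tmp_path):
        genes = [f"G{i}" for i in range(100)]
        db = generate_annotation_db(10, genes, "Reactome", seed=7)
        path = tmp_path / "db.gmt"
        db.write_gmt(path)
        back = AnnotationDB.read_gmt(path, category="Reactome")
        assert back.terms == db.terms

    def test_every_term_has_members(self):
        db = generate_annotation_db(20, [f"G{i}" for i in range(30)], "KEGG", seed=2)
        assert all(len(m) >= 1 for m in db.terms.values())


class TestInteractionEdgeGenerator:
    def test_planted_labels_cover_all_nodes(self):
        nodes = [f"N{i}" for i in range(24)]
        edges, labels = generate_interaction_edges(nodes, n_communities=3, seed=0)
        assert set(labels) == set(nodes)
        assert set(labels.values()) == {0, 1, 2}
        assert ((edges["combined_score"] >= 0) & (edges["combined_score"] <= 1)).all()


class TestImageGenerator:
    def test_truth_invariants(self):
        truth = simulate_image_truth(n_pairs=10, n_unpaired_pre=5, n_unpaired_post=5,
                                     stack_shape=(12, 80, 80), seed=0)
        extent = truth.extent_um
        for pts in (truth.pre_centroids, truth.post_centroids):
            assert (pts >= 0).all() and (pts < extent).all()
        for i, j in truth.paired_indices:
            d = np.linalg.norm(truth.pre_centroids[i] - truth.post_centroids[j])
            assert d <= 0.5

    def test_snr_must_be_positive(self):
        truth = simulate_image_truth(n_pairs=2, n_unpaired_pre=2, n_unpaired_post=2,
                                     stack_shape=(10, 60, 60), seed=1)
        with pytest.raises(ParameterError):
            generate_image_stack(truth, snr=0)

    def test_stack_determinism(self):
        truth = simulate_image_truth(n_pairs=5, n_unpaired_pre=3, n_unpaired_post=3,
                                     stack_shape=(10, 60, 60), seed=3)
        s1, _ = generate_image_stack(truth, snr=20, seed=8)
        s2, _ = generate_image_stack(truth, snr=20, seed=8)
        np.testing.assert_array_equal(s1.channels["pre"], s2.channels["pre"])
        np.testing.assert_array_equal(s1.channels["post"], s2.channels["post"])

    def test_occluder_keeps_centroids_out(self):
        truth = simulate_image_truth(n_pairs=8, n_unpaired_pre=4, n_unpaired_post=4,
                                     n_nuclei=2, nucleus_radius_um=1.0,
                                     stack_shape=(24, 100, 100), seed=5)
        for pts in (truth.pre_centroids, truth.post_centroids):
            for p in pts:
                assert not truth._inside_occluder(p)
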