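"""Contracts of the phantom generator: determinism, geometry, causal labels."""

import hashlib

import numpy as np
import pytest

from fundusmtl import synth
from fundusmtl.synth import (Clause, DiseaseRule, LabelRule, LesionSpec,
                             VesselTreeParams, generate_dataset,
                             generate_vessel_tree, render_sample)


@pytest.fixture(scope="module")
def default_tree():
    return generate_vessel_tree(VesselTreeParams(field_radius=28), 7, (64, 64))


def simple_rule(threshold=5):
    return LabelRule(diseases=(
        DiseaseRule("k", (Clause("n_microaneurysms", threshold),)),))


class TestVesselTree:
    def test_zero_trees_give_empty_output(self):
        tree = generate_vessel_tree(VesselTreeParams(n_trees=0), 0, (64, 64))
        assert tree.mask.sum() == 0
        assert tree.tortuosity_score == 0.0
        assert tree.centerlines == []

    def test_identical_seed_is_bit_identical(self):
        params = VesselTreeParams()
        a = generate_vessel_tree(params, 123, (64, 64))
        b = generate_vessel_tree(params, 123, (64, 64))
        assert np.array_equal(a.mask, b.mask)
        assert a.tortuosity_score == b.tortuosity_score
        c = generate_vessel_tree(params, 124, (64, 64))
        assert not np.array_equal(a.mask, c.mask)

    def test_full_branching_segment_count(self):
        # branch_prob=1: each of 2 trees is a full binary tree of depth 3
        # with 2^3 - 1 = 7 segments
        tree = generate_vessel_tree(
            VesselTreeParams(n_trees=2, max_depth=3, branch_prob=1.0), 5,
            (64, 64))
        assert len(tree.centerlines) == 2 * (2 ** 3 - 1)

    def test_chain_when_never_branching(self):
        tree = generate_vessel_tree(
            VesselTreeParams(n_trees=3, max_depth=4, branch_prob=0.0), 5,
            (64, 64))
        assert len(tree.centerlines) == 3 * 4

    def test_mask_binary_and_inside_fundus_disc(self, default_tree):
        assert set(np.unique(default_tree.mask)) <= {0, 1}
        h, w = default_tree.mask.shape
        rr, cc = np.mgrid[:h, :w]
        dist2 = (rr - h / 2) ** 2 + (cc - w / 2) ** 2
        assert (dist2[default_tree.mask == 1] <= 28 ** 2).all()

    def test_tortuosity_score_tracks_parameter(self):
        lo = generate_vessel_tree(VesselTreeParams(tortuosity=0.05), 1,
                                  (64, 64))
        hi = generate_vessel_tree(VesselTreeParams(tortuosity=0.5), 1,
                                  (64, 64))
        assert hi.tortuosity_score > 2 * lo.tortuosity_score
        # E|N(0, s)| = s * sqrt(2/pi); the score estimates it
        assert lo.tortuosity_score == pytest.approx(
            0.05 * np.sqrt(2 / np.pi), rel=0.3)

    def test_degenerate_field_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            VesselTreeParams(field_radius=1, width_root=2.0)

    def test_field_must_fit_image(self):
        with pytest.raises(ValueError, match="fit"):
            generate_vessel_tree(VesselTreeParams(field_radius=40), 0,
                                 (64, 64))


class TestRenderSample:
    def test_no_lesions_means_negative_label(self, default_tree):
        sample = render_sample(default_tree, LesionSpec(), simple_rule(5), 0)
        assert sample.labels.tolist() == [0]

    def test_lesions_above_threshold_fire_label(self, default_tree):
        sample = render_sample(default_tree, LesionSpec(n_microaneurysms=6),
                               simple_rule(5), 0)
        assert sample.labels.tolist() == [1]

    def test_image_range_and_mask_support(self, default_tree):
        sample = render_sample(default_tree, LesionSpec(n_exudates=3),
                               simple_rule(), 3)
        assert sample.image.dtype == np.float32
        assert sample.image.min() >= 0.0 and sample.image.max() <= 1.0
        assert np.array_equal(sample.vessel_mask, default_tree.mask)

    def test_vessel_pixels_recounted_from_rendered_image(self, default_tree):
        # vessels are drawn last with a constant color, so thresholding the
        # rendered (noise-free) image recovers exactly the mask support
        sample = render_sample(default_tree, LesionSpec(n_hemorrhages=2,
                                                        n_exudates=2),
                               simple_rule(), 4, noise_sigma=0.0)
        vessel_color = np.array([0.45, 0.13, 0.10], dtype=np.float32)
        recount = (np.abs(sample.image - vessel_color).sum(axis=2)
                   < 1e-5).sum()
        assert recount == sample.vessel_mask.sum()

    def test_undefined_rule_feature_raises(self, default_tree):
        bad = LabelRule(diseases=(
            DiseaseRule("x", (Clause("n_cotton_wool_spots", 1),)),))
        with pytest.raises(KeyError, match="n_cotton_wool_spots"):
            render_sample(default_tree, LesionSpec(), bad, 0)

    def test_oversized_lesion_rejected(self, default_tree):
        with pytest.raises(ValueError, match="radius"):
            render_sample(default_tree,
                          LesionSpec(n_exudates=1, exudate_radius=40.0),
                          simple_rule(), 0)


class TestGenerateDataset:
    def test_paired_eyes_share_patient_and_tree(self):
        samples, manifest = generate_dataset(4, seed=0, paired_eyes=True)
        assert manifest["patient_id"].nunique() == 2
        left, right = samples[0], samples[1]
        assert left.patient_id == right.patient_id
        assert (left.eye, right.eye) == ("left", "right")
        # right eye is the mirrored vessel tree of the same seed
        assert np.array_equal(left.vessel_mask, right.vessel_mask[:, ::-1])

    def test_odd_paired_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_dataset(5, seed=0, paired_eyes=True)

    def test_manifest_schema_and_label_consistency(self):
        samples, manifest = generate_dataset(12, seed=1)
        c = samples[0].labels.shape[0]
        assert list(manifest.columns) == (["path", "patient_id", "eye"]
                                          + [f"label_{j}" for j in range(c)])
        for i, s in enumerate(samples):
            assert manifest.loc[i, [f"label_{j}" for j in range(c)]
                                ].tolist() == s.labels.tolist()

    def test_seeded_manifest_hash_is_stable(self):
        _, m1 = generate_dataset(10, seed=9)
        _, m2 = generate_dataset(10, seed=9)
        h1 = hashlib.sha256(m1.to_csv(index=False).encode()).hexdigest()
        h2 = hashlib.sha256(m2.to_csv(index=False).encode()).hexdigest()
        assert h1 == h2

    def test_multilabel_fraction_exceeds_dataset_floor(self):
        # the default configuration targets the >= 23% multi-label share of
        # public multi-disease fundus datasets (checked at smaller n here;
        # the acceptance suite re-checks at n=1000)
        samples, _ = generate_dataset(400, seed=2)
        labels = np.stack([s.labels for s in samples])
        assert (labels.sum(axis=1) >= 2).mean() >= 0.23

    def test_rare_class_prevalence_is_controllable(self):
        # the tortuosity-driven class has prevalence p_high_tortuosity;
        # configured at 0.06 the observed rate must fall within 3 binomial
        # standard deviations for n = 500
        p = 0.06
        n = 500
        dist = synth.LesionDistribution(p_high_tortuosity=p)
        samples, _ = generate_dataset(n, seed=3, lesions_distribution=dist)
        labels = np.stack([s.labels for s in samples])
        observed = labels[:, 2].mean()
        assert abs(observed - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_labels_identifiable_from_provenance(self):
        # a decision tree on (lesion counts, tortuosity) alone reaches 100%
        # accuracy: labels are deterministic functions of provenance
        from sklearn.tree import DecisionTreeClassifier

        samples, _ = generate_dataset(200, seed=4)
        feats = synth.provenance_features(samples)
        labels = np.stack([s.labels for s in samples])
        for j in range(labels.shape[1]):
            if labels[:, j].sum() in (0, len(samples)):
                continue
            clf = DecisionTreeClassifier(random_state=0)
            clf.fit(feats, labels[:, j])
            assert clf.score(feats, labels[:, j]) == 1.0

    def test_label_noise_flips_some_labels(self):
        clean, _ = generate_dataset(60, seed=5)
        noisy, _ = generate_dataset(60, seed=5, label_flip_prob=0.3)
        clean_l = np.stack([s.labels for s in clean])
        noisy_l = np.stack([s.labels for s in noisy])
        frac = (clean_l != noisy_l).mean()
        assert 0.1 < frac < 0.5

    def test_png_round_trip(self, tmp_path):
        import imageio.v3 as iio

        samples, manifest = generate_dataset(3, seed=6,
                                             out_dir=str(tmp_path))
        img = iio.imread(manifest.loc[0, "path"])
        assert img.shape == (64, 64, 3) and img.dtype == np.uint8
        mask = iio.imread(tmp_path / "sample_00000_mask.png")
        assert set(np.unique(mask)) <= {0, 255}
        assert np.array_equal((mask > 127).astype(np.uint8),
                              samples[0].vessel_mask)
        assert (tmp_path / "manifest.csv").exists()
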