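"""Vessel graph extraction and the 24-feature descriptor on phantoms."""

import numpy as np
import pytest

from funduskit.features import (FEATURE_NAMES, classify_av, detect_junctions,
                                extract_features, skeletonize_vessels,
                                tortuosity)
from funduskit.enhancement import preprocess
from funduskit.synthetic import generate_fundus, spec_for_grade


def _bar_mask(h=40, w=60, width=5):
    m = np.zeros((h, w), dtype=bool)
    m[h // 2 - width // 2: h // 2 + (width + 1) // 2, 5:-5] = True
    return m


class TestSkeleton:
    def test_straight_bar_is_one_segment_with_correct_width(self):
        g = skeletonize_vessels(_bar_mask(width=5))
        assert len(g.segments) == 1
        assert not g.junctions
        assert g.widths[0] == pytest.approx(5.0, abs=1.0)

    def test_y_mask_has_one_bifurcation_three_segments(self):
        m = np.zeros((60, 60), dtype=bool)
        m[30:33, 5:30] = True          # stem
        for i in range(25):            # two diverging branches
            m[28 - i // 2: 31 - i // 2, 30 + i] = True
            m[31 + i // 2: 34 + i // 2, 30 + i] = True
        g = skeletonize_vessels(m)
        kinds = [k for _, _, k in g.junctions]
        assert kinds.count("bifurcation") == 1
        assert kinds.count("crossover") == 0
        assert len(g.segments) == 3

    def test_x_mask_has_one_crossover(self):
        m = np.zeros((61, 61), dtype=bool)
        for i in range(61):
            m[max(0, i - 1):i + 2, i] = True
            m[max(0, 59 - i):62 - i, i] = True
        g = skeletonize_vessels(m)
        kinds = [k for _, _, k in g.junctions]
        assert kinds.count("crossover") == 1
        # the crossing bars are separated into four arms
        assert len(g.segments) == 4

    def test_empty_mask_yields_empty_graph(self):
        g = skeletonize_vessels(np.zeros((32, 32), dtype=bool))
        assert g.segments == [] and g.junctions == [] and g.widths == []

    def test_synthetic_tree_bifurcations_match_generator_bookkeeping(self):
        s = generate_fundus(spec_for_grade("normal", seed=13, width=128,
                                           height=128, noise_sd=0.0))
        g = skeletonize_vessels(s.vessel_mask)
        found = np.array([(r, c) for r, c, k in g.junctions
                          if k == "bifurcation"], dtype=float)
        truth = np.array(s.branch_points, dtype=float)
        truth = truth[(truth[:, 0] >= 0) & (truth[:, 0] < 128)
                      & (truth[:, 1] >= 0) & (truth[:, 1] < 128)]
        assert len(found) > 0
        # most true branch points should have a detected junction nearby
        d = np.sqrt(((truth[:, None, :] - found[None, :, :]) ** 2).sum(-1))
        matched = (d.min(axis=1) <= 6.0).mean()
        assert matched >= 0.5


class TestTortuosity:
    def test_straight_chain_is_one(self):
        chain = np.stack([np.full(20, 5), np.arange(20)], axis=1)
        assert tortuosity(chain) == pytest.approx(1.0)

    def test_curved_chain_exceeds_one(self):
        t = np.linspace(0, np.pi, 50)
        chain = np.stack([10 + 5 * np.sin(t), 20 * t / np.pi], axis=1)
        assert tortuosity(chain) > 1.0

    def test_always_at_least_one_on_synthetic_graph(self, normal_sample):
        g = skeletonize_vessels(normal_sample.vessel_mask)
        assert all(tortuosity(s) >= 1.0 for s in g.segments)


class TestClassifyAV:
    def test_fallback_rule_separates_synthetic_arteries_and_veins(self):
        s = generate_fundus(spec_for_grade("normal", seed=17, width=128,
                                           height=128, noise_sd=0.0))
        g = skeletonize_vessels(s.vessel_mask)
        av = classify_av(s.image, g)
        correct = total = 0
        for chain, lab in zip(g.segments, av.labels):
            r, c = chain[:, 0], chain[:, 1]
            a = s.artery_mask[r, c].mean()
            v = s.vein_mask[r, c].mean()
            if max(a, v) < 0.6:
                continue  # ambiguous segment (overlap region)
            truth = "artery" if a > v else "vein"
            total += 1
            correct += (lab == truth)
        assert total > 4
        assert correct / total >= 0.9

    def test_identical_segments_degenerate_to_one_class(self):
        m = _bar_mask()
        g = skeletonize_vessels(m)
        img = np.full((40, 60), 0.5)
        with pytest.warns(RuntimeWarning):
            av = classify_av(img, g)
        assert av.degenerate

    def test_trained_knn_on_separable_segment_features(self):
        from sklearn.neighbors import KNeighborsClassifier
        s = generate_fundus(spec_for_grade("normal", seed=19, width=128,
                                           height=128, noise_sd=0.0))
        g = skeletonize_vessels(s.vessel_mask)
        truth = []
        for chain in g.segments:
            r, c = chain[:, 0], chain[:, 1]
            truth.append("artery" if s.artery_mask[r, c].mean()
                         >= s.vein_mask[r, c].mean() else "vein")
        av = classify_av(s.image, g, model=KNeighborsClassifier(3),
                         labels_for_fit=truth)
        acc = np.mean([p == t for p, t in zip(av.labels, truth)])
        assert acc >= 0.95  # train-set accuracy of the fitted model


class TestExtractFeatures:
    def test_constant_image_texture_limits(self):
        img = np.full((64, 64, 3), 0.5)
        enh = np.full((64, 64), 0.5)
        mask = _bar_mask(64, 64)
        g = skeletonize_vessels(mask)
        vec = extract_features(img, enh, mask, None, g)
        named = dict(zip(FEATURE_NAMES, vec))
        assert named["glcm_energy"] == pytest.approx(1.0)
        assert named["glcm_entropy"] == pytest.approx(0.0, abs=1e-12)
        assert named["glcm_contrast"] == pytest.approx(0.0)

    def test_vessel_density_is_mask_fraction(self):
        img = np.random.default_rng(0).uniform(size=(50, 40, 3))
        enh = img[..., 1]
        fov = np.ones((50, 40), dtype=bool)
        mask = np.zeros((50, 40), dtype=bool)
        mask[:10] = True  # exactly 20% of the FOV
        g = skeletonize_vessels(mask)
        vec = extract_features(img, enh, mask, None, g, fov=fov)
        assert dict(zip(FEATURE_NAMES, vec))["vessel_density"] == pytest.approx(0.2)

    def test_straight_tube_phantom_width_and_tortuosity(self):
        mask = _bar_mask(40, 60, width=6)
        img = np.dstack([mask * 0.8] * 3)
        g = skeletonize_vessels(mask)
        vec = extract_features(img, mask * 0.8, mask, None, g)
        named = dict(zip(FEATURE_NAMES, vec))
        assert named["mean_vessel_width"] == pytest.approx(6.0, abs=1.0)
        assert named["mean_tortuosity"] == pytest.approx(1.0, abs=0.01)

    def test_full_pipeline_vector_on_synthetic_image(self, severe_sample):
        enh = preprocess(severe_sample.image)
        g = skeletonize_vessels(severe_sample.vessel_mask)
        av = classify_av(severe_sample.image, g)
        vec = extract_features(severe_sample.image, enh.plane,
                               severe_sample.vessel_mask,
                               severe_sample.disc_mask, g, av,
                               fov=severe_sample.fov_mask)
        assert vec.shape == (24,)
        assert np.isfinite(vec).all()
        named = dict(zip(FEATURE_NAMES, vec))
        for key in ("disc_area_fraction", "disc_obscuration", "vessel_density",
                    "junction_density"):
            assert 0.0 <= named[key] <= 1.0
        assert named["mean_tortuosity"] >= 1.0

    def test_disc_obscuration_zero_without_crossing_vessels(self):
        img = np.random.default_rng(1).uniform(size=(64, 64, 3))
        enh = img[..., 1]
        vessel = _bar_mask(64, 64)
        disc = np.zeros((64, 64), dtype=bool)
        disc[5:15, 5:15] = True  # far from the bar
        g = skeletonize_vessels(vessel)
        vec = extract_features(img, enh, vessel, disc, g)
        assert dict(zip(FEATURE_NAMES, vec))["disc_obscuration"] == 0.0

    def test_empty_mask_warns_and_zeroes_vascular_group(self):
        img = np.random.default_rng(2).uniform(size=(64, 64, 3))
        g = skeletonize_vessels(np.zeros((64, 64), dtype=bool))
        with pytest.warns(RuntimeWarning):
            vec = extract_features(img, img[..., 1],
                                   np.zeros((64, 64), dtype=bool), None, g)
        named = dict(zip(FEATURE_NAMES, vec))
        assert named["vessel_density"] == 0.0
        assert named["mean_vessel_width"] == 0.0

    def test_mean_artery_width_decreases_with_narrowing_presets(self):
        widths = []
        for grade in ("normal", "mild", "moderate", "severe"):
            # default working canvas: narrow calibers stay above the
            # 1-pixel rasterization floor there
            s = generate_fundus(spec_for_grade(grade, seed=23, noise_sd=0.0))
            g = skeletonize_vessels(s.artery_mask)
            widths.append(np.mean(g.widths))
        assert all(a > b for a, b in zip(widths, widths[1:]))
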