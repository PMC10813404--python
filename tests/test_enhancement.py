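"""Enhancement chain against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest

from funduskit.enhancement import (ChannelStats, DegenerateChannelError,
                                   HSVImage, channel_probability, contrast_gain,
                                   doane_normalize, gaussian_response,
                                   preprocess, rgb_to_hsv_paper, select_channel,
                                   skewness)


class TestGaussianResponse:
    def test_worked_2x2_channel(self):
        ch = np.array([[0.2, 0.4], [0.6, 0.8]])
        st = gaussian_response(ch)
        # scalar oracle: population moments, then the printed density form
        m = (0.2 + 0.4 + 0.6 + 0.8) / 4
        s = np.sqrt((0.04 + 0.16 + 0.36 + 0.64) / 4 - m ** 2)
        assert st.m == pytest.approx(0.5)
        assert st.s == pytest.approx(s)
        for val, got in zip(ch.ravel(), st.G.ravel()):
            exp = 1.0 / (2 * np.pi * s) * np.exp(-((val - m) ** 2) / s)
            assert got == pytest.approx(exp)

    def test_constant_channel_is_degenerate(self):
        with pytest.raises(DegenerateChannelError):
            gaussian_response(np.full((4, 4), 0.3))

    def test_response_maximal_at_the_mean(self):
        ch = np.array([[0.2, 0.5], [0.5, 0.8]])
        st = gaussian_response(ch)
        assert st.m == pytest.approx(0.5)
        assert st.G.max() == pytest.approx(1.0 / (2 * np.pi * st.s))
        assert np.unravel_index(st.G.argmax(), ch.shape) in ((0, 1), (1, 0))


class TestContrastGain:
    def test_zero_gaussian_response_gives_unit_scaling(self):
        ch = np.array([[0.2, 0.4], [0.6, 0.8]])
        st = gaussian_response(ch)
        st_zero = ChannelStats(m=st.m, s=st.s, n=st.n, G=np.zeros_like(ch))
        cg = contrast_gain(ch, st_zero, lam=0.2)
        assert np.allclose(cg.g, 1.0)
        assert np.allclose(cg.gain, 1.0 + cg.f)

    def test_zero_f_means_identity(self):
        ch = np.ones((3, 3))  # (1 - o) = 0 everywhere -> f = 0
        st = ChannelStats(m=1.0, s=0.1, n=9, G=np.zeros((3, 3)))
        cg = contrast_gain(ch, st, lam=0.2)
        assert cg.f == 0.0
        assert np.allclose(cg.gain, 1.0)

    def test_worked_2x2_matches_scalar_oracle(self):
        ch = np.array([[0.2, 0.4], [0.6, 0.8]])
        st = gaussian_response(ch)
        cg = contrast_gain(ch, st, lam=0.2)
        # brute-force oracle: every quantized value unique -> p = 1/4
        f = sum(0.25 * (1 - v) for v in ch.ravel()) / 4
        assert cg.f == pytest.approx(f)
        for G, o, gain in zip(st.G.ravel(), ch.ravel(), cg.gain.ravel()):
            g = 1 + G / 0.2
            assert gain == pytest.approx(1 + f / g)

    def test_rejects_nonpositive_lambda(self):
        ch = np.array([[0.2, 0.4], [0.6, 0.8]])
        st = gaussian_response(ch)
        with pytest.raises(ValueError):
            contrast_gain(ch, st, lam=0.0)


class TestHSV:
    def test_gray_pixel(self):
        img = np.full((1, 1, 3), 0.5)
        hsv = rgb_to_hsv_paper(img)
        assert hsv.beta_s[0, 0] == 0.0
        assert hsv.beta_v[0, 0] == pytest.approx(1 / 3)
        assert hsv.beta_h[0, 0] == 0.0
        assert not hsv.hue_valid[0, 0]

    def test_pure_red(self):
        img = np.zeros((1, 1, 3))
        img[0, 0, 0] = 1.0
        hsv = rgb_to_hsv_paper(img)
        assert hsv.beta_r[0, 0] == 1.0
        assert hsv.beta_v[0, 0] == 1.0
        assert hsv.beta_s[0, 0] == 1.0

    def test_scalar_oracle_on_mixed_pixel(self):
        r, g, b = 0.6, 0.3, 0.1
        img = np.array([[[r, g, b]]])
        hsv = rgb_to_hsv_paper(img)
        t = r + g + b
        br, bg, bb = r / t, g / t, b / t
        hue = np.arccos(0.5 * (2 * br - bg - bb) /
                        np.sqrt((br - bg) ** 2 + (br - bb) * (bg - bb)))
        assert hsv.beta_h[0, 0] == pytest.approx(hue)
        assert hsv.beta_s[0, 0] == pytest.approx((br - bb) / br)
        assert hsv.beta_v[0, 0] == pytest.approx(br)

    def test_chromaticities_sum_to_one(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.01, 1.0, (16, 16, 3))
        hsv = rgb_to_hsv_paper(img)
        total = hsv.beta_r + hsv.beta_g + hsv.beta_b
        assert np.all(np.abs(total - 1.0) < 1e-9)


class TestDoane:
    def test_symmetric_plane_has_zero_skew(self):
        plane = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]).reshape(1, -1)
        assert skewness(plane) == pytest.approx(0.0, abs=1e-12)

    def test_skew_matches_moment_oracle(self):
        plane = np.tile([0.1, 0.2, 0.7], 16).reshape(4, 12)
        x = plane.ravel()
        m, s = x.mean(), x.std()
        expected = np.mean((x - m) ** 3) / s ** 3
        rec = doane_normalize(plane)
        assert rec.skew == pytest.approx(expected)

    def test_finite_with_zeros_and_rescaled(self):
        plane = np.array([[0.0, 0.5], [0.25, 1.0]])
        rec = doane_normalize(plane)
        assert np.isfinite(rec.psi_h).all()
        assert rec.psi_h.min() == pytest.approx(0.0)
        assert rec.psi_h.max() == pytest.approx(1.0)


class TestChannelProbability:
    def test_constant_plane(self):
        assert np.allclose(channel_probability(np.full((5, 5), 0.4)), 1.0)

    def test_two_valued_plane(self):
        plane = np.array([[0.1, 0.9], [0.9, 0.1]])
        assert np.allclose(channel_probability(plane), 0.5)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        plane = rng.uniform(size=(4, 4))
        prob = channel_probability(plane)
        q = np.round(plane * 255).astype(int)
        for idx in np.ndindex(4, 4):
            assert prob[idx] == pytest.approx(np.sum(q == q[idx]) / 16)


class TestSelectChannel:
    @staticmethod
    def _mk(h, s, v):
        return HSVImage(beta_h=h, beta_s=s, beta_v=v, beta_r=h, beta_g=s,
                        beta_b=v, hue_valid=np.ones(h.shape, dtype=bool))

    def test_identical_planes_fall_through_to_v(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=(8, 8))
        sel = select_channel(self._mk(p.copy(), p.copy(), p.copy()))
        assert (sel.choice_map == "v").all()
        assert np.array_equal(sel.selected_plane, p)

    def test_engineered_h_selection(self):
        # h has all-unique values (rare -> low probability); s, v constant
        h = np.linspace(0, 1, 64).reshape(8, 8)
        s = np.full((8, 8), 0.5)
        v = np.full((8, 8), 0.5)
        sel = select_channel(self._mk(h, s, v))
        assert (sel.choice_map == "h").all()

    def test_matches_brute_force_cascade(self):
        rng = np.random.default_rng(5)
        h = rng.choice([0.1, 0.2, 0.3], size=(10, 10))
        s = rng.choice([0.4, 0.5], size=(10, 10))
        v = rng.choice([0.6, 0.7, 0.8, 0.9], size=(10, 10))
        sel = select_channel(self._mk(h, s, v))
        ph, ps, pv = (channel_probability(x) for x in (h, s, v))
        for idx in np.ndindex(10, 10):
            mp = (ph[idx] + ps[idx] + pv[idx]) / 3
            if ph[idx] < mp:
                exp = "h"
            elif ps[idx] < mp:
                exp = "s"
            else:
                assert pv[idx] <= mp  # cascade is total
                exp = "v"
            assert sel.choice_map[idx] == exp


class TestPreprocess:
    def test_deterministic_and_bounded(self, normal_sample):
        e1 = preprocess(normal_sample.image)
        e2 = preprocess(normal_sample.image)
        assert np.array_equal(e1.plane, e2.plane)
        assert e1.plane.min() >= 0.0 and e1.plane.max() <= 1.0
        assert e1.plane.shape == normal_sample.image.shape[:2]

    def test_increases_local_contrast(self, normal_sample):
        from scipy import ndimage as ndi

        def rms_local(p, size=15):
            m = ndi.uniform_filter(p, size)
            m2 = ndi.uniform_filter(p * p, size)
            return float(np.sqrt(np.maximum(m2 - m * m, 0).mean()))

        enh = preprocess(normal_sample.image)
        assert rms_local(enh.plane) >= rms_local(normal_sample.image[..., 1])

    def test_degenerate_channel_warns_and_survives(self):
        img = np.zeros((64, 64, 3))
        img[..., 1] = np.random.default_rng(0).uniform(size=(64, 64))
        img[..., 0] = 0.5  # constant red channel
        img[..., 2] = 0.25
        with pytest.warns(RuntimeWarning):
            enh = preprocess(img)
        assert np.isfinite(enh.plane).all()

    def test_resize_option(self, normal_sample):
        enh = preprocess(normal_sample.image, resize=(80, 100))
        assert enh.plane.shape == (80, 100)
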