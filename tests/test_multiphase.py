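"""Four-phase segmentation: membership algebra, oracles, phantom runs."""

import numpy as np
import pytest

from spfseg.core import SmoothingKernel
from spfseg.evolution import EvolutionParams, segment_twophase
from spfseg.metrics import dice, multi_label_dice
from spfseg.multiphase import (
    fourphase_local_fits,
    fourphase_means,
    fourphase_spf,
    membership_fields,
    quantile_initializations,
    segment_fourphase,
)
from spfseg.phantoms import PhantomSpec, make_phantom


class TestMembershipFields:
    def test_zero_fields_give_quarter_each(self):
        z = np.zeros((4, 4))
        for m in membership_fields(z, z, 0.3):
            np.testing.assert_allclose(m, 0.25)

    def test_saturation_limit(self):
        big = np.full((3, 3), 1e9)
        m1, m2, m3, m4 = membership_fields(big, big, 0.1)
        np.testing.assert_allclose(m1, 1.0, atol=1e-6)
        for m in (m2, m3, m4):
            np.testing.assert_allclose(m, 0.0, atol=1e-6)

    def test_partition_of_unity(self, rng):
        phi1 = rng.uniform(-5, 5, size=(8, 8))
        phi2 = rng.uniform(-5, 5, size=(8, 8))
        total = sum(membership_fields(phi1, phi2, 0.3))
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


def loop_fourphase_means(image, memberships):
    out = []
    for m in memberships:
        num = den = 0.0
        for i in range(image.shape[0]):
            for j in range(image.shape[1]):
                num += image[i, j] * m[i, j]
                den += m[i, j]
        out.append(num / den)
    return out


class TestFourphaseMeansAndFits:
    def test_constant_image(self):
        image = np.full((6, 6), 0.42)
        ms = membership_fields(np.ones((6, 6)), -np.ones((6, 6)), 0.3)
        for c in fourphase_means(image, ms):
            assert c == pytest.approx(0.42)
        for f in fourphase_local_fits(image, ms, SmoothingKernel(sigma=2.0)):
            np.testing.assert_allclose(f, 0.42)

    def test_quadrant_means_near_quadrant_values(self):
        image, truth = make_phantom(PhantomSpec(shape=(16, 16), geometry="four_quadrant"))
        phi1 = np.where(np.isin(truth, [0, 1]), 1.0, -1.0)
        phi2 = np.where(np.isin(truth, [0, 2]), 1.0, -1.0)
        ms = membership_fields(phi1, phi2, 0.3)
        means = fourphase_means(image, ms)
        expected = loop_fourphase_means(image, ms)
        np.testing.assert_allclose(means, expected, atol=1e-10)
        # soft memberships pull toward the global mean but ordering holds
        assert means[0] < means[1] < means[2] < means[3] or means[0] < means[2]

    def test_random_fixture_matches_loop_oracle(self, rng):
        image = rng.uniform(size=(6, 6))
        phi1 = np.where(rng.uniform(size=(6, 6)) > 0.5, 1.0, -1.0)
        phi2 = np.where(rng.uniform(size=(6, 6)) > 0.5, 1.0, -1.0)
        ms = membership_fields(phi1, phi2, 0.3)
        np.testing.assert_allclose(
            fourphase_means(image, ms), loop_fourphase_means(image, ms), atol=1e-10
        )

    def test_fits_match_naive_windowed_oracle(self, rng):
        image = rng.uniform(size=(6, 6))
        phi1 = np.where(rng.uniform(size=(6, 6)) > 0.5, 1.0, -1.0)
        phi2 = np.where(rng.uniform(size=(6, 6)) > 0.5, 1.0, -1.0)
        ms = membership_fields(phi1, phi2, 0.3)
        kernel = SmoothingKernel(sigma=1.5)
        fits = fourphase_local_fits(image, ms, kernel)
        w2 = kernel.weights_2d()
        r = kernel.radius
        for m, f in zip(ms, fits):
            for i in range(6):
                for j in range(6):
                    num = den = 0.0
                    for di in range(-r, r + 1):
                        for dj in range(-r, r + 1):
                            ii = min(max(i + di, 0), 5)
                            jj = min(max(j + dj, 0), 5)
                            w = w2[di + r, dj + r]
                            num += w * m[ii, jj] * image[ii, jj]
                            den += w * m[ii, jj]
                    assert f[i, j] == pytest.approx(num / den, abs=1e-8)


class TestFourphaseSPF:
    @staticmethod
    def _state(image, truth):
        # orient so the phi1-positive region is the brighter one on both
        # phi2 sides: regions (1,2,3,4) = quadrant intensities (1.0,0.7,0.4,0.1)
        phi1 = np.where(np.isin(truth, [2, 3]), 1.0, -1.0)
        phi2 = np.where(np.isin(truth, [1, 3]), 1.0, -1.0)
        ms = membership_fields(phi1, phi2, 0.3)
        means = fourphase_means(image, ms)
        fits = fourphase_local_fits(image, ms, SmoothingKernel(sigma=2.0))
        return ms, means, fits

    def test_constant_image_zero_spf(self):
        image = np.full((8, 8), 0.6)
        truth = np.zeros((8, 8), int)
        truth[:4, 4:] = 1
        truth[4:, :4] = 2
        truth[4:, 4:] = 3
        ms, means, fits = self._state(image, truth)
        s1, s2 = fourphase_spf(image, ms, means, fits, np.full(image.shape, 0.5))
        assert np.all(s1 == 0) and np.all(s2 == 0)

    def test_global_mode_ignores_local_fits(self, rng):
        image, truth = make_phantom(PhantomSpec(shape=(16, 16), geometry="four_quadrant"))
        ms, means, fits = self._state(image, truth)
        garbage = tuple(rng.uniform(size=image.shape) for _ in range(4))
        omega = np.ones_like(image)
        s_ref = fourphase_spf(image, ms, means, fits, omega)
        s_garbage = fourphase_spf(image, ms, means, garbage, omega)
        np.testing.assert_allclose(s_ref[0], s_garbage[0])
        np.testing.assert_allclose(s_ref[1], s_garbage[1])

    def test_sign_matches_conditional_midpoint_on_quadrants(self):
        image, truth = make_phantom(PhantomSpec(shape=(32, 32), geometry="four_quadrant"))
        ms, means, fits = self._state(image, truth)
        omega = np.ones_like(image)
        s1, _ = fourphase_spf(image, ms, means, fits, omega)
        c1, c2, c3, c4 = means
        h2 = ms[0] + ms[2]
        mid = np.where(h2 > 0.5, 0.5 * (c1 + c3), 0.5 * (c2 + c4))
        interior = np.abs(image - mid) > 0.05  # skip near-tie pixels
        assert np.all(np.sign(s1[interior]) == np.sign((image - mid)[interior]))

    def test_bounded(self, rng):
        image = rng.uniform(size=(10, 10))
        phi1 = rng.uniform(-1, 1, size=(10, 10))
        phi2 = rng.uniform(-1, 1, size=(10, 10))
        ms = membership_fields(phi1, phi2, 0.3)
        means = fourphase_means(image, ms)
        fits = fourphase_local_fits(image, ms, SmoothingKernel(sigma=2.0))
        omega = rng.uniform(0, 1, size=(10, 10))
        for s in fourphase_spf(image, ms, means, fits, omega):
            assert np.all(np.abs(s) <= 1.0)


class TestSegmentFourphase:
    def test_quadrant_phantom_rectangle_inits(self):
        image, truth = make_phantom(PhantomSpec(shape=(96, 96), geometry="four_quadrant"))
        res = segment_fourphase(
            image, (10, 86, 8, 50), (8, 50, 10, 86), EvolutionParams(alpha=30.0)
        )
        report = multi_label_dice(res.labels, truth, "best-permutation")
        assert min(report.per_label.values()) >= 0.95

    def test_brain_rings_mean_dice(self):
        spec = PhantomSpec(
            shape=(96, 96), geometry="brain_rings", bias="gaussian_blob",
            bias_strength=0.2, noise_sigma=0.01, seed=3,
        )
        image, truth = make_phantom(spec)
        init1, init2 = quantile_initializations(image)
        res = segment_fourphase(
            image, init1, init2, EvolutionParams(alpha=50.0, max_iters=50)
        )
        report = multi_label_dice(res.labels, truth, "best-permutation")
        assert report.mean >= 0.90

    def test_partition_of_unity_every_iteration(self):
        image, _ = make_phantom(PhantomSpec(shape=(64, 64), geometry="four_quadrant"))
        res = segment_fourphase(
            image, (8, 56, 6, 34), (6, 34, 8, 56), EvolutionParams(alpha=30.0, max_iters=30)
        )
        partition_errors = [h[2] for h in res.history]
        assert max(partition_errors) <= 1e-12

    def test_two_value_image_uses_two_labels(self):
        image, _ = make_phantom(
            PhantomSpec(shape=(96, 96), geometry="disk", region_intensities=(0.0, 1.0))
        )
        res = segment_fourphase(image, (25, 50, 25, 50), (35, 70, 35, 70),
                                EvolutionParams(alpha=30.0))
        counts = np.sort([(res.labels == k).sum() for k in (1, 2, 3, 4)])
        assert counts[-2:].sum() / image.size >= 0.99

    def test_frozen_phi2_reduces_to_twophase(self):
        image, truth = make_phantom(PhantomSpec(shape=(128, 128), geometry="disk"))
        init = (30, 60, 30, 60)
        mask2 = segment_twophase(image, init, EvolutionParams(mode="proposed")).mask
        res4 = segment_fourphase(
            image, init, params=EvolutionParams(mode="proposed", alpha=20.0),
            phi2_field=np.full(image.shape, 1e6),
        )
        mask4 = res4.labels == 1
        assert dice(mask2, mask4) == 1.0

    def test_eps_sensitivity_peaks_at_default(self):
        spec = PhantomSpec(
            shape=(96, 96), geometry="brain_rings", bias="gaussian_blob",
            bias_strength=0.2, noise_sigma=0.01, seed=3,
        )
        image, truth = make_phantom(spec)
        init1, init2 = quantile_initializations(image)
        scores = {}
        for eps_d in (0.1, 0.3, 0.8):
            res = segment_fourphase(
                image, init1, init2,
                EvolutionParams(alpha=50.0, eps_d=eps_d, max_iters=50),
            )
            scores[eps_d] = multi_label_dice(res.labels, truth, "best-permutation").mean
        assert scores[0.3] >= scores[0.1]
        assert scores[0.3] >= scores[0.8]

    def test_labels_deterministic_function_of_final_signs(self):
        image, _ = make_phantom(PhantomSpec(shape=(64, 64), geometry="four_quadrant"))
        res = segment_fourphase(image, (8, 56, 6, 34), (6, 34, 8, 56),
                                EvolutionParams(alpha=30.0, max_iters=20))
        p1, p2 = res.phi1_final > 0, res.phi2_final > 0
        expected = np.full(image.shape, 4)
        expected[p1 & p2] = 1
        expected[p1 & ~p2] = 2
        expected[~p1 & p2] = 3
        np.testing.assert_array_equal(res.labels, expected)

    def test_non_finite_image_rejected(self):
        image = np.full((20, 20), 0.5)
        image[0, 0] = np.inf
        with pytest.raises(ValueError):
            segment_fourphase(image, (2, 10, 2, 10), (5, 15, 5, 15))
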