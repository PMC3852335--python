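"""Radial signatures, the Eq.-style DFT convention, descriptor
normalization and the classic shape-descriptor invariances."""
import numpy as np
import pytest

from cryptgrade import (ContourSet, dft, generate_crypt_boundary,
                        image_shape_features, normalize_descriptors,
                        radial_signature)
from cryptgrade.fourier import RadialSignature, RawDescriptors, crypt_descriptors, inverse_dft
from cryptgrade.geometry import Boundary
from cryptgrade.mst import centroid_from_boundary

from conftest import naive_dft


def circle(radius=10.0, n=720, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Boundary(np.column_stack([center[0] + radius * np.cos(t),
                                     center[1] + radius * np.sin(t)]))


class TestRadialSignature:
    def test_circle_gives_constant_radius(self):
        # dense polygonal circle: radius constant up to the chord sagitta
        sig = radial_signature(circle(10.0, n=8192), (0.0, 0.0), K=64)
        assert np.allclose(sig.samples, 10.0, rtol=0, atol=1e-5)

    def test_square_geometry(self):
        sq = Boundary(np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]]))
        sig = radial_signature(sq, (0.0, 0.0), K=16)
        assert sig.samples[0] == pytest.approx(1.0, abs=1e-12)      # theta = 0
        assert sig.samples[2] == pytest.approx(np.sqrt(2), abs=1e-12)  # theta = pi/4

    def test_ellipse_matches_closed_form(self):
        a, b = 20.0, 10.0
        t = np.linspace(0, 2 * np.pi, 32768, endpoint=False)
        ell = Boundary(np.column_stack([a * np.cos(t), b * np.sin(t)]))
        sig = radial_signature(ell, (0.0, 0.0), K=64)
        theta = 2 * np.pi * np.arange(64) / 64
        expected = a * b / np.sqrt(b**2 * np.cos(theta)**2 + a**2 * np.sin(theta)**2)
        assert np.allclose(sig.samples, expected, rtol=0, atol=1e-6)

    def test_centroid_outside_rejected(self):
        with pytest.raises(ValueError):
            radial_signature(circle(5.0), (50.0, 0.0), K=64)

    def test_max_crossing_taken_for_nonconvex_shape(self):
        # a star polygon is non-convex; every bin must still be filled
        t = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        r = 10.0 + 4.0 * np.cos(5 * t)
        star = Boundary(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        sig = radial_signature(star, (0.0, 0.0), K=64)
        assert np.all(np.isfinite(sig.samples)) and np.all(sig.samples > 0)


class TestDFT:
    def test_constant_signal_is_dc_only(self):
        sig = RadialSignature(np.full(32, 7.5), 32)
        z = dft(sig).coefficients
        assert z[0] == pytest.approx(7.5)
        assert np.allclose(z[1:], 0.0, atol=1e-12)

    def test_single_cosine_splits_into_conjugate_pair(self):
        # direct-summation check at K = 8: cos(2*pi*k/K) -> z_1 = z_7 = 1/2
        K = 16
        samples = 5.0 + np.cos(2 * np.pi * np.arange(K) / K)
        z = dft(RadialSignature(samples, K)).coefficients
        assert z[1] == pytest.approx(0.5, abs=1e-12)
        assert z[K - 1] == pytest.approx(0.5, abs=1e-12)
        others = np.delete(z, [0, 1, K - 1])
        assert np.allclose(others, 0.0, atol=1e-12)

    def test_matches_literal_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        for K in (16, 32, 64):
            samples = rng.uniform(5.0, 15.0, K)
            z = dft(RadialSignature(samples, K)).coefficients
            assert np.allclose(z, naive_dft(samples), atol=1e-12)

    def test_inverse_recovers_samples(self):
        rng = np.random.default_rng(3)
        samples = rng.uniform(5.0, 15.0, 64)
        raw = dft(RadialSignature(samples, 64))
        rec = inverse_dft(raw)
        assert np.allclose(rec, samples, rtol=1e-9)

    def test_conjugate_symmetry_for_real_input(self):
        rng = np.random.default_rng(4)
        z = dft(RadialSignature(rng.uniform(1, 2, 32), 32)).coefficients
        assert np.allclose(z[1:], np.conj(z[1:][::-1]), atol=1e-12)

    def test_truncated_reconstruction_error_is_monotone(self):
        """Reconstruction from the first m coefficient pairs converges
        monotonically in MSE as m grows."""
        b = generate_crypt_boundary(25.0, 0.5, rng_seed=7)
        c = centroid_from_boundary(b)
        sig = radial_signature(b, (c.x, c.y), K=64)
        raw = dft(sig)
        errs = []
        for m in range(1, 33):
            rec = inverse_dft(raw, n_pairs=m)
            errs.append(float(np.mean((rec - sig.samples) ** 2)))
        assert np.all(np.diff(errs) <= 1e-12)
        assert errs[-1] <= 1e-18


class TestNormalization:
    def test_perfect_circle_is_degenerate(self):
        sig = radial_signature(circle(10.0), (0.0, 0.0), K=64)
        dv = normalize_descriptors(dft(sig))
        assert dv.degenerate
        assert np.all(dv.magnitudes == 0.0)

    def test_first_magnitude_is_one_when_not_degenerate(self):
        for seed in range(5):
            b = generate_crypt_boundary(25.0, 0.4, rng_seed=seed)
            c = centroid_from_boundary(b)
            dv = crypt_descriptors(b, (c.x, c.y))
            assert not dv.degenerate
            assert dv.magnitudes[0] == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        b = generate_crypt_boundary(25.0, 0.4, rng_seed=2)
        c = centroid_from_boundary(b).point
        dv1 = crypt_descriptors(b, c)
        b3 = Boundary(c + 3.0 * (b.vertices - c))
        dv3 = crypt_descriptors(b3, c)
        assert np.allclose(dv1.magnitudes, dv3.magnitudes, atol=1e-9)

    def test_translation_invariance_is_exact(self):
        b = generate_crypt_boundary(25.0, 0.4, rng_seed=2)
        c = centroid_from_boundary(b).point
        dv1 = crypt_descriptors(b, c)
        shift = np.array([123.0, -45.0])
        dv2 = crypt_descriptors(Boundary(b.vertices + shift), c + shift)
        # centroid-relative parametrization: invariant to rounding of the
        # shifted coordinates
        assert np.allclose(dv1.magnitudes, dv2.magnitudes, rtol=0, atol=1e-12)

    def test_rotation_invariance(self):
        b = generate_crypt_boundary(25.0, 0.4, rng_seed=5, n_vertices=720)
        c = centroid_from_boundary(b).point
        dv1 = crypt_descriptors(b, c)
        for ang in (2 * np.pi / 64, 0.3, 1.234):  # grid-aligned and not
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            rb = Boundary((b.vertices - c) @ R.T + c)
            dv2 = crypt_descriptors(rb, c)
            assert np.allclose(dv1.magnitudes, dv2.magnitudes, atol=1e-3)


class TestImageShapeFeatures:
    def test_single_crypt_equals_its_descriptor(self):
        b = generate_crypt_boundary(25.0, 0.4, rng_seed=1, center=(100, 100))
        c = centroid_from_boundary(b)
        own = crypt_descriptors(b, (c.x, c.y))
        feats = image_shape_features(ContourSet(crypts=[b]))
        assert np.allclose(feats.values, own.magnitudes, atol=1e-12)

    def test_two_identical_crypts_average_to_either(self):
        b1 = generate_crypt_boundary(25.0, 0.4, rng_seed=1, center=(100, 100))
        b2 = Boundary(b1.vertices + np.array([120.0, 0.0]))
        feats = image_shape_features(ContourSet(crypts=[b1, b2]))
        single = image_shape_features(ContourSet(crypts=[b1]))
        assert np.allclose(feats.values, single.values, atol=1e-9)

    def test_degenerate_crypts_excluded_from_mean(self):
        b = generate_crypt_boundary(25.0, 0.4, rng_seed=1, center=(100, 100))
        disk = circle(20.0, center=(300.0, 100.0))
        cents = np.array([centroid_from_boundary(b).point, [300.0, 100.0]])
        feats = image_shape_features(ContourSet(crypts=[b, disk]), centroids=cents)
        single = image_shape_features(ContourSet(crypts=[b]))
        assert feats.n_degenerate == 1
        assert np.allclose(feats.values, single.values, atol=1e-12)

    def test_all_degenerate_flagged(self):
        feats = image_shape_features(ContourSet(crypts=[circle(20.0, center=(50, 50))]),
                                     centroids=np.array([[50.0, 50.0]]))
        assert feats.all_degenerate
        assert np.all(feats.values == 0.0)

    def test_distortion_cohorts_separate(self):
        """Under |z1| normalization the first harmonic measured about the
        area centroid scales as the *square* of the distortion amplitude, so
        normalized magnitudes 2-9 run *higher* for mildly distorted outlines:
        cohort means must separate with that ordering."""
        means = {}
        for d in (0.1, 0.5):
            vals = []
            for seed in range(20):
                b = generate_crypt_boundary(25.0, d, rng_seed=100 + seed)
                c = centroid_from_boundary(b)
                dv = crypt_descriptors(b, (c.x, c.y))
                vals.append(dv.magnitudes[1:].mean())
            means[d] = float(np.mean(vals))
        assert means[0.1] > means[0.5]
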