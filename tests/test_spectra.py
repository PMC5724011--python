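"""Isotopic envelopes: binomial mixtures, centroids, modality calls."""

import math

import numpy as np
import pytest

from hdxdiff.spectra import (
    DELTA_MASS,
    Spectrum,
    centroid_mass,
    classify_modality,
    simulate_envelope,
)


def binom_pmf_brute(k, n, p):
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


class TestSimulateEnvelope:
    def test_undeuterated_single_peak(self):
        sp = simulate_envelope(7, [(0.0, 1.0)], base_mz=1031.0)
        assert sp.intensity[0] == pytest.approx(1.0)
        assert sp.intensity[1:] == pytest.approx(np.zeros(7), abs=1e-15)

    def test_fully_deuterated_peak_at_top_mass(self):
        sp = simulate_envelope(7, [(1.0, 1.0)], base_mz=1031.0, charge=1)
        assert sp.intensity[-1] == pytest.approx(1.0)
        assert sp.mz[-1] == pytest.approx(1031.0 + 7 * DELTA_MASS)

    def test_mixture_equals_brute_force_binomials(self):
        sp = simulate_envelope(7, [(0.1, 0.5), (0.9, 0.5)], base_mz=1000.0)
        for k in range(8):
            expected = 0.5 * binom_pmf_brute(k, 7, 0.1) + 0.5 * binom_pmf_brute(k, 7, 0.9)
            assert sp.intensity[k] == pytest.approx(expected, abs=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            simulate_envelope(5, [(0.5, 0.7), (0.2, 0.7)], base_mz=500.0)
        with pytest.raises(ValueError):
            simulate_envelope(5, [(1.5, 1.0)], base_mz=500.0)

    def test_isotope_convolution_hook_shifts_centroid(self):
        plain = simulate_envelope(5, [(0.3, 1.0)], base_mz=800.0)
        conv = simulate_envelope(5, [(0.3, 1.0)], base_mz=800.0,
                                 isotope_pattern=np.array([0.7, 0.3]))
        assert centroid_mass(conv) > centroid_mass(plain)


class TestCentroid:
    def test_single_peak_is_its_mz(self):
        sp = Spectrum(mz=np.array([1031.0, 1032.0]), intensity=np.array([1.0, 0.0]))
        assert centroid_mass(sp) == pytest.approx(1031.0)

    def test_two_equal_peaks_average(self):
        sp = Spectrum(mz=np.array([1031.0, 1033.0]), intensity=np.array([1.0, 1.0]))
        assert centroid_mass(sp) == pytest.approx(1032.0)

    def test_binomial_mean_identity(self):
        for n, p, z in [(7, 0.4, 1), (10, 0.85, 2), (12, 0.05, 1)]:
            sp = simulate_envelope(n, [(p, 1.0)], base_mz=1000.0, charge=z)
            assert centroid_mass(sp) == pytest.approx(1000.0 + n * p * DELTA_MASS / z, abs=1e-9)

    def test_mixture_centroid_is_weighted_average(self):
        a = simulate_envelope(9, [(0.2, 1.0)], base_mz=900.0)
        b = simulate_envelope(9, [(0.8, 1.0)], base_mz=900.0)
        mix = simulate_envelope(9, [(0.2, 0.3), (0.8, 0.7)], base_mz=900.0)
        expected = 0.3 * centroid_mass(a) + 0.7 * centroid_mass(b)
        assert centroid_mass(mix) == pytest.approx(expected, abs=1e-9)


class TestModality:
    def test_pure_binomial_unimodal(self):
        sp = simulate_envelope(10, [(0.4, 1.0)], base_mz=1000.0)
        res = classify_modality(sp)
        assert res.label == "unimodal"
        assert res.components[0][0] == pytest.approx(0.4, abs=0.01)

    def test_well_separated_mixture_bimodal_with_recovery(self):
        sp = simulate_envelope(10, [(0.05, 0.5), (0.9, 0.5)], base_mz=1000.0)
        res = classify_modality(sp)
        assert res.label == "bimodal"
        (p1, w1), (p2, w2) = res.components
        assert p1 == pytest.approx(0.05, abs=0.05)
        assert p2 == pytest.approx(0.9, abs=0.05)
        assert w1 == pytest.approx(0.5, abs=0.05)

    def test_flat_two_peak_toy_bimodal(self):
        mz = 1000.0 + DELTA_MASS * np.arange(11)
        inten = np.zeros(11)
        inten[0] = inten[10] = 1.0
        res = classify_modality(Spectrum(mz=mz, intensity=inten))
        assert res.label == "bimodal"

    def test_invariant_to_intensity_scaling(self):
        sp = simulate_envelope(10, [(0.1, 0.4), (0.7, 0.6)], base_mz=1000.0)
        scaled = Spectrum(mz=sp.mz, intensity=sp.intensity * 1e6, charge=sp.charge)
        a, b = classify_modality(sp), classify_modality(scaled)
        assert a.label == b.label
        assert np.allclose(a.components, b.components, atol=1e-4)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            classify_modality(Spectrum(mz=np.array([1.0, 2.0]), intensity=np.array([1.0, 1.0])))

    def test_benchmark_misclassification_below_5_percent(self):
        """Seeded benchmark of well-separated (|p1-p2| >= 0.4) spectra with
        multiplicative intensity noise: < 5% wrong modality calls."""
        rng = np.random.default_rng(99)
        n_spectra, errors = 200, 0
        for i in range(n_spectra):
            n_sites = int(rng.integers(8, 16))
            if i % 2 == 0:
                p = rng.uniform(0.1, 0.9)
                sp = simulate_envelope(n_sites, [(p, 1.0)], base_mz=1000.0)
                truth = "unimodal"
            else:
                p1 = rng.uniform(0.05, 0.3)
                p2 = p1 + rng.uniform(0.4, 0.6)
                w = rng.uniform(0.25, 0.75)
                sp = simulate_envelope(n_sites, [(p1, w), (p2, 1 - w)], base_mz=1000.0)
                truth = "bimodal"
            noisy = Spectrum(mz=sp.mz,
                             intensity=sp.intensity * rng.lognormal(0, 0.02, sp.mz.size),
                             charge=sp.charge)
            if classify_modality(noisy).label != truth:
                errors += 1
        assert errors / n_spectra < 0.05
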