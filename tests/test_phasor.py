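"""Phasor analysis: universal-circle geometry, transform fidelity, clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import heflim as hf
from heflim.exceptions import CalibrationError, InvalidParameterError
from heflim.phasor import (
    OMEGA_76MHZ,
    calibrate,
    cluster_phasor,
    phasor_point,
    phasor_to_lifetime,
    phasor_transform,
    segment_image,
    single_exp_phasor,
)
from heflim.synth import default_region_specs, uniform_layout

TAU_OMEGA_ONE_PS = 1e12 / OMEGA_76MHZ  # lifetime with omega*tau = 1, ~2094.4 ps


class TestUniversalCircle:
    def test_zero_lifetime_maps_to_one_zero(self):
        assert single_exp_phasor(0.0) == pytest.approx((1.0, 0.0))

    def test_omega_tau_one_maps_to_half_half(self):
        g, s = single_exp_phasor(TAU_OMEGA_ONE_PS)
        assert (g, s) == pytest.approx((0.5, 0.5), abs=1e-12)

    @pytest.mark.parametrize("tau", np.linspace(0.0, 1e4, 21).tolist())
    def test_points_lie_exactly_on_semicircle(self, tau):
        g, s = single_exp_phasor(tau)
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-12)
        assert s >= 0

    def test_long_lifetime_limit_approaches_origin(self):
        g, s = single_exp_phasor(1e9)  # ~1 ms >> laser period
        assert abs(g) < 1e-6 and s < 1e-2

    def test_negative_tau_rejected(self):
        with pytest.raises(InvalidParameterError):
            single_exp_phasor(-1.0)


class TestDiscreteTransform:
    def test_delta_decay_at_t0_gives_one_zero(self):
        # all counts in a first bin centered at t=0
        counts = np.zeros(256)
        counts[0] = 1000
        decay = hf.DecayHistogram(counts, bin_width=51.4, t0_offset=-25.7)
        g, s = phasor_point(decay)
        assert (g, s) == pytest.approx((1.0, 0.0), abs=1e-9)

    def test_flat_decay_long_window_near_origin(self):
        # flat I(t) is the window->infinity limit of tau = infinity
        counts = np.ones(4096)
        bw = (1e12 / 76e6) / 4096  # one full period, finely binned
        g, s = phasor_point(hf.DecayHistogram(counts, bin_width=bw))
        assert abs(g) < 1e-9 and abs(s) < 1e-9

    @pytest.mark.parametrize("tau", [200.0, 500.0, 1000.0])
    def test_fine_binned_matches_closed_form_within_1e3(self, tau):
        # window >= 10*tau, fine bins: discrete sum tracks the integral
        n_bins = 2048
        window = max(10.0 * tau, 1.2e4)
        bw = min(window / n_bins, (1e12 / 76e6) / n_bins)
        t = (np.arange(n_bins) + 0.5) * bw
        counts = np.exp(-t / tau)
        g, s = phasor_point(hf.DecayHistogram(counts, bin_width=bw))
        g0, s0 = single_exp_phasor(tau)
        assert g == pytest.approx(g0, abs=1e-3)
        assert s == pytest.approx(s0, abs=1e-3)

    def test_intensity_invariance_machine_precision(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(100, 256).astype(float)
        d1 = hf.DecayHistogram(counts, 51.4)
        d2 = hf.DecayHistogram(counts * 1234.5, 51.4)
        assert phasor_point(d1) == pytest.approx(phasor_point(d2), abs=1e-14)

    def test_cube_transform_masks_zero_pixels(self, default_specs):
        acq = hf.AcquisitionConfig(image_size=(4, 4))
        layout = uniform_layout((4, 4), "background")
        cube = hf.simulate_cube(layout, default_specs, acq, seed=1)
        pmap = phasor_transform(cube)
        assert not pmap.mask.any()


class TestChordRule:
    def test_mixture_phasor_on_chord_at_intensity_weights(self):
        # mixture phasor = intensity-fraction-weighted sum of component
        # phasors with f_i = a_i tau_i / sum a_j tau_j; needs a window that
        # captures the full decay and bins fine enough that the discrete
        # per-component intensities converge to a_i tau_i
        bw = 1.0  # ps
        n_bins = 60000
        t = (np.arange(n_bins) + 0.5) * bw
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(20):
            tau1, tau2 = sorted(rng.uniform(500, 3000, 2))
            a1 = rng.uniform(0.1, 0.9)
            a2 = 1 - a1
            counts = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
            g, s = phasor_point(hf.DecayHistogram(counts, bw))
            # intensity fractions f_i = a_i tau_i / sum_j a_j tau_j
            f1 = a1 * tau1 / (a1 * tau1 + a2 * tau2)
            gd, sd = phasor_point(hf.DecayHistogram(np.exp(-t / tau1), bw))
            ge, se = phasor_point(hf.DecayHistogram(np.exp(-t / tau2), bw))
            gc, sc = f1 * gd + (1 - f1) * ge, f1 * sd + (1 - f1) * se
            worst = max(worst, abs(g - gc), abs(s - sc))
        assert worst < 1e-6

    def test_mixtures_fall_inside_circle(self):
        n_bins = 8192
        bw = (1e12 / 76e6) / n_bins
        t = (np.arange(n_bins) + 0.5) * bw
        counts = 0.5 * np.exp(-t / 500.0) + 0.5 * np.exp(-t / 3000.0)
        g, s = phasor_point(hf.DecayHistogram(counts, bw))
        assert (g - 0.5) ** 2 + s**2 < 0.25


class TestPhasorToLifetime:
    def test_half_half_inverts_to_omega_tau_one(self):
        tp, tm = phasor_to_lifetime(0.5, 0.5)
        assert tp == pytest.approx(TAU_OMEGA_ONE_PS, rel=1e-9)
        assert tm == pytest.approx(TAU_OMEGA_ONE_PS, rel=1e-9)

    @pytest.mark.parametrize("tau", [300.0, 1000.0, 2500.0, 5000.0])
    def test_on_circle_phase_equals_modulation(self, tau):
        g, s = single_exp_phasor(tau)
        tp, tm = phasor_to_lifetime(g, s)
        assert tp == pytest.approx(tau, rel=1e-9)
        assert tm == pytest.approx(tau, rel=1e-9)

    def test_inside_circle_phase_below_modulation(self):
        # two-component mixtures land inside: tau_phase < tau_mod
        rng = np.random.default_rng(11)
        for _ in range(30):
            t1, t2 = sorted(rng.uniform(100, 5000, 2))
            if t2 - t1 < 100:
                continue
            f = rng.uniform(0.2, 0.8)
            g1, s1 = single_exp_phasor(t1)
            g2, s2 = single_exp_phasor(t2)
            g, s = f * g1 + (1 - f) * g2, f * s1 + (1 - f) * s2
            tp, tm = phasor_to_lifetime(g, s)
            assert tp < tm

    def test_nonpositive_g_rejected(self):
        with pytest.raises(InvalidParameterError):
            phasor_to_lifetime(0.0, 0.3)


class TestCalibration:
    def test_reference_at_theory_point_is_identity(self, default_specs):
        acq = hf.AcquisitionConfig(image_size=(2, 2))
        layout = uniform_layout((2, 2), "cancerous")
        cube = hf.simulate_cube(layout, default_specs, acq, seed=2)
        pmap = phasor_transform(cube)
        ref = single_exp_phasor(1500.0)
        out = calibrate(pmap, ref, 1500.0)
        np.testing.assert_allclose(out.G, pmap.G, atol=1e-12)
        assert out.calibrated

    def test_self_calibration_puts_monoexp_on_circle(self):
        # coarse binning biases the discrete phasor off the circle;
        # calibrating against the known lifetime removes the bias
        tau = 1800.0
        acq = hf.AcquisitionConfig(n_bins=64, image_size=(4, 4))
        mix = (hf.FluorophoreComponent(tau, 1.0),)
        mean = hf.expected_decay(mix, acq, 1e7)
        decay = hf.DecayHistogram(np.round(mean).astype(int), acq.bin_width)
        g, s = phasor_point(decay)
        pmap = hf.PhasorMap(
            G=np.array([[g]]), S=np.array([[s]]), harmonic=1,
            angular_frequency=OMEGA_76MHZ, mask=np.ones((1, 1), bool),
        )
        out = calibrate(pmap, (g, s), tau)
        g0, s0 = single_exp_phasor(tau)
        assert out.G[0, 0] == pytest.approx(g0, abs=1e-3)
        assert out.S[0, 0] == pytest.approx(s0, abs=1e-3)
        dist = (out.G[0, 0] - 0.5) ** 2 + out.S[0, 0] ** 2
        assert dist == pytest.approx(0.25, abs=1e-3)

    def test_zero_modulus_reference_rejected(self):
        pmap = hf.PhasorMap(
            G=np.zeros((1, 1)), S=np.zeros((1, 1)), harmonic=1,
            angular_frequency=OMEGA_76MHZ, mask=np.ones((1, 1), bool),
        )
        with pytest.raises(CalibrationError):
            calibrate(pmap, (0.0, 0.0), 1000.0)


def _three_mixture_cube(shape=(30, 30), photons=20000, seed=31):
    """Three vertical bands of well-separated lifetimes; returns cube+labels."""
    acq = hf.AcquisitionConfig(image_size=shape)
    taus = (400.0, 1500.0, 3500.0)
    labels = np.zeros(shape, dtype=int)
    counts = np.zeros((acq.n_bins, *shape), dtype=np.int64)
    third = shape[1] // 3
    for band, tau in enumerate(taus):
        cols = slice(band * third, shape[1] if band == 2 else (band + 1) * third)
        labels[:, cols] = band
        mix = (hf.FluorophoreComponent(tau, 1.0),)
        mean = hf.expected_decay(mix, acq, photons)
        rng = np.random.default_rng(seed + band)
        block = rng.poisson(mean, size=(shape[0], labels[:, cols].shape[1], acq.n_bins))
        counts[:, :, cols] = np.moveaxis(block, 2, 0)
    return hf.TCSPCCube(counts=counts, config=acq), labels


class TestClustering:
    def test_k1_single_cluster_covers_mask(self, default_specs):
        acq = hf.AcquisitionConfig(image_size=(6, 6))
        cube = hf.simulate_cube(
            uniform_layout((6, 6), "peritumoral"), default_specs, acq, seed=3
        )
        pmap = phasor_transform(cube)
        out = cluster_phasor(pmap, k=1, seed=0)
        assert (out.labels[pmap.mask] == 0).all()

    def test_three_mixture_recovery_ari(self):
        cube, labels = _three_mixture_cube()
        pmap = phasor_transform(cube)
        out = cluster_phasor(pmap, k=3, seed=5)
        ari = adjusted_rand_score(labels.ravel(), out.labels.ravel())
        assert ari >= 0.95

    def test_cluster_mean_lifetimes_descending(self):
        cube, _ = _three_mixture_cube(seed=41)
        pmap = phasor_transform(cube)
        out = cluster_phasor(pmap, k=3, seed=5)
        tau = out.cluster_mean_tau_m
        assert np.all(np.diff(tau) <= 0)

    def test_k_exceeding_pixels_rejected(self, default_specs):
        acq = hf.AcquisitionConfig(image_size=(2, 2))
        cube = hf.simulate_cube(
            uniform_layout((2, 2), "cancerous"), default_specs, acq, seed=4
        )
        pmap = phasor_transform(cube)
        with pytest.raises(InvalidParameterError):
            cluster_phasor(pmap, k=10, seed=0)


class TestSegmentation:
    def test_segmentation_matches_layout_up_to_permutation(self):
        cube, labels = _three_mixture_cube(seed=51)
        pmap = phasor_transform(cube)
        out = cluster_phasor(pmap, k=3, seed=5)
        rgb = segment_image(out)
        # each ground-truth band is dominated by a single color
        colors = set()
        for band in range(3):
            vals, counts = np.unique(
                rgb[labels == band].reshape(-1, 3), axis=0, return_counts=True
            )
            dom = tuple(vals[counts.argmax()])
            assert counts.max() / counts.sum() > 0.95
            colors.add(dom)
        assert len(colors) == 3  # color count equals k

    def test_masked_pixels_render_black(self):
        labels = np.full((3, 3), -1)
        labels[1, 1] = 0
        assignment = hf.ClusterAssignment(
            labels=labels, cluster_centers=np.array([[0.5, 0.3]]),
            cluster_mean_tau_m=np.array([1000.0]), k=1,
        )
        rgb = segment_image(assignment)
        assert (rgb[0, 0] == 0).all() and (rgb[1, 1] != 0).any()
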