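"""FLIM analysis: binning, phasors, line fits, lifetimes, LLIF, decay fits."""

import numpy as np
import pytest

from fluorograde.flim import (
    BiExpFit,
    FLIMImage,
    PhasorLine,
    accept_fit,
    analyze_flim_cohort,
    bin_flim_image,
    components_from_line,
    correct_sampling_bias,
    decay_to_phasor,
    fit_biexponential,
    fit_phasor_line,
    flim_phasor_histogram,
    intersect_universal_circle,
    lifetime_from_point,
    llif_project,
    phasor_cloud,
)
from fluorograde.presets import FlimChannel, TissueType
from fluorograde.spectral_phasor import PhasorPoint
from fluorograde.synthetic import DEFAULT_L, DEFAULT_TS_NS, simulate_flim_image

OMEGA = 2 * np.pi / (DEFAULT_L * DEFAULT_TS_NS)  # = 2 pi / 12.5 ns


def _decay(tau, L=DEFAULT_L, Ts=DEFAULT_TS_NS, total=1.0):
    t = np.arange(L) * Ts
    d = np.exp(-t / tau)
    return d / d.sum() * total


def _mixture(f, tau_short, tau_long, total=1.0, **kw):
    return f * _decay(tau_long, total=total, **kw) + (1 - f) * _decay(
        tau_short, total=total, **kw)


class TestBinning:
    def test_512_to_16_superpixels(self):
        img = FLIMImage(np.ones((512, 512, 8)), DEFAULT_TS_NS, "FAD")
        binned = bin_flim_image(img, 32)
        assert binned.shape == (16, 16)
        assert np.all(binned.decays == 1024)

    def test_factor_one_is_identity(self):
        img = FLIMImage(np.arange(2 * 2 * 8).reshape(2, 2, 8), 0.1, "NADH")
        assert bin_flim_image(img, 1) is img

    def test_photon_conservation(self, presets):
        img = simulate_flim_image(presets[TissueType.CONTROL], "NADH", (64, 64),
                                  photons_per_pixel=1e3, seed=1)
        binned = bin_flim_image(img, 32)
        assert binned.decays.sum() == img.decays.sum()

    def test_non_divisible_shape_rejected(self):
        img = FLIMImage(np.ones((10, 10, 8)), 0.1, "FAD")
        with pytest.raises(ValueError, match="not divisible"):
            bin_flim_image(img, 32)


class TestPhasorTransform:
    def test_omega_value(self):
        img = FLIMImage(np.ones((1, 1, DEFAULT_L)), DEFAULT_TS_NS, "FAD")
        assert img.omega == pytest.approx(2 * np.pi / 12.5)
        assert img.omega == pytest.approx(0.50265, abs=5e-5)

    def test_unit_omega_tau_lands_at_half_half(self):
        """Continuous limit: a mono-exponential with omega*tau = 1 sits at
        (0.5, 0.5), the top of the universal circle."""
        L, Ts = 16384, 0.01
        tau = L * Ts / (2 * np.pi)
        p = correct_sampling_bias(decay_to_phasor(_decay(tau, L, Ts), Ts), L)
        assert p.g == pytest.approx(0.5, abs=1e-4)
        assert p.s == pytest.approx(0.5, abs=1e-4)

    def test_corrected_mono_exponentials_on_circle(self):
        for tau in (0.4, 0.55, 1.2, 2.1, 2.5):
            p = correct_sampling_bias(
                decay_to_phasor(_decay(tau), DEFAULT_TS_NS), DEFAULT_L)
            assert abs((p.g - 0.5) ** 2 + p.s ** 2 - 0.25) < 1e-12
            assert lifetime_from_point(p, OMEGA) == pytest.approx(tau, rel=2e-3)

    def test_mixture_phasor_is_weighted_average(self):
        f = 0.5
        pm = decay_to_phasor(_mixture(f, 0.55, 2.1), DEFAULT_TS_NS)
        pl = decay_to_phasor(_decay(2.1), DEFAULT_TS_NS)
        ps = decay_to_phasor(_decay(0.55), DEFAULT_TS_NS)
        assert pm.g == pytest.approx(f * pl.g + (1 - f) * ps.g, abs=1e-12)
        assert pm.s == pytest.approx(f * pl.s + (1 - f) * ps.s, abs=1e-12)

    def test_invalid_decays_rejected(self):
        with pytest.raises(ValueError, match="photons"):
            decay_to_phasor(np.zeros(64), 0.1)
        with pytest.raises(ValueError, match="does not match"):
            decay_to_phasor(np.ones(64), 0.1, L=128)


class TestLineAndCircle:
    def _components(self, tau_short=0.55, tau_long=2.1):
        phasors = [
            correct_sampling_bias(
                decay_to_phasor(_mixture(f, tau_short, tau_long), DEFAULT_TS_NS),
                DEFAULT_L)
            for f in np.linspace(0.1, 0.9, 33)
        ]
        histo = flim_phasor_histogram(phasors)
        line = fit_phasor_line(histo)
        return components_from_line(line, OMEGA)

    def test_control_fad_lifetimes_recovered_within_1pc(self):
        comp = self._components()
        assert comp.tau_short == pytest.approx(0.55, rel=0.01)
        assert comp.tau_long == pytest.approx(2.1, rel=0.01)

    def test_intersections_satisfy_circle_equation(self):
        inter = self._components().intersections
        for p in (inter.short, inter.long):
            assert abs((p.g - 0.5) ** 2 + p.s ** 2 - 0.25) < 1e-9

    def test_tangent_line_flagged(self):
        line = PhasorLine(point=(0.0, 0.5), direction=(1.0, 0.0))
        inter = intersect_universal_circle(line)
        assert inter.tangent
        assert inter.short.g == pytest.approx(0.5)
        assert inter.short.s == pytest.approx(0.5)
        tau = lifetime_from_point(inter.short, OMEGA)
        assert tau == pytest.approx(1 / OMEGA, rel=1e-9)

    def test_missing_intersection_rejected(self):
        line = PhasorLine(point=(0.0, 0.9), direction=(1.0, 0.0))
        with pytest.raises(ValueError, match="does not intersect"):
            intersect_universal_circle(line)

    def test_single_occupied_bin_rejected(self):
        phasors = [PhasorPoint(0.5, 0.3)] * 10
        from fluorograde.flim import FLIMPhasor
        histo = flim_phasor_histogram([FLIMPhasor(0.5, 0.3, 1.0)] * 10)
        with pytest.raises(ValueError, match="no line defined"):
            fit_phasor_line(histo)

    def test_line_order_invariance(self):
        a = correct_sampling_bias(decay_to_phasor(_decay(0.55), DEFAULT_TS_NS), DEFAULT_L)
        b = correct_sampling_bias(decay_to_phasor(_decay(2.1), DEFAULT_TS_NS), DEFAULT_L)
        l1 = fit_phasor_line(flim_phasor_histogram([a, b]))
        l2 = fit_phasor_line(flim_phasor_histogram([b, a]))
        assert l1.slope == pytest.approx(l2.slope)
        assert l1.intercept == pytest.approx(l2.intercept)


class TestLLIF:
    def _comp(self):
        phasors = [
            correct_sampling_bias(
                decay_to_phasor(_mixture(f, 0.55, 2.1), DEFAULT_TS_NS), DEFAULT_L)
            for f in np.linspace(0.1, 0.9, 17)
        ]
        return components_from_line(
            fit_phasor_line(flim_phasor_histogram(phasors)), OMEGA)

    def test_endpoints_and_midpoint(self):
        comp = self._comp()
        inter = comp.intersections
        long_pt = inter.long
        mid = PhasorPoint(0.5 * (inter.short.g + inter.long.g),
                          0.5 * (inter.short.s + inter.long.s))
        from fluorograde.flim import FLIMPhasor
        h = llif_project([FLIMPhasor(long_pt.g, long_pt.s, 1.0),
                          FLIMPhasor(mid.g, mid.s, 1.0)], comp)
        assert h.values[0] == pytest.approx(1.0, abs=1e-9)
        assert h.values[1] == pytest.approx(0.5, abs=1e-9)

    def test_noiseless_mixture_fraction_recovered(self):
        """Against the exact chord through the pure-component phasors the
        projection reproduces the intensity fraction to machine precision."""
        ps = correct_sampling_bias(decay_to_phasor(_decay(0.55), DEFAULT_TS_NS),
                                   DEFAULT_L)
        pl = correct_sampling_bias(decay_to_phasor(_decay(2.1), DEFAULT_TS_NS),
                                   DEFAULT_L)
        d = np.array([pl.g - ps.g, pl.s - ps.s])
        line = PhasorLine(point=(ps.g, ps.s),
                          direction=tuple(d / np.linalg.norm(d)))
        comp = components_from_line(line, OMEGA)
        for f in np.arange(0.1, 0.95, 0.1):
            p = correct_sampling_bias(
                decay_to_phasor(_mixture(f, 0.55, 2.1), DEFAULT_TS_NS), DEFAULT_L)
            h = llif_project([p], comp)
            assert h.values[0] == pytest.approx(f, abs=1e-6)

    def test_fitted_line_fraction_within_histogram_resolution(self):
        """With the histogram-fitted chord the recovery is within 0.02."""
        comp = self._comp()
        for f in np.arange(0.1, 0.95, 0.1):
            p = correct_sampling_bias(
                decay_to_phasor(_mixture(f, 0.55, 2.1), DEFAULT_TS_NS), DEFAULT_L)
            h = llif_project([p], comp)
            assert h.values[0] == pytest.approx(f, abs=0.02)

    def test_tangent_components_rejected(self):
        comp = self._comp()
        inter = intersect_universal_circle(
            PhasorLine(point=(0.0, 0.5), direction=(1.0, 0.0)))
        comp.intersections = inter
        from fluorograde.flim import FLIMPhasor
        with pytest.raises(ValueError, match="coincident"):
            llif_project([FLIMPhasor(0.5, 0.5, 1.0)], comp)


class TestBiexponential:
    def test_noiseless_single_exponential(self):
        fit = fit_biexponential(_decay(1.5, total=1e6), DEFAULT_TS_NS)
        # either both lifetimes collapse to tau or the second amplitude is ~0
        dominant = fit.tau1 if fit.a1 >= fit.a2 else fit.tau2
        assert dominant == pytest.approx(1.5, rel=1e-3)

    def test_poisson_recovery_and_acceptance(self, presets):
        img = simulate_flim_image(presets[TissueType.CONTROL], "FAD", (1, 1),
                                  photons_per_pixel=1e6, seed=3, llif=0.5)
        fit = fit_biexponential(img.decays[0, 0], img.ts)
        assert fit.accepted
        assert fit.tau1 == pytest.approx(0.55, rel=0.05)
        assert fit.tau2 == pytest.approx(2.1, rel=0.05)

    def test_acceptance_rate_at_1e6_photons(self, presets):
        """Correctly specified Poisson decays pass the goodness gate >= 90%."""
        img = simulate_flim_image(presets[TissueType.CONTROL], "NADH", (5, 6),
                                  photons_per_pixel=1e6, seed=17)
        n_acc = sum(fit_biexponential(img.decays[iy, ix], img.ts).accepted
                    for iy in range(5) for ix in range(6))
        assert n_acc >= 27  # 90% of 30

    def test_out_of_window_chi2_rejected(self):
        fit = BiExpFit(1, 1, 0.5, 2.0, 0, chi2_reduced=1.5,
                       max_abs_weighted_residual=1.0, accepted=False)
        assert not accept_fit(fit)
        fit.chi2_reduced = 1.0
        assert accept_fit(fit)
        fit.max_abs_weighted_residual = 5.0
        assert not accept_fit(fit)

    def test_photon_floor(self):
        with pytest.raises(ValueError, match="photons"):
            fit_biexponential(_decay(1.0, total=10), DEFAULT_TS_NS)


class TestCohortAnalysis:
    def test_per_grade_llif_means_ordered(self, presets):
        """LLIF distributions shift to higher values with tumor grade."""
        images = {
            tt: [simulate_flim_image(presets[tt], "NADH", (12, 12),
                                     photons_per_pixel=1e5, seed=20 + i)
                 for i in range(2)]
            for tt in TissueType
        }
        _, llifs = analyze_flim_cohort(images, "NADH")
        means = [llifs[tt].mean() for tt in
                 (TissueType.CONTROL, TissueType.GRADE1, TissueType.GRADE2)]
        assert means[0] < means[1] < means[2]

    def test_mosaic_equals_tiles(self, presets):
        """A 3x3 mosaic pools to the same phasor set as its 9 tiles."""
        tiles = [simulate_flim_image(presets[TissueType.GRADE1], "FAD", (4, 4),
                                     photons_per_pixel=1e4, seed=40 + i)
                 for i in range(9)]
        mosaic = np.zeros((12, 12, tiles[0].L))
        for i, t in enumerate(tiles):
            iy, ix = divmod(i, 3)
            mosaic[4 * iy:4 * iy + 4, 4 * ix:4 * ix + 4] = t.decays
        mosaic_img = FLIMImage(mosaic, tiles[0].ts, "FAD")
        ph_tiles = [p for t in tiles for p in phasor_cloud(t)]
        ph_mosaic = phasor_cloud(mosaic_img)
        h1 = flim_phasor_histogram(ph_tiles)
        h2 = flim_phasor_histogram(ph_mosaic)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    @pytest.mark.parametrize("channel", list(FlimChannel))
    @pytest.mark.parametrize("tt", list(TissueType))
    def test_lifetime_recovery_within_3pc(self, presets, channel, tt):
        """Phasor line + circle intersection recovers the generating
        lifetimes within 3% for every grade and both channels."""
        img = simulate_flim_image(presets[tt], channel, (16, 16),
                                  photons_per_pixel=1e5, seed=7,
                                  llif=(0.2, 0.8))
        comps, _ = analyze_flim_cohort({tt: [img]}, channel)
        ts, tl = presets[tt].flim_lifetimes[channel]
        assert comps.tau_short == pytest.approx(ts, rel=0.03)
        assert comps.tau_long == pytest.approx(tl, rel=0.03)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="no images"):
            analyze_flim_cohort({}, "NADH")

    def test_phasors_inside_universal_circle(self, presets):
        img = simulate_flim_image(presets[TissueType.CONTROL], "FAD", (8, 8),
                                  photons_per_pixel=1e5, seed=2)
        for p in phasor_cloud(img):
            # 3 sigma of shot-noise scatter at 1e5 photons
            assert (p.g - 0.5) ** 2 + p.s ** 2 <= 0.25 + 0.01
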