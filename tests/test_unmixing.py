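"""Constrained Gaussian unmixing: bank, fits, ratios, features, EEM."""

import math

import numpy as np
import pytest

from fluorograde.presets import TissueType
from fluorograde.spectra import (
    EmissionSpectrum,
    binned_gaussian_band,
    duv_axis,
)
from fluorograde.synthetic import noiseless_spectrum, simulate_emission_spectrum
from fluorograde.unmixing import (
    SpectrumFit,
    build_eem,
    collagen_features,
    default_bank,
    duv_ratios,
    fit_spectrum,
    nir_ratios,
    normalize_spectrum,
)


class TestBank:
    def test_tryptophan_window(self):
        e = default_bank().lookup("tryptophan", 275.0)
        assert e.center_window == (335, 345)
        assert e.bandwidth_window == (0, 10)

    def test_shg_only_at_890(self):
        bank = default_bank()
        assert bank.lookup("shg", 890.0) is not None
        assert bank.lookup("shg", 810.0) is None

    def test_nadh_bound_only_at_810(self):
        bank = default_bank()
        assert bank.lookup("nadh_bound", 810.0) is not None
        assert bank.lookup("nadh_bound", 890.0) is None

    def test_excitation_filter(self):
        names = {e.name for e in default_bank().for_excitation(275.0)}
        assert names == {"tyrosine", "tryptophan", "collagen", "nadh"}


class TestNormalize:
    def test_constant_spectrum(self):
        s = EmissionSpectrum(duv_axis(), np.full(duv_axis().size, 5.0), 275.0)
        assert normalize_spectrum(s).intensities.max() == 1.0
        assert normalize_spectrum(s).intensities.min() == 1.0

    def test_idempotent_and_argmax_preserving(self, presets):
        s = noiseless_spectrum(presets[TissueType.GRADE1], 275.0)
        n1 = normalize_spectrum(s)
        n2 = normalize_spectrum(n1)
        np.testing.assert_allclose(n1.intensities, n2.intensities)
        assert np.argmax(n1.intensities) == np.argmax(s.intensities)

    def test_zero_spectrum_rejected(self):
        s = EmissionSpectrum(duv_axis(), np.zeros(duv_axis().size), 275.0)
        with pytest.raises(ValueError, match="all-zero"):
            normalize_spectrum(s)


def _duv_mixture(components):
    """Build a noiseless DUV spectrum from (name, center, fwhm, amp) tuples
    and return it with the numerically integrated per-component areas."""
    wl = duv_axis()
    total = np.zeros_like(wl)
    areas = {}
    for name, c, b, a in components:
        curve = binned_gaussian_band(wl, 1.0, c, b, a)
        total += curve
        areas[name] = curve.sum() * 1.0
    return EmissionSpectrum(wl, total, 275.0), areas


class TestFitSpectrum:
    def test_single_component_is_everything(self):
        spec, _ = _duv_mixture([("tryptophan", 340, 10, 1.0)])
        fit = fit_spectrum(spec, n_restarts=2)
        assert fit.success
        assert fit.proportion("tryptophan") > 99.0
        for other in ("tyrosine", "collagen", "nadh"):
            assert fit.proportion(other) < 1.0

    def test_known_area_round_trip(self):
        """Noiseless four-component mixture: proportions recovered within one
        point of the numeric-integration ground truth, centers within 1 nm."""
        comps = [("tryptophan", 340, 10, 1.0),
                 ("collagen", 400, 45, 0.48),
                 ("tyrosine", 306, 40, 0.30),
                 ("nadh", 430, 55, 0.06)]
        spec, areas = _duv_mixture(comps)
        truth = {n: 100 * a / sum(areas.values()) for n, a in areas.items()}
        fit = fit_spectrum(spec, n_restarts=3)
        assert fit.success
        for name, c, b, a in comps:
            assert abs(fit.proportion(name) - truth[name]) < 1.0
            fitted = next(x for x in fit.components if x.name == name)
            assert abs(fitted.center - c) <= 1.0
        assert abs(sum(fit.integral_proportions.values()) - 100.0) < 0.1

    @pytest.mark.parametrize("exc", [275.0, 810.0, 890.0])
    @pytest.mark.parametrize("tt", list(TissueType))
    def test_preset_round_trip_and_sum(self, preset_fits, presets, tt, exc):
        """Every preset/excitation fit reproduces its generating proportions."""
        from fluorograde.synthetic import component_area
        fit = preset_fits[(tt, exc)]
        assert fit.success
        assert abs(sum(fit.integral_proportions.values()) - 100.0) < 0.1
        p = presets[tt]
        areas = {n: component_area(p, exc, n) for n in p.amplitudes_for(exc)}
        total = sum(areas.values())
        for name, area in areas.items():
            assert abs(fit.proportion(name) - 100 * area / total) < 1.0

    def test_scale_invariance_of_ratios_and_features(self, presets):
        p = presets[TissueType.GRADE1]
        s = noiseless_spectrum(p, 275.0)
        s890 = noiseless_spectrum(p, 890.0)
        f1, f2 = fit_spectrum(s, n_restarts=1), fit_spectrum(s.scaled(7.3), n_restarts=1)
        g1, g2 = fit_spectrum(s890, n_restarts=1), fit_spectrum(s890.scaled(0.2), n_restarts=1)
        r1, r2 = duv_ratios(f1), duv_ratios(f2)
        assert r1.tryp_coll == pytest.approx(r2.tryp_coll, rel=1e-3)
        c1 = collagen_features(f1, g1).as_array()
        c2 = collagen_features(f2, g2).as_array()
        np.testing.assert_allclose(c1, c2, rtol=1e-3)

    def test_residual_decreases_with_noise(self, presets):
        """Statistically, lower counting noise means lower fit residual."""
        p = presets[TissueType.CONTROL]
        def mean_resid(noise):
            out = []
            for seed in range(20):
                s = simulate_emission_spectrum(p, 275.0, noise, seed=seed)
                out.append(fit_spectrum(s, n_restarts=0).residual_norm)
            return np.mean(out)
        assert mean_resid(0.002) < mean_resid(0.05)


class TestRatios:
    def test_duv_arithmetic(self):
        fit = SpectrumFit([], 0.0, {"tryptophan": 60, "collagen": 20,
                                    "tyrosine": 60, "nadh": 5}, 275.0)
        r = duv_ratios(fit)
        assert r.tryp_coll == pytest.approx(3.0)
        assert r.tryp_tyr == pytest.approx(1.0)
        assert r.tryp_nadh == pytest.approx(12.0)

    def test_zero_denominator_flags_nan(self):
        fit = SpectrumFit([], 0.0, {"tryptophan": 60, "collagen": 0,
                                    "tyrosine": 30, "nadh": 10}, 275.0)
        r = duv_ratios(fit)
        assert math.isnan(r.tryp_coll) and not r.defined("tryp_coll")
        assert r.defined("tryp_tyr")

    def test_nir_arithmetic(self):
        fit = SpectrumFit([], 0.0, {"fad": 25, "nadh_free": 50, "nadh_bound": 25,
                                    "porphyrins_i": 10, "porphyrins_ii": 10,
                                    "lipopigments": 40}, 810.0)
        r = nir_ratios(fit)
        assert r.redox == pytest.approx(0.25)
        assert r.pn == pytest.approx(20 / 75)
        assert r.lp == pytest.approx(2.0)
        r_cap = nir_ratios(fit, lp_caption_variant=True)
        assert r_cap.lp == pytest.approx(20 / 60)

    def test_pn_arithmetic_equal_porphyrins(self):
        fit = SpectrumFit([], 0.0, {"fad": 0, "nadh_free": 30, "nadh_bound": 10,
                                    "porphyrins_i": 10, "porphyrins_ii": 10,
                                    "lipopigments": 0}, 810.0)
        assert nir_ratios(fit).pn == pytest.approx(0.5)

    def test_wrong_excitation_rejected(self):
        fit = SpectrumFit([], 0.0, {}, 890.0)
        with pytest.raises(ValueError):
            duv_ratios(fit)
        with pytest.raises(ValueError):
            nir_ratios(fit)

    def test_grade_trends(self, preset_fits):
        tryp_coll = {tt: duv_ratios(preset_fits[(tt, 275.0)]).tryp_coll
                     for tt in TissueType}
        assert (tryp_coll[TissueType.CONTROL] > tryp_coll[TissueType.GRADE1]
                > tryp_coll[TissueType.GRADE2])
        pn = {tt: nir_ratios(preset_fits[(tt, 810.0)]).pn for tt in TissueType}
        assert pn[TissueType.CONTROL] > pn[TissueType.GRADE2]


class TestCollagenFeatures:
    def test_features_increase_with_grade(self, preset_fits):
        feats = {tt: collagen_features(preset_fits[(tt, 275.0)],
                                       preset_fits[(tt, 890.0)]).as_array()
                 for tt in TissueType}
        order = (TissueType.CONTROL, TissueType.GRADE1, TissueType.GRADE2)
        for axis in range(3):
            vals = [feats[tt][axis] for tt in order]
            assert vals[0] < vals[1] < vals[2]

    def test_zero_collagen_gives_zero_features(self, presets):
        from fluorograde.presets import make_tissue_preset
        p = make_tissue_preset("control")
        p.duv_amplitudes = {**p.duv_amplitudes, "collagen": 0.0}
        fd = fit_spectrum(noiseless_spectrum(p, 275.0), n_restarts=1)
        f890 = fit_spectrum(noiseless_spectrum(p, 890.0), n_restarts=1)
        feats = collagen_features(fd, f890)
        assert feats.coll_int < 0.5
        assert feats.coll_peak < 1.0

    def test_requires_both_fits(self, preset_fits):
        fd = preset_fits[(TissueType.CONTROL, 275.0)]
        with pytest.raises(ValueError):
            collagen_features(fd, None)
        with pytest.raises(ValueError, match="275 nm and.*890"):
            collagen_features(fd, preset_fits[(TissueType.CONTROL, 810.0)])


class TestBuildEEM:
    def test_single_spectrum(self, presets):
        s = noiseless_spectrum(presets[TissueType.CONTROL], 275.0)
        eem = build_eem([(275.0, s)])
        assert eem.matrix.shape[0] == 1
        np.testing.assert_allclose(eem.matrix[0], s.intensities)

    def test_eight_rows_sorted_and_order_invariant(self, presets):
        from fluorograde.synthetic import simulate_eem
        excs = np.arange(270.0, 341.0, 10.0)
        full = simulate_eem(presets[TissueType.CONTROL], excs)
        pairs = [(e, full.row(e)) for e in excs]
        eem_fwd = build_eem(pairs)
        eem_rev = build_eem(pairs[::-1])
        assert eem_fwd.matrix.shape[0] == 8
        np.testing.assert_array_equal(eem_fwd.matrix, eem_rev.matrix)
        assert np.all(np.diff(eem_fwd.excitations) > 0)

    def test_mismatched_axes_rejected(self, presets):
        s = noiseless_spectrum(presets[TissueType.CONTROL], 275.0)
        other = EmissionSpectrum(s.wavelengths[:-1], s.intensities[:-1], 280.0)
        with pytest.raises(ValueError, match="emission axis"):
            build_eem([(275.0, s), (280.0, other)])
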