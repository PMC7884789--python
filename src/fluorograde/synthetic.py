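"""Synthetic spectra, hyperspectral cubes, FLIM decay cubes and cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes: emission spectra are sums of fluorophore Gaussian bands, detection
is photon counting (Poisson noise, no read noise), TCSPC decays are
bi-exponential mixtures, and the per-grade trends (collagen / SHG rising
with grade, lipopigments and porphyrins falling, NADH rising) are encoded
in the tissue presets.

All randomness is driven by explicit integer seeds; identical arguments and
seed produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flim import FLIMImage
from .presets import (
    DUV_EXCITATION_PROFILES,
    GENERATION_BANDS,
    FlimChannel,
    TissuePreset,
    TissueType,
    make_tissue_preset,
)
from .spectra import (
    EEM,
    EmissionSpectrum,
    SpectralImage,
    binned_gaussian_band,
    channel_width_of,
    emission_axis,
)

#: default TCSPC timing: 256 bins over a 12.5 ns window (80 MHz excitation)
DEFAULT_L = 256
DEFAULT_TS_NS = 12.5 / 256


def _component_curve(preset: TissuePreset, excitation: float, name: str,
                     wavelengths: np.ndarray) -> np.ndarray:
    center, fwhm = GENERATION_BANDS[name]
    amp = preset.amplitudes_for(excitation).get(name, 0.0)
    return binned_gaussian_band(wavelengths, channel_width_of(wavelengths),
                                center, fwhm, amp)


def component_area(preset: TissuePreset, excitation: float, name: str) -> float:
    """On-axis integral of one fluorophore band (channel sum x width)."""
    wl = emission_axis(excitation)
    w = channel_width_of(wl)
    return float(_component_curve(preset, excitation, name, wl).sum() * w)


def noiseless_spectrum(preset: TissuePreset, excitation: float) -> EmissionSpectrum:
    """Sum of the preset's Gaussian bands on the axis for ``excitation``."""
    wl = emission_axis(excitation)
    total = np.zeros_like(wl)
    for name in preset.amplitudes_for(excitation):
        total += _component_curve(preset, excitation, name, wl)
    return EmissionSpectrum(wl, total, excitation)


def simulate_emission_spectrum(
    preset: TissuePreset,
    excitation: float,
    noise_scale: float = 0.0,
    seed: int = 0,
) -> EmissionSpectrum:
    """Simulate one emission spectrum at a supported excitation wavelength.

    ``noise_scale`` controls Poisson-like counting noise: each channel is
    drawn as ``noise_scale * Poisson(I / noise_scale)``, so the variance at
    intensity I is ``noise_scale * I`` and ``noise_scale = 0`` returns the
    exact noiseless mixture.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    spec = noiseless_spectrum(preset, excitation)
    if noise_scale == 0:
        return spec
    rng = np.random.default_rng(seed)
    noisy = noise_scale * rng.poisson(spec.intensities / noise_scale).astype(float)
    return EmissionSpectrum(spec.wavelengths, noisy, excitation)


def simulate_spectral_image(
    preset: TissuePreset,
    excitation: float,
    shape: tuple[int, int],
    photons_per_pixel: float,
    seed: int = 0,
) -> SpectralImage:
    """Simulate a hyperspectral cube with independent Poisson pixels.

    The preset spectrum is scaled so its channel sum equals
    ``photons_per_pixel``; every pixel is an independent Poisson draw around
    that expectation.
    """
    ny, nx = int(shape[0]), int(shape[1])
    if ny <= 0 or nx <= 0:
        raise ValueError("image shape must be positive")
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be > 0")
    spec = noiseless_spectrum(preset, excitation)
    expected = spec.intensities / spec.intensities.sum() * photons_per_pixel
    rng = np.random.default_rng(seed)
    cube = rng.poisson(np.broadcast_to(expected, (ny, nx, expected.size)))
    return SpectralImage(cube.astype(np.int64), spec.wavelengths, excitation)


def _beta_params(mean: float, spread: float) -> tuple[float, float]:
    """Beta(a, b) shape parameters from a mean and standard deviation."""
    var = min(spread, 0.99 * np.sqrt(mean * (1 - mean))) ** 2
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _draw_fractions(rng: np.random.Generator, n: int, preset: TissuePreset,
                    channel: FlimChannel,
                    llif) -> np.ndarray:
    """Per-pixel long-lifetime intensity fractions.

    ``llif`` may be None (preset beta distribution), a float (fixed
    fraction) or a (low, high) pair (uniform draw).
    """
    if llif is None:
        mean, spread = preset.llif_distribution[channel]
        a, b = _beta_params(mean, spread)
        return rng.beta(a, b, size=n)
    if np.isscalar(llif):
        return np.full(n, float(llif))
    lo, hi = llif
    return rng.uniform(lo, hi, size=n)


def simulate_flim_image(
    preset: TissuePreset,
    channel: FlimChannel | str,
    shape: tuple[int, int],
    L: int = DEFAULT_L,
    Ts: float = DEFAULT_TS_NS,
    photons_per_pixel: float = 1e5,
    seed: int = 0,
    llif=None,
    poisson_noise: bool = True,
    irf_fwhm: float | None = None,
) -> FLIMImage:
    """Simulate a FLIM decay cube for one detection channel.

    Each pixel decay is a two-component exponential mixture sampled on
    ``t = 0, Ts, ..., (L-1) Ts``.  The components are normalised to unit
    area before mixing, so the per-pixel mixing weight is the fraction of
    *emitted intensity* carried by the long-lifetime component — exactly
    the quantity the LLIF analysis reads back.  With ``poisson_noise``
    photon counts are Poisson draws around the expectation; otherwise the
    expectation itself is returned (floating point).

    ``llif`` overrides the preset's per-pixel fraction distribution (see
    :func:`_draw_fractions`).  ``irf_fwhm`` optionally convolves each decay
    with a Gaussian instrument response of the given FWHM (ns).
    """
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be > 0")
    if L < 64:
        raise ValueError("decay length L must be >= 64")
    if Ts <= 0:
        raise ValueError("sampling period Ts must be positive")
    channel = FlimChannel(channel)
    ny, nx = int(shape[0]), int(shape[1])
    tau_short, tau_long = preset.flim_lifetimes[channel]
    t = np.arange(L) * Ts
    comp_long = np.exp(-t / tau_long)
    comp_long /= comp_long.sum()
    comp_short = np.exp(-t / tau_short)
    comp_short /= comp_short.sum()
    if irf_fwhm is not None:
        comp_long = _convolve_irf(comp_long, Ts, irf_fwhm)
        comp_short = _convolve_irf(comp_short, Ts, irf_fwhm)

    rng = np.random.default_rng(seed)
    f = _draw_fractions(rng, ny * nx, preset, channel, llif)
    expected = photons_per_pixel * (
        f[:, None] * comp_long[None, :] + (1.0 - f)[:, None] * comp_short[None, :]
    )
    if poisson_noise:
        decays = rng.poisson(expected).astype(np.int64)
    else:
        decays = expected
    return FLIMImage(decays.reshape(ny, nx, L), Ts, channel)


def _convolve_irf(kernel_decay: np.ndarray, Ts: float, irf_fwhm: float) -> np.ndarray:
    """Convolve a unit-area decay with a Gaussian IRF centred at t=0."""
    sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / Ts
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    out = np.convolve(kernel_decay, g)[: kernel_decay.size + half][half:]
    return out / out.sum() * kernel_decay.sum()


def simulate_eem(preset: TissuePreset, excitations) -> EEM:
    """Assemble a deep-UV excitation-emission matrix for one preset.

    Each fluorophore's amplitude is modulated by its Gaussian excitation-
    efficiency profile, evaluated relative to 275 nm so that the 275 nm row
    (if requested) equals :func:`simulate_emission_spectrum` at 275 nm.
    """
    excitations = np.asarray(list(excitations), dtype=float)
    if excitations.size == 0:
        raise ValueError("excitation list must not be empty")
    if np.any((excitations < 270) | (excitations > 340)):
        raise ValueError("EEM excitations must lie within 270-340 nm")
    wl = emission_axis(275.0)
    rows = np.zeros((excitations.size, wl.size))
    for i, exc in enumerate(np.sort(excitations)):
        for name, amp in preset.duv_amplitudes.items():
            peak, sigma = DUV_EXCITATION_PROFILES[name]
            eff = np.exp(-0.5 * ((exc - peak) / sigma) ** 2) / np.exp(
                -0.5 * ((275.0 - peak) / sigma) ** 2
            )
            center, fwhm = GENERATION_BANDS[name]
            rows[i] += binned_gaussian_band(wl, channel_width_of(wl),
                                            center, fwhm, amp * eff)
    return EEM(np.sort(excitations), wl, rows)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class TissueSample:
    """One labelled synthetic sample of a cohort."""

    label: TissueType
    #: (SHG-Int %, Coll-Peak %, Coll-Int %) drawn around the preset targets
    feature_point: tuple[float, float, float]
    spectra: dict[float, EmissionSpectrum] | None = None
    spectral_images: dict[float, SpectralImage] | None = None
    flim_images: dict[FlimChannel, FLIMImage] | None = None


@dataclass
class Cohort:
    samples: list[TissueSample]
    seed: int

    def labels(self) -> list[TissueType]:
        return [s.label for s in self.samples]

    def feature_points(self) -> np.ndarray:
        return np.asarray([s.feature_point for s in self.samples])


def _separated_targets(separation: float) -> dict[TissueType, np.ndarray]:
    """Per-type feature targets, optionally shrunk toward the grand mean.

    ``separation = 1`` reproduces the preset targets; smaller values pull
    the class means together, degrading class separation.
    """
    targets = {tt: np.asarray(make_tissue_preset(tt).feature_targets)
               for tt in TissueType}
    center = np.mean(list(targets.values()), axis=0)
    return {tt: center + separation * (t - center) for tt, t in targets.items()}


def _sample_preset_for_features(base: TissuePreset,
                                features: np.ndarray) -> TissuePreset:
    """Per-sample preset whose collagen / SHG amplitudes match ``features``.

    Solving the closed-form area fractions keeps the drawn feature point and
    the sample's simulated spectra mutually consistent.
    """
    shg_frac = min(features[0] / 100.0, 0.95)
    coll_frac = min(features[2] / 100.0, 0.95)

    duv = dict(base.duv_amplitudes)
    rest = sum(component_area(base, 275.0, n) for n in duv if n != "collagen")
    unit = TissuePreset(base.tissue_type, {**duv, "collagen": 1.0},
                        dict(base.nir810_amplitudes), dict(base.nir890_amplitudes),
                        dict(base.flim_lifetimes), dict(base.llif_distribution),
                        base.feature_targets, base.feature_spread)
    unit_coll = component_area(unit, 275.0, "collagen")
    duv["collagen"] = coll_frac * rest / ((1 - coll_frac) * unit_coll)

    nir890 = dict(base.nir890_amplitudes)
    rest890 = sum(component_area(base, 890.0, n) for n in nir890 if n != "shg")
    unit890 = TissuePreset(base.tissue_type, dict(base.duv_amplitudes),
                           dict(base.nir810_amplitudes), {**nir890, "shg": 1.0},
                           dict(base.flim_lifetimes), dict(base.llif_distribution),
                           base.feature_targets, base.feature_spread)
    unit_shg = component_area(unit890, 890.0, "shg")
    nir890["shg"] = shg_frac * rest890 / ((1 - shg_frac) * unit_shg)

    return TissuePreset(
        tissue_type=base.tissue_type,
        duv_amplitudes=duv,
        nir810_amplitudes=dict(base.nir810_amplitudes),
        nir890_amplitudes=nir890,
        flim_lifetimes=dict(base.flim_lifetimes),
        llif_distribution=dict(base.llif_distribution),
        feature_targets=tuple(features),
        feature_spread=base.feature_spread,
    )


def simulate_cohort(
    n_control: int,
    n_g1: int,
    n_g2: int,
    seed: int = 0,
    include_images: bool = False,
    separation: float = 1.0,
    image_shape: tuple[int, int] = (8, 8),
    flim_shape: tuple[int, int] = (16, 16),
    photons_per_pixel: float = 1e5,
) -> Cohort:
    """Generate a labelled cohort of synthetic tissue samples.

    Every sample carries a label and a collagen feature point drawn from a
    Gaussian around its type's target with the preset spread (clipped to
    non-negative values).  With ``include_images`` each sample additionally
    carries a deep-UV mean spectrum, 810 / 890 nm spectral cubes and NADH /
    FAD FLIM cubes generated from a per-sample preset consistent with the
    drawn feature point.
    """
    counts = {TissueType.CONTROL: n_control, TissueType.GRADE1: n_g1,
              TissueType.GRADE2: n_g2}
    if any(c < 0 for c in counts.values()):
        raise ValueError("sample counts must be >= 0")
    if sum(counts.values()) == 0:
        raise ValueError("cohort must contain at least one sample")

    rng = np.random.default_rng(seed)
    targets = _separated_targets(separation)
    samples: list[TissueSample] = []
    for tt in TissueType:
        base = make_tissue_preset(tt)
        spread = np.asarray(base.feature_spread)
        for _ in range(counts[tt]):
            features = np.clip(rng.normal(targets[tt], spread), 0.0, None)
            sample = TissueSample(label=tt, feature_point=tuple(features))
            if include_images:
                sp = _sample_preset_for_features(base, features)
                sub = rng.integers(0, 2**31 - 1, size=5)
                sample.spectra = {
                    275.0: simulate_emission_spectrum(sp, 275.0, 0.002, int(sub[0]))
                }
                sample.spectral_images = {
                    810.0: simulate_spectral_image(sp, 810.0, image_shape,
                                                   photons_per_pixel, int(sub[1])),
                    890.0: simulate_spectral_image(sp, 890.0, image_shape,
                                                   photons_per_pixel, int(sub[2])),
                }
                sample.flim_images = {
                    FlimChannel.NADH: simulate_flim_image(
                        sp, FlimChannel.NADH, flim_shape,
                        photons_per_pixel=photons_per_pixel, seed=int(sub[3])),
                    FlimChannel.FAD: simulate_flim_image(
                        sp, FlimChannel.FAD, flim_shape,
                        photons_per_pixel=photons_per_pixel, seed=int(sub[4])),
                }
            samples.append(sample)
    return Cohort(samples=samples, seed=seed)
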