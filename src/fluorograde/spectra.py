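"""Shared spectral containers and Gaussian emission primitives.

Emission spectra are represented on fixed wavelength axes:

* deep-UV (275 nm excitation): 300-550 nm at 1 nm steps, covering the
  tyrosine / tryptophan / collagen-crosslink / NADH emission bands;
* near-infrared two-photon (810 / 890 nm excitation): 380-790 nm at
  10 nm steps (42 channels), the detection range of the spectral detector.

Fluorophore emission bands are modelled as Gaussians parameterised by
(center, FWHM, amplitude); "spectral bandwidth" throughout the package
means full width at half maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: conversion between FWHM and Gaussian sigma: FWHM = 2*sqrt(2 ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DUV_EXCITATION = 275.0
NIR_EXCITATIONS = (810.0, 890.0)
SUPPORTED_EXCITATIONS = (275.0, 810.0, 890.0)


def duv_axis() -> np.ndarray:
    """Deep-UV emission axis, 300-550 nm at 1 nm."""
    return np.arange(300.0, 551.0, 1.0)


def nir_axis() -> np.ndarray:
    """NIR emission axis, 380-790 nm at 10 nm (42 channels)."""
    return np.arange(380.0, 791.0, 10.0)


def emission_axis(excitation: float) -> np.ndarray:
    """Return the emission axis used for a given excitation wavelength."""
    if excitation == DUV_EXCITATION:
        return duv_axis()
    if excitation in NIR_EXCITATIONS:
        return nir_axis()
    raise ValueError(
        f"unsupported excitation {excitation} nm; expected one of "
        f"{SUPPORTED_EXCITATIONS}"
    )


def gaussian_band(
    wavelengths: np.ndarray, center: float, fwhm: float, amplitude: float
) -> np.ndarray:
    """Gaussian emission band amplitude*exp(-(l-c)^2 / (2 sigma^2)).

    ``fwhm`` is the full width at half maximum; sigma = fwhm / 2.355.
    """
    sigma = max(float(fwhm), 1e-9) * FWHM_TO_SIGMA
    return amplitude * np.exp(-0.5 * ((wavelengths - center) / sigma) ** 2)


def gaussian_area(fwhm: float, amplitude: float) -> float:
    """Analytic area under a Gaussian band (amplitude * sigma * sqrt(2 pi))."""
    return float(amplitude) * float(fwhm) * FWHM_TO_SIGMA * np.sqrt(2.0 * np.pi)


def binned_gaussian_band(
    wavelengths: np.ndarray,
    channel_width: float,
    center: float,
    fwhm: float,
    amplitude: float,
) -> np.ndarray:
    """Gaussian band integrated over finite detection channels.

    Each channel centred at ``wavelengths[i]`` integrates the band over
    ``[l - w/2, l + w/2]`` and reports the mean intensity in the channel.
    For bands much wider than the channel this coincides with the point
    sample; for narrow bands (SHG under 890 nm excitation is narrower than
    the 10 nm channels) it conserves the emitted energy instead of aliasing
    it away.
    """
    from scipy.special import erf

    sigma = max(float(fwhm), 1e-9) * FWHM_TO_SIGMA
    half = channel_width / 2.0
    lo = (wavelengths - half - center) / (sigma * np.sqrt(2.0))
    hi = (wavelengths + half - center) / (sigma * np.sqrt(2.0))
    mass = 0.5 * (erf(hi) - erf(lo)) * amplitude * sigma * np.sqrt(2.0 * np.pi)
    return mass / channel_width


def channel_width_of(wavelengths: np.ndarray) -> float:
    """Channel width implied by a regularly spaced wavelength axis."""
    steps = np.diff(wavelengths)
    if steps.size == 0:
        raise ValueError("axis needs at least two channels")
    return float(np.median(steps))


@dataclass
class EmissionSpectrum:
    """A fluorescence emission spectrum at one excitation wavelength."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation: float

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelength and intensity axes differ in length")
        if self.wavelengths.ndim != 1:
            raise ValueError("spectrum axes must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def total(self) -> float:
        return float(self.intensities.sum())

    def scaled(self, k: float) -> "EmissionSpectrum":
        return EmissionSpectrum(self.wavelengths, self.intensities * k, self.excitation)


@dataclass
class SpectralImage:
    """Hyperspectral cube (ny, nx, n_wavelengths) at one excitation."""

    cube: np.ndarray
    wavelengths: np.ndarray
    excitation: float

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("spectral cube must be 3-dimensional (ny, nx, nlambda)")
        if self.cube.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"cube has {self.cube.shape[2]} spectral planes but "
                f"{self.wavelengths.size} wavelengths"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[0], self.cube.shape[1]

    def mean_spectrum(self) -> EmissionSpectrum:
        """Pixel-averaged spectrum (the convention used for unmixing images)."""
        return EmissionSpectrum(
            self.wavelengths, self.cube.mean(axis=(0, 1)), self.excitation
        )

    def pixel_spectrum(self, iy: int, ix: int) -> EmissionSpectrum:
        return EmissionSpectrum(self.wavelengths, self.cube[iy, ix], self.excitation)


@dataclass
class EEM:
    """Excitation-emission matrix: one emission spectrum per excitation row."""

    excitations: np.ndarray
    emission_wavelengths: np.ndarray
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.excitations = np.asarray(self.excitations, dtype=float)
        self.emission_wavelengths = np.asarray(self.emission_wavelengths, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.excitations.size, self.emission_wavelengths.size):
            raise ValueError("EEM matrix shape must be (n_excitations, n_emission)")

    def row(self, excitation: float) -> EmissionSpectrum:
        idx = int(np.argmin(np.abs(self.excitations - excitation)))
        if self.excitations[idx] != excitation:
            raise KeyError(f"no EEM row at {excitation} nm")
        return EmissionSpectrum(self.emission_wavelengths, self.matrix[idx], excitation)
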