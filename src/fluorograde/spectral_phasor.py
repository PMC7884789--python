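"""Spectral phasor analysis of hyperspectral emission images.

Each pixel spectrum is mapped to its first-harmonic Fourier coefficient
over the wavelength axis,

    g = sum_i I(l_i) cos(2 pi (l_i - l0) / Lambda) / sum_i I(l_i)
    s = sum_i I(l_i) sin(2 pi (l_i - l0) / Lambda) / sum_i I(l_i)

with l0 the axis start and Lambda the axis span, so every nonnegative
spectrum lands inside the unit circle and the phase angle increases
monotonically with the emission peak wavelength.  A reference grid of
Gaussian fingerprint phasors (peak 380-790 nm by 10 nm, width 20-100 nm by
20 nm) anchors the plot, and the phase angle can be inverted back to a
peak wavelength for narrow-band spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import EmissionSpectrum, SpectralImage, gaussian_band, nir_axis

__all__ = [
    "PhasorPoint",
    "PhasorHistogram",
    "WavelengthGrid",
    "spectral_phasor_transform",
    "phasor_image",
    "aggregate_histograms",
    "build_wavelength_grid",
    "fingerprint_phasor",
    "invert_phase_to_wavelength",
]


@dataclass(frozen=True)
class PhasorPoint:
    g: float
    s: float
    weight: float = 1.0  # total intensity of the contributing spectrum

    @property
    def phase(self) -> float:
        return float(np.mod(np.arctan2(self.s, self.g), 2.0 * np.pi))

    @property
    def modulus(self) -> float:
        return float(np.hypot(self.g, self.s))


@dataclass
class PhasorHistogram:
    """2D histogram of phasor coordinates with binning metadata."""

    counts: np.ndarray
    g_edges: np.ndarray
    s_edges: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (0.5 * (self.g_edges[:-1] + self.g_edges[1:]),
                0.5 * (self.s_edges[:-1] + self.s_edges[1:]))

    def compatible_with(self, other: "PhasorHistogram") -> bool:
        return (self.counts.shape == other.counts.shape
                and np.allclose(self.g_edges, other.g_edges)
                and np.allclose(self.s_edges, other.s_edges))


DEFAULT_BINS = 128


def _axis_params(wavelengths: np.ndarray) -> tuple[float, float]:
    lam0 = float(wavelengths[0])
    span = float(wavelengths[-1] - wavelengths[0])
    if span <= 0:
        raise ValueError("wavelength axis must span a positive range")
    return lam0, span


def spectral_phasor_transform(spectrum: EmissionSpectrum) -> PhasorPoint:
    """First-harmonic spectral phasor of one emission spectrum."""
    intensities = spectrum.intensities
    if np.any(intensities < 0):
        raise ValueError("spectral phasor requires nonnegative intensities")
    total = intensities.sum()
    if total <= 0:
        raise ValueError("cannot transform a zero-sum spectrum")
    lam0, span = _axis_params(spectrum.wavelengths)
    phase = 2.0 * np.pi * (spectrum.wavelengths - lam0) / span
    g = float((intensities * np.cos(phase)).sum() / total)
    s = float((intensities * np.sin(phase)).sum() / total)
    return PhasorPoint(g, s, float(total))


def phasor_image(
    cube: SpectralImage, bins: int = DEFAULT_BINS
) -> tuple[np.ndarray, PhasorHistogram]:
    """Per-pixel phasor map and its 2D histogram for a spectral cube.

    Returns a (ny, nx, 3) array of (g, s, weight) per pixel — NaN where a
    pixel has zero total intensity — and the histogram over all valid
    pixels; the number of excluded zero pixels is recorded in the
    histogram metadata.
    """
    data = cube.cube.astype(float)
    totals = data.sum(axis=2)
    valid = totals > 0
    if not np.any(valid):
        raise ValueError("all pixels are zero; nothing to transform")
    lam0, span = _axis_params(cube.wavelengths)
    phase = 2.0 * np.pi * (cube.wavelengths - lam0) / span
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (data * np.cos(phase)).sum(axis=2) / totals
        s = (data * np.sin(phase)).sum(axis=2) / totals
    pmap = np.stack([g, s, totals], axis=2)
    pmap[~valid] = np.nan

    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts, _, _ = np.histogram2d(g[valid].ravel(), s[valid].ravel(),
                                  bins=(edges, edges))
    histo = PhasorHistogram(
        counts=counts,
        g_edges=edges,
        s_edges=edges,
        metadata={
            "excitation": cube.excitation,
            "harmonic": 1,
            "axis_start_nm": lam0,
            "axis_span_nm": span,
            "n_zero_pixels": int((~valid).sum()),
        },
    )
    return pmap, histo


def aggregate_histograms(histos) -> PhasorHistogram:
    """Sum phasor histograms bin-wise (pooling samples of one tissue type)."""
    histos = list(histos)
    if not histos:
        raise ValueError("need at least one histogram")
    first = histos[0]
    counts = first.counts.copy()
    n_zero = first.metadata.get("n_zero_pixels", 0)
    for h in histos[1:]:
        if not first.compatible_with(h):
            raise ValueError("histogram binning mismatch")
        counts += h.counts
        n_zero += h.metadata.get("n_zero_pixels", 0)
    meta = dict(first.metadata)
    meta["n_zero_pixels"] = n_zero
    return PhasorHistogram(counts, first.g_edges.copy(), first.s_edges.copy(), meta)


@dataclass
class WavelengthGrid:
    """Reference lattice of Gaussian fingerprint phasors on the NIR axis."""

    nodes: list[tuple[float, float, PhasorPoint]]  # (peak nm, width nm, phasor)


def fingerprint_phasor(
    center: float, width: float, wavelengths: np.ndarray | None = None
) -> PhasorPoint:
    """Phasor of a Gaussian reference spectrum (width = FWHM, nm)."""
    wl = nir_axis() if wavelengths is None else np.asarray(wavelengths, float)
    if not wl[0] <= center <= wl[-1]:
        raise ValueError(f"fingerprint center {center} nm outside the axis")
    if width <= 0:
        raise ValueError("fingerprint width must be positive")
    spec = EmissionSpectrum(wl, gaussian_band(wl, center, width, 1.0), 0.0)
    return spectral_phasor_transform(spec)


def build_wavelength_grid(
    peaks: np.ndarray | None = None, widths: np.ndarray | None = None
) -> WavelengthGrid:
    """Grid of fingerprints: peaks 380-790 nm by 10 nm, widths 20-100 by 20."""
    peaks = nir_axis() if peaks is None else np.asarray(peaks, float)
    widths = np.arange(20.0, 101.0, 20.0) if widths is None else np.asarray(widths, float)
    nodes = [(float(p), float(w), fingerprint_phasor(p, w))
             for p in peaks for w in widths]
    return WavelengthGrid(nodes)


def invert_phase_to_wavelength(
    p: PhasorPoint, wavelengths: np.ndarray | None = None
) -> float:
    """Map a phasor's phase angle linearly back to a peak wavelength.

    Exact for symmetric narrow-band spectra fully contained in the axis;
    approximate for wide bands truncated at the axis edges.
    """
    wl = nir_axis() if wavelengths is None else np.asarray(wavelengths, float)
    lam0, span = _axis_params(wl)
    lam = lam0 + p.phase / (2.0 * np.pi) * span
    if lam > wl[-1]:
        raise ValueError("phase angle maps outside the wavelength axis")
    return float(lam)
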