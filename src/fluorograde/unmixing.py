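"""Constrained Gaussian decomposition of tissue autofluorescence spectra.

An emission spectrum is modelled as a sum of fluorophore Gaussian bands,
each constrained to a literature window for its peak wavelength and
spectral bandwidth (FWHM).  The fit yields per-fluorophore *integral
proportions* — the percentage of the total fitted area carried by each
band — from which the molecular ratios (Tryp/Tyr, Tryp/NADH, Tryp/Coll,
redox, PN, LP) and the collagen feature triple (SHG-Int, Coll-Peak,
Coll-Int) are derived.

Bands are evaluated as bin-integrated Gaussians over the detection
channels (see :func:`fluorograde.spectra.binned_gaussian_band`), which is
essential for the SHG line: its bandwidth (<= 5 nm) is narrower than the
10 nm NIR channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spectra import (
    EEM,
    EmissionSpectrum,
    binned_gaussian_band,
    channel_width_of,
)

__all__ = [
    "BankEntry",
    "FluorophoreBank",
    "SpectrumFit",
    "MolecularRatios",
    "CollagenFeatures",
    "default_bank",
    "normalize_spectrum",
    "fit_spectrum",
    "duv_ratios",
    "nir_ratios",
    "collagen_features",
    "build_eem",
]


@dataclass(frozen=True)
class BankEntry:
    """Fitting window for one fluorophore at a set of excitations."""

    name: str
    center_window: tuple[float, float]  # nm
    bandwidth_window: tuple[float, float]  # FWHM, nm
    excitations: frozenset[float]

    def __post_init__(self) -> None:
        if self.center_window[0] > self.center_window[1]:
            raise ValueError(f"empty center window for {self.name}")
        if self.bandwidth_window[0] > self.bandwidth_window[1]:
            raise ValueError(f"empty bandwidth window for {self.name}")


@dataclass
class FluorophoreBank:
    entries: list[BankEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            for exc in e.excitations:
                if (e.name, exc) in seen:
                    raise ValueError(f"duplicate bank entry ({e.name}, {exc})")
                seen.add((e.name, exc))

    def for_excitation(self, excitation: float) -> list[BankEntry]:
        sel = [e for e in self.entries if excitation in e.excitations]
        if not sel:
            raise ValueError(f"bank has no entries at {excitation} nm")
        return sel

    def lookup(self, name: str, excitation: float) -> BankEntry | None:
        for e in self.entries:
            if e.name == name and excitation in e.excitations:
                return e
        return None


def default_bank() -> FluorophoreBank:
    """Fitting windows of the endogenous fluorophores.

    Deep-UV (275 nm): tyrosine, tryptophan, collagen crosslinks and NADH.
    NIR two-photon: SHG (890 nm only, at half the excitation wavelength),
    free NADH, protein-bound NADH (810 nm only — replaced by SHG at
    890 nm), FAD, lipopigments and the two porphyrin bands.
    """
    duv = frozenset({275.0})
    nir = frozenset({810.0, 890.0})
    return FluorophoreBank([
        BankEntry("tyrosine", (301, 311), (0, 50), duv),
        BankEntry("tryptophan", (335, 345), (0, 10), duv),
        BankEntry("collagen", (380, 420), (0, 50), duv),
        BankEntry("nadh", (430, 430), (0, 60), duv),
        BankEntry("shg", (440, 450), (0, 5), frozenset({890.0})),
        BankEntry("nadh_free", (460, 470), (45, 50), nir),
        BankEntry("nadh_bound", (443, 445), (40, 48), frozenset({810.0})),
        BankEntry("fad", (520, 530), (30, 50), nir),
        BankEntry("lipopigments", (570, 600), (0, 180), nir),
        BankEntry("porphyrins_i", (615, 630), (0, 10), nir),
        BankEntry("porphyrins_ii", (675, 690), (0, 10), nir),
    ])


def normalize_spectrum(spectrum: EmissionSpectrum) -> EmissionSpectrum:
    """Scale a spectrum to unit maximum (NFI convention)."""
    peak = spectrum.intensities.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spectrum.scaled(1.0 / peak)


@dataclass
class FittedComponent:
    name: str
    center: float
    bandwidth: float  # FWHM nm
    amplitude: float


@dataclass
class SpectrumFit:
    """Result of a constrained Gaussian decomposition."""

    components: list[FittedComponent]
    residual_norm: float
    integral_proportions: dict[str, float]  # percent of total fitted area
    excitation: float
    success: bool = True
    model: np.ndarray | None = field(default=None, repr=False)
    wavelengths: np.ndarray | None = field(default=None, repr=False)

    def proportion(self, name: str) -> float:
        return self.integral_proportions.get(name, 0.0)


def _clip_bandwidth_window(window: tuple[float, float],
                           channel_width: float) -> tuple[float, float]:
    """Floor degenerate bandwidth windows to avoid singular components.

    The lower edge is raised to half a channel width, but never above 80%
    of the upper edge so that narrow windows (SHG: 0-5 nm on a 10 nm grid)
    stay non-empty.
    """
    lo, hi = window
    hi = max(hi, 0.5)
    lo = max(lo, min(0.5 * channel_width, 0.8 * hi))
    return lo, hi


def fit_spectrum(
    spectrum: EmissionSpectrum,
    bank: FluorophoreBank | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> SpectrumFit:
    """Bounded least-squares decomposition of a spectrum into bank Gaussians.

    Each component has three parameters (center, FWHM, amplitude) bounded
    by its bank windows and amplitude >= 0.  The trust-region solver is
    restarted from the window midpoints plus ``n_restarts`` seeded random
    interior points; the best solution is kept.  A fit that never converges
    is returned with ``success=False`` rather than silently falling back.
    """
    bank = bank or default_bank()
    entries = bank.for_excitation(spectrum.excitation)
    wl = spectrum.wavelengths
    y = spectrum.intensities
    width = channel_width_of(wl)
    ymax = float(y.max())
    if ymax <= 0:
        raise ValueError("cannot fit an all-zero spectrum")

    lbs, ubs = [], []
    for e in entries:
        c_lo, c_hi = e.center_window
        b_lo, b_hi = _clip_bandwidth_window(e.bandwidth_window, width)
        eps = 1e-6  # strictly ordered bounds for degenerate (fixed) windows
        lbs += [c_lo - eps, b_lo - eps, 0.0]
        ubs += [c_hi + eps, b_hi + eps, 10.0 * ymax * max(1.0, width)]
    lb = np.asarray(lbs)
    ub = np.asarray(ubs)

    def model(params: np.ndarray) -> np.ndarray:
        out = np.zeros_like(wl)
        for i in range(len(entries)):
            c, b, a = params[3 * i: 3 * i + 3]
            out += binned_gaussian_band(wl, width, c, b, a)
        return out

    def resid(params: np.ndarray) -> np.ndarray:
        return model(params) - y

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lb + ub)]
    for _ in range(n_restarts):
        starts.append(lb + rng.uniform(0.2, 0.8, size=lb.size) * (ub - lb))

    best = None
    for x0 in starts:
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                xtol=tol, ftol=tol, gtol=tol)
        except Exception:  # noqa: BLE001 - solver failure is a fit failure
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return SpectrumFit([], math.inf, {}, spectrum.excitation, success=False)

    components = []
    areas = {}
    for i, e in enumerate(entries):
        c, b, a = best.x[3 * i: 3 * i + 3]
        components.append(FittedComponent(e.name, float(c), float(b), float(a)))
        areas[e.name] = float(
            binned_gaussian_band(wl, width, c, b, a).sum() * width
        )
    total = sum(areas.values())
    proportions = {n: (100.0 * v / total if total > 0 else 0.0)
                   for n, v in areas.items()}
    return SpectrumFit(
        components=components,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        integral_proportions=proportions,
        excitation=spectrum.excitation,
        success=bool(best.status > 0),
        model=model(best.x),
        wavelengths=wl,
    )


@dataclass
class MolecularRatios:
    """Molecular ratios of integral proportions; undefined ratios are NaN."""

    tryp_tyr: float = math.nan
    tryp_nadh: float = math.nan
    tryp_coll: float = math.nan
    redox: float = math.nan
    pn: float = math.nan
    lp: float = math.nan

    def defined(self, name: str) -> bool:
        return not math.isnan(getattr(self, name))


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def duv_ratios(fit: SpectrumFit) -> MolecularRatios:
    """Tryp/Tyr, Tryp/NADH and Tryp/Coll from a 275 nm fit.

    A zero denominator yields NaN (an undefined-ratio flag), not an error.
    """
    if fit.excitation != 275.0:
        raise ValueError("DUV ratios require a 275 nm fit")
    tryp = fit.proportion("tryptophan")
    return MolecularRatios(
        tryp_tyr=_safe_ratio(tryp, fit.proportion("tyrosine")),
        tryp_nadh=_safe_ratio(tryp, fit.proportion("nadh")),
        tryp_coll=_safe_ratio(tryp, fit.proportion("collagen")),
    )


def nir_ratios(fit: SpectrumFit, lp_caption_variant: bool = False) -> MolecularRatios:
    """Redox, PN and LP ratios from an 810 nm fit.

    redox = FAD / (NADH-free + NADH-bound + FAD);
    PN = (Porph I + Porph II) / (NADH-free + NADH-bound);
    LP = Lipopigments / (Porph I + Porph II), or with
    ``lp_caption_variant`` the alternative
    Porphyrins / (Lipopigments + Porphyrins).
    """
    if fit.excitation != 810.0:
        raise ValueError("NIR ratios require an 810 nm fit")
    nadh = fit.proportion("nadh_free") + fit.proportion("nadh_bound")
    fad = fit.proportion("fad")
    porph = fit.proportion("porphyrins_i") + fit.proportion("porphyrins_ii")
    lipo = fit.proportion("lipopigments")
    if lp_caption_variant:
        lp = _safe_ratio(porph, lipo + porph)
    else:
        lp = _safe_ratio(lipo, porph)
    return MolecularRatios(
        redox=_safe_ratio(fad, nadh + fad),
        pn=_safe_ratio(porph, nadh),
        lp=lp,
    )


@dataclass
class CollagenFeatures:
    """The collagen feature triple used by the 3D discrimination stage."""

    shg_int: float  # % of total 890 nm fitted area
    coll_peak: float  # collagen component peak, % of the normalized maximum
    coll_int: float  # % of total 275 nm fitted area

    def as_array(self) -> np.ndarray:
        return np.asarray([self.shg_int, self.coll_peak, self.coll_int])


def collagen_features(fit_duv: SpectrumFit, fit_nir890: SpectrumFit) -> CollagenFeatures:
    """Combine a 275 nm and an 890 nm fit of one sample into the feature triple.

    Coll-Peak is the fitted collagen component's peak height after the
    spectrum is normalised to unit maximum, expressed in percent.
    """
    if fit_duv is None or fit_nir890 is None:
        raise ValueError("both the 275 nm and the 890 nm fit are required")
    if fit_duv.excitation != 275.0 or fit_nir890.excitation != 890.0:
        raise ValueError("expected fits at 275 nm and 890 nm")
    coll = next((c for c in fit_duv.components if c.name == "collagen"), None)
    if coll is None or fit_duv.model is None:
        raise ValueError("the 275 nm fit lacks a collagen component")
    global_max = float(fit_duv.model.max())
    width = channel_width_of(fit_duv.wavelengths)
    coll_curve = binned_gaussian_band(fit_duv.wavelengths, width, coll.center,
                                      coll.bandwidth, coll.amplitude)
    coll_peak = 100.0 * float(coll_curve.max()) / global_max if global_max > 0 else 0.0
    return CollagenFeatures(
        shg_int=fit_nir890.proportion("shg"),
        coll_peak=coll_peak,
        coll_int=fit_duv.proportion("collagen"),
    )


def build_eem(spectra) -> EEM:
    """Assemble an EEM from (excitation, spectrum) pairs, sorted by excitation."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    spectra.sort(key=lambda p: p[0])
    axis = spectra[0][1].wavelengths
    for _, s in spectra[1:]:
        if s.wavelengths.shape != axis.shape or not np.allclose(s.wavelengths, axis):
            raise ValueError("all spectra must share one emission axis")
    matrix = np.vstack([s.intensities for _, s in spectra])
    return EEM(np.asarray([e for e, _ in spectra], dtype=float), axis, matrix)
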