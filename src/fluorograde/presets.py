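"""Tissue presets: the generating parameters of the synthetic study conditions.

Each preset bundles, for one tissue type (non-tumoral control, grade I or
grade II meningeal tumor), the relative Gaussian band amplitudes of the
endogenous fluorophores under deep-UV (275 nm) and two-photon NIR (810 /
890 nm) excitation, the bi-exponential FLIM lifetimes of the NADH and FAD
detection channels, the distribution of the long-lifetime intensity
fraction (LLIF), and the generating means of the collagen feature triple
(SHG-Int, Coll-Peak, Coll-Int) used by the 3D discrimination stage.

Lifetimes follow the per-grade values established for these tissues:
protein-bound NADH 2.19 / 1.98 / 1.80 ns and FAD component pairs
(0.55, 2.1) / (0.89, 2.5) / (1.2, 2.4) ns for control / grade I / grade II.
Amplitudes are relative weights chosen to reproduce the characteristic
per-grade trends: collagen and SHG contributions rise steeply with grade,
lipopigment and porphyrin emission falls, and NADH rises.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class TissueType(str, enum.Enum):
    CONTROL = "control"
    GRADE1 = "grade1"
    GRADE2 = "grade2"


class FlimChannel(str, enum.Enum):
    """TCSPC detection channels: channel 1 (NADH) and channel 2 (FAD)."""

    NADH = "NADH"
    FAD = "FAD"


#: default (center nm, FWHM nm) of each fluorophore band used for simulation;
#: every pair lies inside the corresponding fitting window of the bank.
GENERATION_BANDS: dict[str, tuple[float, float]] = {
    # deep-UV (275 nm)
    "tyrosine": (306.0, 40.0),
    "tryptophan": (340.0, 10.0),
    "collagen": (400.0, 45.0),
    "nadh": (430.0, 55.0),
    # NIR (810 / 890 nm)
    "shg": (445.0, 5.0),
    "nadh_free": (465.0, 47.0),
    "nadh_bound": (444.0, 44.0),
    "fad": (525.0, 40.0),
    "lipopigments": (585.0, 100.0),
    "porphyrins_i": (622.0, 10.0),
    "porphyrins_ii": (682.0, 10.0),
}

#: Gaussian excitation-efficiency profiles (peak nm, sigma nm) for the
#: deep-UV fluorophores, used to assemble excitation-emission matrices.
#: Profiles are evaluated relative to their value at 275 nm so that the
#: 275 nm EEM row coincides with the plain simulated spectrum.
DUV_EXCITATION_PROFILES: dict[str, tuple[float, float]] = {
    "tyrosine": (274.0, 10.0),
    "tryptophan": (278.0, 12.0),
    "collagen": (275.0, 18.0),
    "nadh": (330.0, 30.0),
}


@dataclass
class TissuePreset:
    """Generating parameters for one tissue type."""

    tissue_type: TissueType
    duv_amplitudes: dict[str, float]
    nir810_amplitudes: dict[str, float]
    nir890_amplitudes: dict[str, float]
    #: channel -> (tau_short ns, tau_long ns)
    flim_lifetimes: dict[FlimChannel, tuple[float, float]]
    #: channel -> (mean, spread) of the long-lifetime intensity fraction
    llif_distribution: dict[FlimChannel, tuple[float, float]]
    #: generating means of (SHG-Int %, Coll-Peak %, Coll-Int %)
    feature_targets: tuple[float, float, float]
    #: per-axis standard deviations of the feature triple across samples
    feature_spread: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        for amps in (self.duv_amplitudes, self.nir810_amplitudes, self.nir890_amplitudes):
            for name, a in amps.items():
                if a < 0:
                    raise ValueError(f"negative amplitude for {name}")
                if name not in GENERATION_BANDS:
                    raise ValueError(f"unknown fluorophore {name!r}")
        for ch, (ts, tl) in self.flim_lifetimes.items():
            if not 0 < ts < tl:
                raise ValueError(f"require 0 < tau_short < tau_long for {ch}")
        for ch, (m, s) in self.llif_distribution.items():
            if not 0 < m < 1:
                raise ValueError(f"LLIF mean must lie in (0, 1) for {ch}")
            if s <= 0:
                raise ValueError(f"LLIF spread must be positive for {ch}")

    def amplitudes_for(self, excitation: float) -> dict[str, float]:
        if excitation == 275.0:
            return dict(self.duv_amplitudes)
        if excitation == 810.0:
            return dict(self.nir810_amplitudes)
        if excitation == 890.0:
            return dict(self.nir890_amplitudes)
        raise ValueError(f"unsupported excitation {excitation} nm")


_PRESETS: dict[TissueType, dict] = {
    TissueType.CONTROL: dict(
        duv_amplitudes={"tyrosine": 0.25, "tryptophan": 1.0, "collagen": 0.10, "nadh": 0.05},
        nir810_amplitudes={
            "nadh_free": 0.30, "nadh_bound": 0.25, "fad": 0.90,
            "lipopigments": 1.00, "porphyrins_i": 0.45, "porphyrins_ii": 0.35,
        },
        nir890_amplitudes={
            "shg": 0.15, "nadh_free": 0.30, "fad": 0.90,
            "lipopigments": 1.00, "porphyrins_i": 0.45, "porphyrins_ii": 0.35,
        },
        flim_lifetimes={FlimChannel.NADH: (0.40, 2.19), FlimChannel.FAD: (0.55, 2.10)},
        llif_distribution={FlimChannel.NADH: (0.30, 0.08), FlimChannel.FAD: (0.30, 0.08)},
        feature_targets=(0.5, 9.7, 19.0),
        feature_spread=(0.3, 2.0, 2.5),
    ),
    TissueType.GRADE1: dict(
        duv_amplitudes={"tyrosine": 0.22, "tryptophan": 1.0, "collagen": 0.45, "nadh": 0.10},
        nir810_amplitudes={
            "nadh_free": 0.55, "nadh_bound": 0.45, "fad": 0.85,
            "lipopigments": 0.55, "porphyrins_i": 0.20, "porphyrins_ii": 0.15,
        },
        nir890_amplitudes={
            "shg": 1.20, "nadh_free": 0.50, "fad": 0.85,
            "lipopigments": 0.50, "porphyrins_i": 0.20, "porphyrins_ii": 0.15,
        },
        flim_lifetimes={FlimChannel.NADH: (0.40, 1.98), FlimChannel.FAD: (0.89, 2.50)},
        llif_distribution={FlimChannel.NADH: (0.50, 0.10), FlimChannel.FAD: (0.50, 0.10)},
        feature_targets=(5.1, 43.6, 48.8),
        feature_spread=(1.2, 4.0, 4.0),
    ),
    TissueType.GRADE2: dict(
        duv_amplitudes={"tyrosine": 0.20, "tryptophan": 1.0, "collagen": 0.85, "nadh": 0.18},
        nir810_amplitudes={
            "nadh_free": 0.90, "nadh_bound": 0.75, "fad": 0.80,
            "lipopigments": 0.30, "porphyrins_i": 0.08, "porphyrins_ii": 0.06,
        },
        nir890_amplitudes={
            "shg": 8.00, "nadh_free": 0.70, "fad": 0.55,
            "lipopigments": 0.25, "porphyrins_i": 0.07, "porphyrins_ii": 0.05,
        },
        flim_lifetimes={FlimChannel.NADH: (0.40, 1.80), FlimChannel.FAD: (1.20, 2.40)},
        llif_distribution={FlimChannel.NADH: (0.80, 0.07), FlimChannel.FAD: (0.80, 0.07)},
        feature_targets=(33.0, 82.4, 60.4),
        feature_spread=(3.0, 4.0, 4.0),
    ),
}


def make_tissue_preset(tissue_type: TissueType | str) -> TissuePreset:
    """Build the default generating preset for one tissue type.

    Raises ``ValueError`` for an unknown tissue type.
    """
    try:
        tt = TissueType(tissue_type)
    except ValueError as exc:
        raise ValueError(f"unknown tissue type {tissue_type!r}") from exc
    return TissuePreset(tissue_type=tt, **_PRESETS[tt])
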