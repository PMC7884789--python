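# fluorograde

Multiscale autofluorescence analysis for discriminating meningioma grades
(WHO grade I / II) from non-tumoral brain tissue, using endogenous
fluorescence only — no exogenous labels.

Meningioma resection quality drives recurrence risk, but no intraoperative
tool gives real-time histopathological feedback at the resection margin.
Tissue autofluorescence carries that information: collagen crosslinks
(deep-UV emission near 410 nm) and fibrillar collagen's second-harmonic
generation (SHG, at exactly half the 890 nm excitation wavelength) rise
steeply with tumor grade, while NADH and FAD binding states — read out
through their fluorescence lifetimes — track the metabolic shift of the
tumor. `fluorograde` implements the complete quantitative analysis chain
for such measurements, together with a synthetic-data generator that
emulates the study conditions so every stage is testable at the desk.

## What it computes

* **Constrained Gaussian unmixing** — an emission spectrum is fitted as a
  sum of fluorophore Gaussian bands (tyrosine, tryptophan, collagen, NADH
  under 275 nm; SHG, free/bound NADH, FAD, lipopigments, porphyrins under
  810/890 nm), each bounded to its literature window for peak wavelength
  and FWHM. The *integral proportion* `X-Int` is the percentage of the
  total fitted area carried by band X.
* **Molecular ratios** — `Tryp/Tyr`, `Tryp/NADH`, `Tryp/Coll`,
  `redox = FAD/(NADH + FAD)`, `PN = Porphyrins/NADH`,
  `LP = Lipopigments/Porphyrins`.
* **Spectral phasors** — each pixel spectrum maps to its first Fourier
  harmonic `(G, S)` over the 380–790 nm axis; histograms per tissue type,
  a reference grid of Gaussian fingerprints, and phase-angle inversion
  back to peak wavelength.
* **FLIM phasors** — TCSPC decays map to `(G, S)` at
  `omega = 2*pi/(L*Ts)`; mono-exponentials lie on the universal circle,
  mixtures on chords. A count-weighted total-least-squares line through
  the pooled phasor histogram intersects the circle at the two component
  lifetimes (`tau = S/(omega*G)`), and projection along the chord gives
  the per-pixel long-lifetime intensity fraction (LLIF).
* **Bi-exponential decay fits** — Poisson-weighted least squares with the
  standard acceptance gate: reduced chi-squared in [0.8, 1.2], weighted
  residuals within ±4.
* **3D ellipsoid discrimination** — per-type Gaussian ellipsoids at 60%
  probability mass over (SHG-Int, Coll-Peak, Coll-Int), with the two
  threshold-gated tests (SHG-Int 2.5 for control-vs-tumor, 22 for grade
  I-vs-II), sensitivity/specificity `Se = TP/(TP+FN)`,
  `Sp = TN/(TN+FP)`, and Monte-Carlo ellipsoid overlap.

## Worked example

```python
import numpy as np
from fluorograde import (
    make_tissue_preset, simulate_emission_spectrum, simulate_flim_image,
    fit_spectrum, collagen_features, analyze_flim_cohort,
)
from fluorograde.presets import FlimChannel, TissueType

# spectra of a grade II preset at both excitations, unmixed
p = make_tissue_preset("grade2")
fit_duv = fit_spectrum(simulate_emission_spectrum(p, 275.0))
fit_890 = fit_spectrum(simulate_emission_spectrum(p, 890.0))
feats = collagen_features(fit_duv, fit_890)
print(f"SHG-Int {feats.shg_int:.1f}  Coll-Peak {feats.coll_peak:.1f}  "
      f"Coll-Int {feats.coll_int:.1f}")

# FLIM phasor lifetimes of the control preset's FAD channel
ctrl = make_tissue_preset("control")
imgs = [simulate_flim_image(ctrl, "FAD", (16, 16), photons_per_pixel=1e6,
                            seed=50 + k, llif=(0.2, 0.8)) for k in range(4)]
comps, _ = analyze_flim_cohort({TissueType.CONTROL: imgs}, FlimChannel.FAD)
print(f"FAD lifetimes: bound {comps.tau_short:.2f} ns, "
      f"free {comps.tau_long:.2f} ns")
```

prints

```
SHG-Int 33.0  Coll-Peak 82.4  Coll-Int 60.4
FAD lifetimes: bound 0.55 ns, free 2.10 ns
```

The grade II feature triple sits far above the tumor thresholds
(SHG-Int > 22, Coll-Int > 28), and the phasor pipeline recovers the
control FAD component lifetimes (0.55 / 2.1 ns) from the simulated
photon-counting decays.

A command-line interface mirrors the library:
`fluorograde simulate | fit-spectra | spectral-phasor | flim |
discriminate | run` (see `fluorograde --help`).

## Layout

```
src/fluorograde/
  presets.py          tissue presets (generating parameters per grade)
  spectra.py          spectral containers, Gaussian band primitives
  synthetic.py        spectra / cubes / decays / cohort generator
  unmixing.py         constrained Gaussian decomposition, ratios, features
  spectral_phasor.py  spectral phasor transform, histograms, grid
  flim.py             FLIM phasors, line fit, lifetimes, LLIF, bi-exp fits
  discrimination.py   ellipsoids, the two tests, Se/Sp, threshold rules
  io.py               TIFF/HDF5/CSV contracts, run configuration
  pipeline.py, cli.py end-to-end run and command-line interface
```

See `docs/methods.md` for the models, parameter choices and limitations.
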