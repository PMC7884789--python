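# Methods

This note records the models implemented in `fluorograde`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Spectral model and unmixing

An emission spectrum is modelled as a sum of fluorophore Gaussian bands
`a * exp(-(l - c)^2 / (2 sigma^2))`, parameterised by center `c` (nm),
FWHM (nm, `sigma = FWHM / (2 sqrt(2 ln 2))`) and amplitude `a >= 0`.
"Spectral bandwidth" is read as FWHM throughout — the conventional meaning
of bandwidth for emission bands.

**Bin-integrated evaluation.** Detection channels have finite width
(1 nm on the deep-UV axis 300–550 nm, 10 nm on the NIR axis 380–790 nm).
Bands are therefore evaluated as the mean of the Gaussian integrated over
each channel, not as point samples. For bands much wider than a channel
the two coincide; for the SHG line (FWHM ≤ 5 nm, narrower than one NIR
channel) point sampling would alias most of the emitted energy away,
whereas bin integration conserves it and spreads it over the one or two
channels bracketing 445 nm — which is also what a real spectral detector
does. Generator and fit model share this evaluation, so noiseless
round-trips are exact.

**Fitting.** Bounded trust-region least squares over
(center, FWHM, amplitude) per component, with bounds equal to the
literature windows of the fluorophore bank; the NADH deep-UV entry has a
fixed 430 nm center (degenerate window widened by 1e-6 for the solver).
Degenerate bandwidth lower bounds are floored at half a channel width,
capped at 80% of the upper bound so narrow windows stay feasible. The
solver restarts from the window midpoints plus 5 seeded random interior
points (tolerances 1e-8) and keeps the lowest cost; a fit that never
converges is returned flagged, never silently replaced. Integral
proportions are per-component areas over the axis (channel sum × width)
as a percentage of the total fitted area, so they sum to 100 exactly.
For image cubes the pixel-averaged spectrum is fitted (mean-spectrum
convention); per-pixel unmixing maps are out of scope.

**Ratios.** The redox ratio is `FAD/(NADHfree + NADHbound + FAD)` — the
standard optical redox convention, with both NADH binding states in the
denominator.
`LP = Lipopigments/(PorphI + PorphII)` is primary; the caption variant
`Porphyrins/(Lipopigments + Porphyrins)` is available via
`lp_caption_variant`. Zero denominators yield NaN flags, not exceptions.

**Coll-Peak** is the fitted collagen component's peak height after the
spectrum is normalised to unit maximum (×100). Normalisation is to the
global maximum; for all spectra considered here the global maximum is the
tryptophan peak, so the two candidate conventions coincide. The printed
thresholds (2.5, 22, 28) are interpreted as percent integral proportion.

## Spectral phasors

First-harmonic transform over the wavelength axis:
`g = sum I(l) cos(2 pi (l - l0)/Lambda) / sum I`, `s` the sine analog,
`l0` the axis start, `Lambda` the axis span. Every nonnegative spectrum
lies inside the unit circle; mixtures combine intensity-weighted. Phase
inversion to peak wavelength is exact for symmetric bands fully inside
the axis and approximate for wide or truncated bands. Histograms use
128×128 bins over [-1, 1]²; the reference grid spans peaks 380–790 nm by
10 nm and widths 20–100 nm by 20 nm (210 nodes).

## FLIM phasors and lifetimes

Decays sampled at period `Ts` (ns) for `L` bins transform at
`omega = 2 pi/(L Ts)`. Defaults are `L = 256`, `Ts = 12.5/256 ns`
(a 12.5 ns window, matching 80 MHz pulsed excitation — typical for
two-photon TCSPC; the acquisition hardware's actual values are
configurable everywhere).

**Sampling-bias correction.** The plain discrete-sum phasor of a sampled
exponential is `p = (1-x)/(1-x e^{i theta})` with `x = exp(-Ts/tau)`,
`theta = 2 pi/L` — a point measurably *inside* the universal circle
(2–5% lifetime bias at the default timing). The similarity transform
`v = cos(theta/2) e^{i theta/2} p` maps that locus exactly onto the
universal circle for every `tau` (derived from the geometric-series
closed form), is linear (so mixture phasors remain intensity-weighted
combinations), and reduces the recovery error to < 0.1%. The lifetime
pipeline applies it by default; `decay_to_phasor` returns the raw sums.

**Line fit and intersections.** The chord is fitted on the pooled phasor
histogram (256×256 bins over [0,1]×[0,0.6]) by count-weighted total least
squares over bins holding ≥ 50% of the maximum bin count — a robust
stand-in for "localise the local maxima", which is under-specified.
Intersections with `(g-1/2)^2 + s^2 = 1/4` solve the quadratic exactly;
tangency is flagged. `tau = s/(omega g)` at each intersection; the point
with larger `g` is the short-lifetime component.

**LLIF.** Pixels project orthogonally onto the chord; LLIF is the
normalised coordinate from the short- toward the long-lifetime
intersection, clipped to [0, 1] — for noiseless mixtures exactly the
fraction of emitted intensity carried by the long-lived component.
Cohort analysis fits the line once on the all-type pooled histogram per
molecule, then computes per-type LLIF histograms (50 bins, unweighted by
default; intensity weighting available) against that shared chord, so
types are directly comparable. Component identities: the long-lived
NADH component is protein-bound; the long-lived FAD component is free.

**Bi-exponential fits.** `A1 exp(-t/tau1) + A2 exp(-t/tau2) + B` by
least squares with Poisson weights `sigma = sqrt(max(counts, 1))`,
three spread starting points, lifetimes ordered on return. Acceptance
requires reduced chi-squared in [0.8, 1.2] and all weighted residuals
within ±4; on correctly specified Poisson simulations at 1e6 photons the
acceptance rate is ≳ 90% (the residual gate alone rejects ~1.6% by
chance at L = 256). ROI decays are summed before fitting.

## 3D ellipsoid discrimination

Per-type ellipsoids use the sample mean and the full sample covariance —
"standard deviation as covariance parameters" is ambiguous, and the
feature clouds are visibly correlated, so off-diagonals are kept (a
diagonal-only option exists). The 60% boundary is the chi-squared
(3 dof) quantile, `Mahalanobis^2 <= 2.9462`, the unique scaling putting
60% of a trivariate Gaussian's mass inside. Membership is
boundary-inclusive. Overlap between ellipsoids is a seeded Monte-Carlo
Jaccard estimate over the joint bounding box.

Decision rules follow the stated wording exactly, including boundary
conventions (tumor requires SHG-Int *strictly* above 2.5; grade I allows
SHG-Int *equal* to 22). Points satisfying neither rule are
*indeterminate*. By default indeterminates are treated as abstentions and
excluded from the Se/Sp denominators: a 60%-mass ellipsoid necessarily
leaves a substantial fraction of its own fitting points outside under
resubstitution, so counting abstentions as errors would bound sensitivity
near the enclosed mass regardless of class separation and would measure
the mass parameter, not the discrimination. The strict alternative
(`indeterminate="error"`) is available and is what the
separation-degradation property tests use. Se/Sp are computed by
resubstitution (ellipsoids fitted on the points they classify), as no
hold-out protocol is defined for cohorts of this size. Per-point (not
per-sample aggregate) classification is used throughout.

## Synthetic-data generator

The generator encodes the study conditions as per-grade presets:

* **Lifetimes** (ns): NADH channel (free, bound) = (0.40, 2.19) control,
  (0.40, 1.98) grade I, (0.40, 1.80) grade II; FAD channel (bound, free)
  = (0.55, 2.10), (0.89, 2.50), (1.20, 2.40). The free-NADH lifetime is
  set to 0.4 ns for every grade — a typical literature value; free NADH
  is not expected to shift with grade.
* **LLIF distributions**: per-pixel fractions are Beta-distributed with
  (mean, sd) = (0.30, 0.08) control, (0.50, 0.10) grade I, (0.80, 0.07)
  grade II for both channels — reproducing the rightward LLIF shift with
  grade.
* **Band amplitudes** are relative weights chosen once to reproduce the
  qualitative per-grade orderings (collagen and SHG rising, lipopigments
  and porphyrins falling, NADH rising, tryptophan dominant in deep-UV);
  absolute intensities and photon budgets are conventions, not
  reproductions. The resulting feature triples — (0.5, 9.7, 19.0)
  control, (5.1, 43.6, 48.8) grade I, (33.0, 82.4, 60.4) grade II —
  straddle the decision thresholds exactly as the per-grade trends
  require, and are frozen as the cohort generator's targets with
  per-axis spreads (0.3, 2.0, 2.5) / (1.2, 4.0, 4.0) / (3.0, 4.0, 4.0).
* **Noise** is Poisson on photon counts everywhere (TCSPC and spectral
  detection are photon counting); there is no read noise. No instrument
  response function is convolved by default; an optional Gaussian IRF of
  configurable FWHM exists. FLIM mixture components are area-normalised
  before mixing so the mixing weight *is* the emitted-intensity fraction
  the LLIF analysis reads back.
* **Cohorts** draw per-sample feature points from Gaussians around the
  targets; when images are requested, each sample's collagen and SHG
  amplitudes are solved in closed form to match its drawn SHG-Int and
  Coll-Int, keeping spectra and feature points mutually consistent. A
  `separation` factor shrinks class-mean differences toward the grand
  mean for sensitivity studies.
* **EEMs** modulate each deep-UV fluorophore by a Gaussian
  excitation-efficiency profile (tryptophan/tyrosine/collagen peaking at
  274–278 nm, NADH at 330 nm), normalised at 275 nm so the 275 nm row
  equals the plain simulated spectrum.

What the generator does **not** emulate: tissue morphology (whorls,
vessels, collagen texture), spatial correlation between pixels, blood
absorption, detector afterpulsing or IRF asymmetry, scattering, and
inter-patient biological variability beyond the stated Gaussian spreads.
Passing tests therefore demonstrate the correctness of the analysis
algorithms under the assumed statistical model — not clinical performance
on real tissue, whose headline sensitivities/specificities depend on
patient data that is not distributable.

## Problem sizes

Tests and the acceptance script run at desk scale: 16×16 (already-binned)
FLIM images at 1e5–1e6 photons per super-pixel, 8×8–32×32 spectral cubes,
1e5-point Monte-Carlo samples, cohorts of 25 samples. These sizes were
chosen so that every recovery tolerance is met with comfortable
statistical margin while the full suite completes in well under a minute.

## Known limitations

* The phasor line fit assumes exactly two lifetime components per
  channel; three-component mixtures bias both intersections.
* Phase-to-wavelength inversion degrades for emission bands wider than
  ~100 nm or truncated by the axis.
* Bi-exponential fits use Neyman (counts-based) weights; at very low
  counts per bin this slightly biases reduced chi-squared downward.
* Ellipsoid Se/Sp are resubstitution estimates and optimistic by
  construction for small cohorts.
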