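# Methods

This note documents the models, defaults and numerical choices behind
`paleoflim`, and what the synthetic generator does and does not emulate.

## TCSPC decay model

Each pixel of a FLIM acquisition is a histogram of photon arrival times
over one laser period.  The model is an amplitude-weighted sum of
exponentials reconvolved with the instrument response function (IRF) plus a
constant background:

    m(t) = [ Σₖ aₖ exp(−t/τₖ) ] ⊛ IRF + b,    K ≤ 3

with `⊛` a circular (periodic) convolution on the bin grid — the steady
state of a pulse train.  The aₖ are pre-exponential amplitudes, so the
photon share of component k is ∝ aₖτₖ; the intensity-weighted average
lifetime is Σaₖτₖ²/Σaₖτₖ.  Truncation to one period is handled by the
circular convolution itself; for the default parameters (τ_max = 6.5 ns,
50 ns period) inter-pulse wrap is < 0.1 %.

**Timing defaults.**  20 MHz pulse rate → 50 ns window, 1024 bins
(≈ 48.8 ps/bin), so the 0.3 ns component spans ~6 bins.  The IRF default is
a Gaussian of 100 ps FWHM centered 2 ns into the window (acquisition
systems rarely publish their IRF; a narrow Gaussian is the standard
surrogate and any measured IRF histogram can be supplied instead).

**Fitting.**  Counts are Poisson, and per-pixel counts are low (the
acquisition regime caps count rates around 2000 cps), so fits minimize the
Poisson deviance (C statistic) rather than Gaussian-weighted χ².  The
optimizer is variable projection: Nelder–Mead over log-lifetimes with
non-negative least-squares amplitudes + background inside, multi-started
from log-spaced lifetimes in [2·bin, period/4] (3 starts), then a joint
L-BFGS-B polish of the exact deviance with analytic gradients.  Components
are always reported sorted ascending in lifetime (ties broken by
amplitude); non-convergence sets a flag rather than raising.  On noiseless
(exact-model) data the fit reproduces the input histogram to better than
10⁻⁶ of peak, which is the cross-module oracle connecting generator and
fitter.

**FastFLIM.**  The average-lifetime map is the mean photon arrival time
minus the IRF centroid — the standard published definition of the rapid
estimate (vendor implementations are proprietary).  Pixels with fewer than
`min_photons` (default 50) counts are undefined and carried as NaN.

**Whole-cube analysis.**  The default mode fits the pooled decay once
(K = 3), then recovers per-pixel amplitudes by non-negative unmixing
against the fixed component templates (a linear-unmixing mode: fast,
stable at ~10³ photons/pixel).  Free per-pixel fitting is available behind
`mode="free"` for small images.  The short-lifetime mask selects defined
pixels whose shortest component (τ₁ ≤ 1 ns by default) carries at least
half the fitted intensity; this isolates the picosecond-lifetime fungal
and conducting-tissue vesicle signal.

**Amplitude patterns and information limits.**  A Cramér–Rao analysis of
the fungal-class decay (a = 0.97/0.02/0.01) at 10⁵ photons shows the weak
middle component's lifetime cannot be recovered with a median error much
below 5 % — an information limit, not an estimator defect (the fitter
measures within ~10 % of the bound).  Recovery tests therefore use the
pooled scene decay, whose component intensities are balanced.

## Raman model and pipeline

**Generator.**  Spectra are sums of height-parametrized Lorentzian bands
(Gaussian and pseudo-Voigt available) on a baseline of a gentle cubic
polynomial plus one broad Gaussian (FWHM 1500 cm⁻¹) emulating
luminescence; noise is Poisson by default.  Band centers move linearly in
excitation photon energy, `center(E) = center₀ + Disp·(E − E_ref)`, with
the 514 nm photon energy (2.412 eV) as anchor.  The default disordered sp²
carbon materials place D/G at 1358/1608 cm⁻¹ with FWHM(G) = 56 cm⁻¹ and a
D/G height ratio of 0.55, subbands at 1266 and 1450 cm⁻¹ (a 1433 cm⁻¹
reading at 514 nm also occurs for such material; the config keeps 1450 and
notes the discrepancy), C-H stretch and 2D′ bands at 2960/3220 cm⁻¹, and
dispersions Disp(D)/Disp(G) of 4.1/8.3 cm⁻¹/eV for the arbuscule material
and 8.2/10.3 for the vesicle material.

**Calibration** is a rigid axis shift pinning the crystalline-Si line to
520.7 cm⁻¹; it is idempotent and rejects measured positions outside
[480, 560] cm⁻¹ (wrong peak).  Line positions are read sub-sample by
parabolic interpolation of the maximum.

**Baseline correction** follows the off-ROI procedure: a reference
spectrum taken away from the structures is scaled by least squares on the
band-free points and subtracted; a polynomial (default order 3) fitted
outside the band windows (± 20 cm⁻¹ pad) removes what remains.  On
noiseless fixtures this perturbs fitted centers by < 0.1 cm⁻¹ and heights
by < 2 %.

**Band fitting** is a simultaneous lmfit least squares of all requested
bands plus a free constant, over the windows sub1266 [1200,1320], D
[1320,1410], sub1450 [1410,1520], G [1560,1660], and in the near-UV range
CH [2900,3050] and 2D′ [3150,3300] (± 60 cm⁻¹ of context).  Overlapping
broad Lorentzians create local minima, so starting values are data-driven:
centers at the in-window maxima and heights from a non-negative unmixing
of unit-height templates; widths are capped at twice the window so no band
can swallow a neighbour.  Centers are hard-constrained to their windows.
Flat spectra return `success=False` with no parameters.

**Derived quantities.**  Dispersion is the OLS slope of position on photon
energy (the two-point case reduces to the closed-form slope exactly);
I(D)/I(G) is the ratio of fitted *heights*, following the amorphous-carbon
convention (recorded in the summary so the area convention is auditable);
Lₐ uses √(idig/C′) with C′(2.41 eV) = 0.0055 Å⁻² in the nanocrystalline
regime and C(514 nm)/idig = 44 Å/idig in the graphitic regime.  The
automatic regime choice uses FWHM(G) ≥ 40 cm⁻¹ as the nanocrystalline
signature.  An optional E⁻⁴ scaling of C′ across excitation energies is
off by default (cluster size is reported at 514 nm).  Band maps fit one
band per grid point (10 µm default step) and record 0 where the fit fails.

## Morphometry

All measurements are 2-D (section plane); no stereological correction for
oblique sectioning is attempted — a documented limitation, as real
sections are rarely perfectly transverse.  Foreground is 8-connected,
background 4-connected.

* **Equivalent diameter** = 2·√(area/π) · pixel size.
* **Wall thickness** (closed annulus): the mean uses the ribbon identity
  thickness = area / medial length, with the medial length the average of
  the inner and outer boundary lengths measured on marching-squares
  contours smoothed circularly (σ = 3 px) — accurate to a fraction of a
  pixel and robust to jagged or block-upsampled boundaries, where
  pixel-counting perimeters overestimate.  The SD comes from sub-pixel
  distance-transform samples along the endpoint-pruned medial-axis loop.
  Masks without an enclosed hole are rejected.
* **Tubular width**: skeletonize, then width = 2 × distance transform at
  skeleton pixels.  The EDT is sampled on a 4× bilinearly upsampled mask
  because the nearest-background distance overshoots the true boundary by
  an orientation-dependent amount (half a pixel for grid-aligned edges,
  near zero for oblique ones); upsampling shrinks this below an eighth of
  a pixel, which is removed as a fixed correction.  Skeleton pixels within
  2× the local width of a branch point are excluded (the EDT inflates at
  junctions).  Blob-like masks (skeleton < 3× median width) are rejected.

All estimator constants were validated against analytic disc, bar and
annulus oracles at several radii and scales.

## Synthetic scenes: what they emulate, what they do not

The default scene (160×160 px at 0.5 µm/px) holds a seeded random branched
tree dilated to hyphal width (a space-filling stand-in for an arbuscule —
only the mask matters), an elongate vesicle ellipse, a plant-tissue disc,
and dim background.  Structures receive 1000 photons/pixel (background
50): acquisition protocols state count-rate caps rather than per-pixel
totals, so the budget folds frame accumulation into one number chosen to
give per-pixel unmixing a realistic ~3 % amplitude noise.  Decay classes:
fungal and vesicle dominated by the 0.3 ns component (amplitude ≥ 0.96),
plant tissue by 6.5 ns (intensity-weighted mean > 6 ns), background by an
intermediate 2.0 ns — the intermediate value is a placeholder, flagged in
the config, as dim-background lifetimes are rarely quantified.

The generator does **not** emulate: chert matrix texture or its
autofluorescence spectrum, optical sectioning/PSF blur, boundary
partial-volume mixing of decays, detector afterpulsing or dead time,
cosmic-ray spikes in spectra, or spatially varying Raman baselines.
Passing tests therefore demonstrate correctness of the estimators under
the stated statistical model (Poisson counting, linear band dispersion,
crisp tissue boundaries), not robustness to every instrument artifact of
real acquisitions.

## Problem sizes and determinism

Analyses run at desk scale: 160×160×1024 cubes (~6×10⁶ photons), pooled
fits thinned to 10⁵ photons where a fixed photon budget is stated, 100
replicates for noisy-recovery medians, and diagnosis fixtures up to
740×740 px.  Every random draw flows from an explicit integer seed through
`numpy.random.SeedSequence`; identical (inputs, seed) pairs are
bit-reproducible, and the pipeline writes a config snapshot beside its
outputs so any run can be replayed.
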