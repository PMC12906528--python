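# Methods

## Scope and model overview

`monovis` simulates the optical-bench evaluation of enhanced-monofocal
intraocular lenses and the derived mini-monovision analysis.  The chain
is: pupil wavefront → PSF → through-focus MTF/PTF → CSF-weighted simVA
defocus curve → binocular combination under a myopic offset → depth-of-
focus summaries, plus a parallel image pathway (USAF targets blurred by
the same PSFs and fused by quadratic summation).

The commercial lens prescriptions this kind of bench measures are
proprietary, so the bench is *synthetic*: the two design families are
stylised stand-ins that reproduce the depth-of-focus **mechanism**, not
any particular lens surface.

- `quantum_like` (central add-power zone): +0.9 D of add power inside a
  1.0-mm zone radius, decreasing linearly to zero over a 0.5-mm
  transition, monofocal beyond; lens Z(4,0) −0.1 μm at 6 mm
  (corneal-SA-correcting); Abbe number 41.
- `emv_like` (SA-amplifying): lens Z(4,0) +0.15 μm at 6 mm, growing by
  0.004 μm per diopter of nominal power above 10 D (spherical
  aberration tends to increase with lens power); no add zone; Abbe
  number 56.
- `neutral_monofocal`: aberration-free reference lens.

All defaults live in `src/monovis/presets.yaml`, never in code, and are
echoed into every pipeline manifest.

## Wavefront model

The pupil optical path difference (μm) is rotationally symmetric and
assembled from:

- **Stimulus defocus**: Zernike `c(2,0) = D R²/(4√3)` (R the pupil
  radius in metres).  Sign convention: the through-focus axis is
  stimulus defocus at the spectacle plane, negative toward near; a
  stimulus `d` (after vergence transfer `d/(1 − v·d)` over the
  `v = 12 mm` vertex distance) contributes `+d·r²/2`, a central add
  power `P(r)` contributes `+∫₀^r P(ρ) ρ dρ`, so a +0.9 D add is best
  corrected near −0.9 D.  The convention is pinned by a translation-
  equivariance test (a constant +0.5 D add moves the through-focus peak
  to −0.5 D).
- **Corneal SA**: Z(4,0) = 0.27 μm specified at 5.15 mm, restricted to
  the working aperture by the analytic concentric-scaling law
  (`c40·ε⁴` plus the induced defocus `√15·c40·ε²(ε²−1)`); scaling
  *beyond* the reference aperture requires an explicit flag.
- **Lens SA**: same law from the design's 6-mm reference.
- **Add-zone phase**: the radial integral above, evaluated on a fine
  1-D grid and interpolated onto the pupil map.

## Fourier optics

The aperture spans half of a 512² embedding grid (2× zero padding).
PSF = |FFT(mask·exp(i2πW/λ))|², normalised to unit sum; the OTF is the
FFT of the PSF, 1 at zero frequency, interpolated as a complex quantity
onto the 1–150 lp/mm reporting grid (image-plane scale from the model
eye's 17.2-mm focal length, ≈ 0.30 mm per degree).  Frequencies beyond
the incoherent cutoff `D/(λf)` are set to MTF = PTF = 0 and flagged.
Imaginary OTF components below 10⁻⁹ of the zero-frequency value are
FFT round-off of a centrosymmetric PSF and are zeroed, so symmetric
systems report PTF exactly 0 or π.  A wavefront whose OPD steps more
than half a wavelength between adjacent samples raises a sampling
error instead of silently aliasing.  Doubling the grid to 1024²
changes reported MTF values by < 0.5% absolute for the presets.

Polychromatic mode (optional; the default is monochromatic 546 nm,
which is what the acuity metric consumes) propagates five wavelengths
480–620 nm, weights the complex OTFs by the photopic luminosity
function, and shifts each wavelength's defocus by the lens's
longitudinal chromatic aberration `−P·(λ−546)/(V·170 nm)` for Abbe
number V.

## Refraction (best focus)

Best focus is the grid defocus maximising MTF at 50 lp/mm (a common
bench criterion; the frequency is configurable), ties broken toward
0 D.  Through-focus data are never re-centred — the best focus is
stored alongside.  For defocus curves and monovision the eye must be
*refracted*: `emmetropic_sweep` first scans a wide ±3 D pilot grid,
then measures the +0.5…−2.5 D reporting grid relative to the located
best focus, emulating an instrument that focuses before sweeping and a
surgeon who targets emmetropia.  This matters: the SA-amplifying design
sits ≈ 1.1 D from the paraxial zero (SA focal shift plus the induced
defocus of the corneal aperture rescale).

## Acuity metric

`wOTF = (1/150) Σ_{f=1}^{150} MTF(f)·cos(PTF(f))·CSF(f)` and
`simVA = wOTF^(−0.36)` (logMAR).  Because a negative power of a
positive number is positive, the metric cannot produce simVA ≤ 0; its
absolute scale is fixed entirely by the CSF amplitude, which multiplies
every logMAR value by a constant factor and cancels out of all
comparative statements (pointwise MTF dominance ⇒ simVA ordering).

The neural CSF is the band-pass form
`CSF(f) = S·(f/fp)^a·exp(a(1 − f/fp))` in cycles/degree with peak
frequency `fp = 6 cpd` and low-frequency exponent `a = 2` — a smooth
stand-in for the classical neural (post-optical) contrast-sensitivity
measurements, with a single interior maximum and strict decline above
the peak.  The amplitude `S` is set by a deterministic convention: the
closed-form diffraction-limited 3-mm system at 546 nm must score
0.04 logMAR at best focus (a realistic just-better-than-20/20 anchor;
values ≤ 0 are unreachable by construction).  The calibration constant
is recomputed on demand and reported in curve provenance and run
manifests.

Monocular values multiply decimal acuity by 0.93 (7% reduction), i.e. a
constant +0.0315 logMAR shift, applied in one dedicated operation; the
alternative readings (reducing MAR or the wOTF itself) would change the
constant but not any curve shape.  Non-positive wOTF (spurious
resolution dominating) raises a warning and the node is recorded as
missing in curves — never clamped or interpolated away.

## Binocular combination

At each defocus node of two monocular-calibrated curves:
ΔVA = |L − R|, avgVA = (L + R)/2, and the summation factor
`BE = 1.17 − 0.24·ΔVA − 0.11·avgVA − 0.07·Offset` multiplies the
better eye's decimal acuity: `logMAR_bin = min(L, R) − log10(BE)`.
Design choices, each isolated in one place:

- **Offset convention**: the regression's Offset enters as a magnitude
  in diopters (larger interocular offsets always reduce summation);
  the signed alternative is available on `BinocularEffectModel`.
- **Application rule**: BE scales the better eye's decimal acuity,
  matching the definition of binocular summation as improvement over
  the better-seeing eye.
- **Missing nodes**: one seeing eye → its value with BE = 1, flagged;
  BE ≤ 0 → node undefined, flagged.  Grids are aligned by linear
  interpolation onto the dominant eye's 0.05-D grid.

The myopic eye's curve is the plano curve shifted: its VA at stimulus
`x` is the plano value at `x + offset`; nodes whose support leaves the
measured window are missing.  Its monocular *distance* VA (the plano
curve at `+offset`) is outside the +0.5 D window for offsets > 0.5 D,
so the pipeline measures it with one extra bench evaluation rather than
extrapolating.

Depth of focus at a cut-off (0.1 / 0.2 logMAR) is the summed width of
the sub-threshold intervals, crossings located by linear interpolation;
nested cut-offs give nested ranges by construction.

## Image pathway

Targets are tri-bar elements (bar frequency `2^(g+(e−1)/6)` lp/mm,
5:1 bar length:width, three bars per orientation), rendered dark (0.0)
on light (1.0) with 4× supersampled edges, deterministic by
construction.  PSFs are resampled to the chart's pixel scale, cropped
to the centred window holding 99.9% of their energy (capped at 129 px;
far diffraction tails carry negligible energy), renormalised to unit
sum, and applied with replicate boundary handling; the default 64-px
background margin keeps the border constant so mean intensity is
conserved to machine precision.  Binocular fusion is per-pixel
`√((a²+b²)/2)` — identical inputs are a fixed point; the un-normalised
`√(a²+b²)` variant is selectable and recorded in image metadata.
Output is 16-bit grayscale PNG/TIFF.

Fine-bar Michelson contrast falls strictly with defocus up to ≈ 1.5 D
on the presets; beyond that, contrast reversal (spurious resolution)
can raise it again, which is physical and left visible.

## Problem sizes and determinism

Defaults: 512² pupil grids, 61-node defocus sweeps (0.05 D step),
150-point frequency grids, 576-px charts at 2 μm/px.  The full default
pipeline (12 design-power-aperture combinations with refraction passes,
curves, four offsets and image panels) runs in well under ten minutes
on one CPU, and everything is deterministic: rerunning a configuration
reproduces bit-identical CSVs, verified in the test suite.  The
spherical-aberration sensitivity analysis in the acceptance tests uses
an extended +2.5…−4.5 D window so that interval widths are not censored
by the reporting window.

## What the synthetic bench does and does not show

The generator reproduces the *structure* of real bench data — through-
focus MTF/PTF of rotationally symmetric designs behind an aberrated
model cornea, aperture dependence, best-focus identification — so
passing tests validate the analysis chain end to end.  It does not
reproduce any particular commercial lens: no measurement noise, no
tilt/decentration, no higher-order or asymmetric aberrations, no
manufacturing tolerances, and the stylised presets' absolute MTF levels
and depth-of-focus widths are therefore not predictions for named
products.  Residual astigmatism, letter-chart psychophysics and
re-estimation of the binocular-effect regression coefficients are out
of scope; the regression is taken as given and applied within the
0–1.0 D offset range it was derived for.
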