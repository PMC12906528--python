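# monovis

Simulation toolkit for **mini-monovision with enhanced-monofocal
intraocular lenses (IOLs)**.  It answers a pre-surgical planning
question: how much binocular depth of focus does a small myopic offset
(0.25–1.0 D) in the non-dominant eye buy, and what does it cost at
distance, for lens designs that already stretch their monocular depth of
focus — either with a central add-power zone or by amplifying the
cornea's positive spherical aberration?

The package chains four stages, each usable on its own:

1. **Synthetic optical bench** (`monovis.bench`) — scalar Fourier optics
   for stylised IOL designs behind a model cornea with 0.27 μm of
   primary spherical aberration Z(4,0) at 5.15 mm.  Pupil wavefronts
   (Zernike defocus + rescaled corneal and lens SA + the radial phase of
   a central add-power profile) are propagated to PSFs, and through-focus
   MTF/PTF curves are reported on the 1–150 lp/mm image-plane grid over
   stimulus defocus +0.50 to −2.5 D at the spectacle plane, at 3-mm and
   4.5-mm apertures.  Externally measured bench CSVs can be ingested
   through the same interface.
2. **Simulated visual acuity** (`monovis.acuity`) — the CSF-weighted
   optical transfer function

   ```
   wOTF = (d/150) Σ_{f=1}^{150/d} MTF(fd) · cos(PTF(fd)) · CSF(fd),   d = 1 lp/mm
   ```

   mapped to logMAR by the power law `simVA = wOTF^b` with `b = −0.36`.
   The neural CSF is a calibrated band-pass weighting; the metric's
   native calibration is binocular, and monocular values apply a 7%
   reduction of decimal acuity (+0.0315 logMAR).
3. **Mini-monovision** (`monovis.monovision`) — the non-dominant eye's
   curve is shifted by the myopic offset and the eyes are combined per
   defocus level with the empirical binocular-summation regression

   ```
   BE = 1.17 − 0.24·ΔVA − 0.11·avgVA − 0.07·Offset
   ```

   applied to the better eye's decimal acuity.  Depth of focus is read
   off at the 0.1 and 0.2 logMAR cut-offs by linear interpolation.
4. **Image synthesis** (`monovis.images`) — USAF-1951-style tri-bar
   targets (bar frequency `2^(group+(element−1)/6)` lp/mm), blurred by
   bench PSFs and fused per pixel by quadratic summation
   `√((a² + b²)/2)` to visualise the binocular impression.

## Worked example

Monocular defocus curve of the central-add-zone preset at 20 D behind
the model cornea, combined binocularly with a 0.5 D myopic offset:

```python
import monovis as mv

cfg = mv.BenchConfig(aperture_diameter_mm=3.0)      # photopic pupil
cornea = mv.ModelCornea()                            # 0.27 um SA at 5.15 mm
design = mv.make_iol_design("quantum_like", 20.0)    # central-add-zone preset

tfd = mv.emmetropic_sweep(design, cornea, cfg)       # through-focus MTF/PTF
csf = mv.default_csf(cfg)                            # calibrated neural CSF
curve = mv.to_monocular(mv.defocus_curve(tfd, csf), mv.AcuityConfig())

plano = mv.combine_binocular(mv.make_scenario(curve, 0.0))
mono = mv.combine_binocular(mv.make_scenario(curve, 0.5))
for key, value in mv.scenario_report(plano, mono).items():
    print(f"{key:>25s}: {value:.3f}")
```

prints

```
  improvement_at_minus_2D: 0.018
     far_distance_penalty: 0.014
          dof_width_0p1_D: 2.658
          dof_width_0p2_D: 3.000
  nondominant_distance_va: 0.080
```

i.e. the 0.5-D offset improves binocular acuity at the −2.0 D stimulus
(50 cm) by 0.018 logMAR, costs 0.014 logMAR at distance, keeps binocular
acuity at 0.1 logMAR or better over 2.66 D of defocus (0.2 logMAR over
the whole measured window), and leaves the myopic eye at 0.080 logMAR
monocularly at distance.

## Command line

The experiment driver reproduces the full comparison grid
(2 designs × 3 powers × 2 apertures × 4 offsets) with CSV, plot and
image artifacts plus a checksummed run manifest:

```sh
monovis all --out runs/default            # full pipeline
monovis bench --config my_config.yaml     # through-focus CSVs only
```

All physical constants (vertex distance, model-eye focal length, CSF
calibration, design presets) live in `src/monovis/presets.yaml` and are
echoed into every run manifest.

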