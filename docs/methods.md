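# Methods

This note documents the physical models, algorithms, and frozen parameter
choices behind `nwloc`. All defaults named here are set in code
(`nwloc.config` mirrors them in the YAML schema) and were calibrated on
pilot simulations before the test suite was frozen.

## 1. Array model

A nanowire array is a square lattice of vertical wires with pitch
`p = 0.99 µm`, wire length `L = 2.5 µm`, and small in-plane placement jitter
(sd 0.02 µm). A fraction of sites (default 15 %) is defective, split evenly
between *missing* wires (empty site) and *kinked* wires (the wire bent
during growth). Kink heights are drawn uniformly on `[0, 0.3·L]`: kinks
originate early in growth, so the straight stem below the kink is short and
the bent top section lies far from the focal plane at the tips.

Molecules are placed by a Poisson process at a chosen surface density.
Wire-bound molecules sit at a uniform axial position on a 50 nm grid along
their wire; substrate-bound molecules lie at `z = 0`. On a kinked wire
(default `kinked_binding="background"`), a molecule's position follows the
bent geometry: below the kink it sits on the stem at the site, above the
kink it sits at the kink height, displaced laterally by the excess arc
length in a random azimuth. Kinked-wire molecules never couple to the
waveguide, so they contribute only defocused, unenhanced background — they
are confounders, not signal. Ground truth for evaluation is the set of
straight wires carrying at least one molecule.

## 2. Image formation

**Optics.** Emission 670 nm, NA 1.2; the in-focus PSF is an isotropic
pixel-integrated Gaussian with `σ = 0.21 λ/NA ≈ 0.117 µm` (≈ 1.08 px at the
0.1083 µm pixel pitch). Out-of-focus emitters are rendered with
`σ(Δz) = σ₀ √(1 + (Δz/z_R)²)`. The effective axial scale is frozen at
`z_R = 1.1 µm`: the physical depth of field `n λ / NA²` is ≈ 0.6–0.7 µm, and
an order-1 µm Gaussian-beam-style scale reproduces the qualitative fact that
substrate emitters 2.5 µm below the tip plane are strongly blurred yet still
occasionally detectable by a localization-only analysis.

**Enhancement.** A wire-coupled molecule's emission is multiplied by a
linear axial enhancement ramp from 2 (base) to 18 (tip), mean 10, and
re-emitted *at the tip*, i.e. rendered in focus at the wire position.
Non-coupled molecules are rendered at their own position with defocus
`Δz = L − z`.

**Photon budget.** Expected photons per molecule are
`base_photon_rate × exposure × enhancement`, with the base rate frozen at
4.5 photons/ms — a design-time calibration chosen so that an unenhanced
in-focus molecule at the 100 ms condition (450 photons over background
12 photons/px) is clearly detectable while defocused substrate emitters are
marginal, which is the regime the pipeline is designed to discriminate.
Photons are drawn Poisson per molecule and distributed over pixels by a
multinomial on the pixel-integrated PSF (exact photon conservation);
background is Poisson at 0.12 photons/px/ms; the camera applies gain 1,
dark offset 100 counts, and Gaussian read noise of 2 counts.

**Bright-field.** The matched bright-field frame shows every standing wire
(straight or kinked) as a Gaussian blob (sd 0.15 µm) with −30 % contrast on
a flat field; missing sites are blank.

## 3. Bright-field-guided fusion

`estimate_lattice` recovers the lattice basis and phase from the
bright-field frame: the two dominant non-DC FFT peaks near the nominal
spacing give the basis (refined by 3×3 centroid), and the phase of the
corresponding DFT tone gives the offset. A confidence score (peak-to-median
spectral contrast, threshold 5) rejects frames without a credible lattice,
in which case the pipeline degrades to localization-only.

`fuse` then suppresses off-lattice fluorescence before detection:

1. The frame is split into a smooth background (Gaussian blur, sd 8 px) and
   a spot-scale residual. The background — diffuse haze from defocused
   emitters — is removed outright; this prevents the later lattice weight
   from carving smooth haze into spot-shaped artifacts at the sites.
2. The residual is low-pass filtered in the Fourier domain (isotropic
   Gaussian, `σ_k = 2.5/(2π σ_psf)`). Deliberately, no lattice-harmonic
   comb is applied: passing only lattice harmonics replicates a fraction of
   every bright spot onto neighboring lattice sites (≈ 0.8 % per site in
   pilots), creating ghost detections precisely where they cannot be told
   from real wires.
3. The filtered residual is multiplied by a real-space lattice-proximity
   weight: 1 within 0.10 µm of a predicted site, Gaussian falloff with sd
   0.05 µm beyond. A global `strength` in [0, 1] (default 0.9) blends
   between identity and the full weight.

Because fusion suppresses off-lattice noise, a threshold estimated from the
fused frame would deflate and admit on-lattice noise peaks. The pipeline
therefore anchors the detection threshold to the noise floor of the *raw*
frame (`estimate_noise_sigma0`, finest à-trous plane, MAD-based).

## 4. Localization

Detection uses the undecimated à-trous B3-spline wavelet transform
(3 levels; exact reconstruction is tested). The pixel-noise sd is estimated
robustly from the finest detail plane and propagated to coarser planes by
precomputed white-noise attenuation factors; each plane is hard-thresholded
at `k·σ` (k = 3) and plane 2 — the diffraction-limited spot scale — is the
detection image. Candidates are strict 8-neighborhood maxima whose local
radial gradient exceeds the robust gradient scale of the detection image;
nearby maxima are merged keeping the brighter.

Each candidate is refined in a 7×7 window by maximum-likelihood fitting of
a pixel-integrated 2-D Gaussian plus constant background under a Poisson
noise model (log-parameterized, L-BFGS-B with analytic gradients).
Uncertainties are CRLB estimates from the Fisher information; fits with
photon significance below 5 (photons / CRLB photons) are rejected, and
near-coincident fits are deduplicated keeping the brighter. The fitted
precision is verified against the CRLB in the test suite.

## 5. Postprocessing

Tips are detected in the bright-field frame (sign-agnostic contrast,
subpixel centroid refinement; ≈ 20 nm accuracy on synthetic frames) and
tessellated by Voronoi cells. Each detection is assigned to its nearest
tip and kept iff its distance is at most `r_max = p/3` — well below the
half-pitch that would make assignment ambiguous, well above localization
error. With `one_per_wire` (default) at most one detection survives per
cell: nearest to the tip, ties broken by brightness, with a deterministic,
order-independent final tie-break. Excluded rows carry a reason
(`far_from_tip`, `duplicate_in_cell`).

## 6. Quantification

For a frame with detections at N wires, `Ī_i` is the mean dark-corrected
intensity in a 3×3 window at wire i; `I_tot = Σ Ī_i`; `I_avg = I_tot/N`
(undefined at N = 0, not zero). Analog baselines for comparison: the mean
dark-corrected pixel (`i_px`) and the mean over above-threshold pixels
(`i_thr`). Given blank-field statistics, blank-normalized `N′` and `I′` are
reported. Dark offset comes from blank medians, with a histogram-mode
fallback for single frames. For time series, `cumulative_binding` links
detections across frames by nearest neighbor within a configurable radius
and counts distinct sites — a monotone surrogate for cumulative bound
molecules. The wire tapering factor is `(d_bot − d_top)/(d_bot + d_top)`.

## 7. Evaluation

Detections are matched one-to-one to ground-truth bright wires greedily on
globally sorted distances (order-independent; equal to the exhaustive
optimum on the configurations tested) with `d_max = p/2`. Headline
statistics: Jaccard index `TP/(TP+FP+FN)`, precision, recall, and the
pooled false-positive fraction `FP/(TP+FP)` per condition.
`run_simulation_study` sweeps densities {0.05, 1.22, 30.4} molecules/µm²
(regimes I–III) × exposures {50, 100} ms × seeds, analyzing identical
frames with the full pipeline and a localization-only baseline. Per-frame
seeds derive deterministically from the base seed and all remain below
2³¹.

## 8. Limitations

- The enhancement profile is a linear ramp; real waveguide coupling depends
  on wire geometry and wavelength in ways not modeled here.
- Defocus is an isotropic Gaussian widening; aberrated or ringed defocus
  PSFs are not modeled, which flatters the localization-only baseline less
  than a real microscope might.
- The kinked-wire geometry (kink height ≤ 0.3 L, rigid bent top) is a
  simplified stand-in for the range of real growth defects.
- Bright-field rendering ignores diffraction ring structure around wires.
- The photon-budget calibration (base rate 4.5 photons/ms) is a design
  choice, not a fitted instrument constant; absolute intensities should not
  be compared to any specific hardware.
- `cumulative_binding` is a documented surrogate; it undercounts when two
  molecules bind the same site sequentially within the linking radius.
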