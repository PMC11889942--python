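# Methods

## Signal model and noise

A voxel's (or tube's) multi-echo magnitude signal is modelled as a
mono-exponential decay, S(TE) = S₀·exp(−TE/T2), with T2 (spin-echo) or T2*
(gradient-echo) in milliseconds and rates R2 = 1000/T2 in s⁻¹. Noise is
Rician: the simulator adds independent Gaussian noise of standard deviation
σ to two quadrature channels and takes the magnitude,
`out = hypot(S + g₁, g₂)`. σ is the **per-channel** SD, not the SD of the
magnitude. Consequences the tests verify: at zero amplitude the output is
Rayleigh with mean σ·√(π/2); at high SNR the mean approaches the amplitude;
the expectation never falls below the underlying amplitude (Rician bias).
Additive Gaussian noise is deliberately not offered — magnitude MRI data are
Rician, and the low-signal bias is exactly what the fitting safeguards below
are for.

All randomness flows through a single integer seed per specification object.
Tubes draw from independent streams spawned from the phantom seed, so a
tube's series does not depend on how many tubes precede it.

## Relaxometry

The default fitter is weighted least squares on ln S versus TE with weights
S² (for constant-variance additive noise, Var[ln S] ≈ σ²/S², so S²-weighting
restores homoscedasticity). It is closed-form, deterministic, and recovers
the generating (S₀, T2) exactly on noiseless data — the property the
acceptance tests pin at 10⁻⁸ relative error. `method="nls"`
(scipy `curve_fit` on the exponential model, initialised from the log fit)
refines the estimate in the signal domain; at S₀/σ ≥ 100 the two agree to
about 0.1%.

Safeguards, all configurable through `FitConfig`:

* **Noise floor.** Echoes with signal ≤ `noise_floor` are dropped per voxel
  before fitting (default 2σ when σ is known, else 0), because the Rician
  floor flattens the tail of the decay and biases log-domain fits.
* **SNR mask.** Voxels whose first-echo signal is below `snr_k`·σ (default
  k = 5) are marked invalid — this excludes air/background, where a "fit"
  would be noise-on-noise.
* **Plausibility bounds.** Fits outside T2 ∈ [1, 2000] ms, non-decaying
  signals (fitted rate ≤ 0), or voxels with fewer than two usable echoes are
  flagged invalid rather than raising; the validity mask propagates through
  every later stage. The reciprocal conversion likewise marks non-positive
  times invalid instead of producing infinities.

The volume path is fully vectorised numpy (a 64³×16-echo volume fits in
about a second on one core); the `nls` volume path loops over voxels and is
intended for small regions.

## Calibration and concentration mapping

Calibration is plain (unweighted) OLS of rate on concentration over tube
phantoms — two points give the exact interpolating line; r² is snapped to
1.0 when the points are collinear to machine precision so the collinearity
invariant is exact. Inversion is the algebraic inverse with one asymmetry:

* absolute-rate maps (R2/R2*) subtract the fitted intercept,
  C = (rate − b)/r, because the intercept is the agent-free medium rate;
* ΔR2* maps use a **zero** intercept, C = ΔR2*/r, because the tissue
  baseline has already cancelled in the post − pre subtraction. This
  resolves the mismatch between a spin-echo phantom calibration and
  gradient-echo in vivo mapping: only the slope transfers.

Negative concentrations (inevitable under noise where true uptake is zero)
are clipped to 0 and counted; the count is reported as a QC signal rather
than treated as an error. In a noisy scene roughly half the non-uptake
voxels clip, which is the expected behaviour of a symmetric noise on a
zero-mean difference.

## Quantification

ΔR2* is defined on the intersection of the pre/post validity masks; grids
must already be aligned (registration is out of scope). Hypointensity uses
an explicit, logged rule — the source workflow relies on a radiologist's
reading, so the rule here is the configurable part: a tumor voxel is
hypointense when strictly below μ_ref − k·σ_ref (population SD, default
k = 2) over a user-supplied reference ROI disjoint from the tumor. The
threshold is computed from the **pre-injection** image and reused for the
post-injection image, so the reported increase is attributable to the agent
rather than to threshold drift. Strict inequality makes the degenerate
σ_ref = 0 case well-defined (0%).

Volumetry: mask volume is voxel count × voxel volume; contour volume is the
sum over slices of polygon area × slice thickness, with vertices in 0-based
voxel units (voxel-center convention) scaled by the in-plane spacing before
the area is taken (shapely's planar area, i.e. the shoelace formula).
A single stated coordinate convention avoids half-voxel volume errors;
contours closed explicitly (first = last vertex) or implicitly are both
accepted.

## Synthetic data: what it does and does not emulate

The packaged tube fixture places six tubes at a serial two-fold dilution
from 15.7 down to 0.98 μg/mL plus an agent-free tube, with T2 interpolated
from the linear rate law anchored at the two measured pairs (71.1 ms at
0.98 μg/mL; 13.1 ms at 15.7 μg/mL) — only those two pairs and the range are
known, so the law is the minimal generative assumption, and the anchors are
reproduced exactly by construction. The default echo train is 16–376 ms in
8 ms steps (the fitting protocol); the acquisition dialect of 50 echoes at
ΔTE = 8 ms can be requested by passing explicit echo times.

The default scene is a 64³ grid at 0.0625×0.0625×0.5 mm spacing with a
uniform background R2* of 20 s⁻¹ (T2* = 50 ms, typical cortical tissue at
7 T), S₀ = 1000, an axis-aligned ellipsoidal tumor containing a concentric
uptake core at 7 μg/mL, relaxivity taken from the anchored phantom law, and
the in vivo 16-echo protocol (TE = 3.3 + 3k ms). Ellipsoids are restricted
to axis-aligned ones so volumetry oracles have analytic volumes.

Not modelled, by design: k-space/phase reconstruction and SWI, B0
inhomogeneity, partial-volume blurring, spatially varying coil sensitivity,
physiological motion, and registration error between time points. Passing
tests therefore demonstrate the correctness of the estimation chain under
the stated signal model, not robustness to those real-data effects.

## Problem sizes and numerical choices

The test suite exercises 32³ scenes for speed and one 64³ scene for the
end-to-end check; the noisy end-to-end condition uses S₀/σ = 50 with a
fixed seed and requires the median concentration error in the uptake region
below 10% (measured ≈3.6%), and the noiseless condition below 2% (measured
at machine precision). Volumetry is checked against analytic solids: a 2 mm
sphere at 0.1 mm spacing (voxel-count volume within 2%) and a 64-gon circle
stack (within 0.5%; the inscribed-polygon area deficit of a 64-gon is
0.16%).

Ties and degenerate inputs: duplicate tube ids, non-increasing echo trains,
empty ROIs, overlapping tumor/reference ROIs, concentration-free designs
(all tube concentrations equal) and sub-3-vertex contours raise validation
errors; per-voxel fit failures never raise and are carried in the validity
mask instead.

## Known limitations

* The mono-exponential model is fitted even where multi-compartment decay
  would be more faithful; no multi-exponential option is provided.
* The log-linear estimator is slightly biased at low SNR even with the
  noise floor; the `nls` refinement reduces but does not remove Rician bias
  (no Rician-likelihood fitter is included).
* Hypointensity depends on the reference-ROI choice; the package makes the
  rule explicit and reproducible but cannot validate the ROI itself.
* ΔR2*-based concentration assumes perfect pre/post alignment and a purely
  linear rate–concentration relation; susceptibility-induced non-linearity
  at high local concentrations is not modelled.
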