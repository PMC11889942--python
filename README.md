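# spioquant

Quantitative MRI detection and quantification of superparamagnetic iron-oxide
(SPIO) nanoparticles — such as antibody-conjugated theranostic agents targeted
at tumor antigens — from multi-echo magnitude images.

SPIO agents shorten the transverse relaxation times T2/T2*, so their local
accumulation is visible in two ways: as an increase in the voxel-wise
relaxation rate R2\* = 1/T2\*, and as dark (hypointense) signal on
T2\*-weighted images. `spioquant` implements the full measurement chain:

1. **Signal model.** Multi-echo magnitude signal decays as
   S(TE) = S₀·exp(−TE/T2), corrupted by Rician noise (magnitude of a complex
   signal with independent Gaussian channels).
2. **Relaxometry.** Voxel-wise (or per-tube) mono-exponential fitting —
   closed-form weighted log-linear least squares (weights S², the standard
   variance-stabilising choice), with optional nonlinear refinement — and the
   reciprocal conversion R2\* = 1000/T2\* (T2\* in ms, R2\* in s⁻¹).
3. **ΔR2\* mapping.** ΔR2\* = R2\*(post-injection) − R2\*(pre-injection),
   voxel-wise on aligned volumes.
4. **Calibration.** Ordinary least squares of relaxation rate on Fe
   concentration over agarose tube phantoms, `rate = r·C + b`, where the
   slope r (s⁻¹ per μg/mL) is the relaxivity-like transformation coefficient.
   Inverting the line converts rate or ΔR2\* maps into local concentration
   maps (μg Fe/mL).
5. **ROI quantification.** Percent hypointense tumor volume at a
   reference-derived threshold μ_ref − k·σ_ref (and its post-injection
   increase), voxel-mask volumetry, and tumor volume by integrating manually
   contoured slice polygons (shoelace area × slice thickness).

A synthetic-data module stands in for the scanner: tube phantoms whose rate
rises linearly with Fe concentration (anchored at the measured pairs
T2 = 71.1 ms at 0.98 μg/mL and 13.1 ms at 15.7 μg/mL), and pre/post-injection
brain scenes with an ellipsoidal tumor, a known uptake region, and exact
ground-truth maps — so every stage is testable with no downloads.

## Worked example

```python
from spioquant import reference_phantom_spec
from spioquant.pipeline import calibrate_phantom, fit_phantom

spec = reference_phantom_spec()          # 6 tubes, 0–15.7 μg Fe/mL, TEs 16–376 ms
print(fit_phantom(spec)[["tube_id", "fe_conc", "t2_ms"]].to_string(index=False))
model = calibrate_phantom(spec)
print(f"slope {model.slope:.4f} s^-1/(ug/mL), intercept {model.intercept:.4f} s^-1")
```

prints

```
tube_id  fe_conc      t2_ms
 tube00     0.00 100.817366
 tube01     0.98  71.100000
 tube02     1.96  54.913467
 tube03     3.93  37.672849
 tube04     7.85  23.187114
 tube05    15.70  13.100000
slope 4.2304 s^-1/(ug/mL), intercept 9.9189 s^-1
```

The fitted T2 of the 0.98 and 15.7 μg/mL tubes reproduce the measured anchor
values; the calibration slope says each μg/mL of Fe raises R2 by ≈4.23 s⁻¹,
and the intercept is the rate of agent-free agarose (≈9.92 s⁻¹, T2 ≈ 101 ms).
The `examples/` directory has one narrative script per capability (phantom
calibration, scene concentration mapping, hypointensity quantification,
volumetry), each printing the numbers it computes and what they mean.

A thin CLI covers the same stages for shell use:

```sh
spioquant simulate phantom --config phantom.json --out out/
spioquant fit --phantom-config phantom.json --out fits.csv
spioquant calibrate --phantom-config phantom.json --out calibration.json
spioquant run-all --config pipeline.json --out run/
```

Every run writes a `provenance.json` (config hash, seed, package versions).

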