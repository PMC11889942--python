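"""In vivo-style concentration mapping on a synthetic brain scene.

Simulates pre- and post-injection 16-echo gradient-echo volumes of a 64^3
scene whose tumor core has taken up 7 ug/mL of nanoparticles, then runs the
full pipeline: voxel-wise T2* fit of both time points, reciprocal to R2*,
subtraction to dR2*, and inversion through the relaxivity slope to a
concentration map.  Ground truth is known, so the recovery error is printed.
"""

import numpy as np

from spioquant import reference_scene_spec
from spioquant.pipeline import map_scene_concentration
from spioquant.relaxometry import FitConfig

spec = reference_scene_spec(noise_sigma=20.0, seed=1)  # S0/sigma = 50
res = map_scene_concentration(
    spec, fit_config=FitConfig(noise_sigma=spec.noise_sigma))

truth = res.truth
ok = res.conc.valid & truth.uptake_mask
est = res.conc.values[ok]
rel_err = np.abs(est - spec.conc) / spec.conc

print(f"uptake region: {truth.uptake_mask.sum()} voxels at {spec.conc} ug/mL")
print(f"median recovered concentration: {np.median(est):.3f} ug/mL")
print(f"median relative error:          {np.median(rel_err) * 100:.2f} %")
print(f"voxels clipped at zero:         {res.conc.n_clipped}")
print("\nThe dR2* subtraction cancels the tissue baseline, so the")
print("concentration estimate depends only on the relaxivity slope.")
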