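"""Simulate beta patterns with planted structure and compute cross-run
similarity.

The generator plants a known mixture of POI structure in the condition
covariance of the voxel signals; the similarity stage recovers it as a
Fisher-z matrix averaged over run pairs. The empirical matrix is compared
with the closed-form expectation.
"""

import numpy as np

from rsapcm import (
    GeneratorConfig,
    cross_run_similarity,
    default_poi_library,
    expected_similarity,
    simulate_dataset,
)

library = default_poi_library()
cfg = GeneratorConfig(
    n_subjects=6, n_runs=6, n_voxels=2000,
    poi_weights={"RM_NS": 0.37}, run_noise_sd=1.0, rng_seed=7,
)
ds = simulate_dataset(cfg, library)

sim = cross_run_similarity(ds, "sub-01", "ROI")
print("similarity matrix for sub-01 (Fisher z), video block:")
print(np.round(sim.matrix[9:, 9:], 3))
print("run pairs per cell: diagonal", sim.n_pairs[9, 9], "(= C(6,2)),",
      "off-diagonal", sim.n_pairs[9, 10], "(= 6x6 run pairs)")

emp = np.mean([cross_run_similarity(ds, s, "ROI").matrix for s in ds.subjects], axis=0)
z_exp = expected_similarity(cfg, library)
print("\nvideo-pair cell: empirical %.3f vs analytic %.3f"
      % (emp[9, 10], z_exp[9, 10]))
print("within-condition (diagonal) cell: empirical %.3f vs analytic %.3f"
      % (emp[0, 0], z_exp[0, 0]))
print("(the diagonal reflects cross-run pattern reliability; the planted "
      "0.37 covariance among videos appears as z ~ atanh(0.37/2.37))")
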