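"""Monte-Carlo cross-validation: identification rates over repeated splits.

Repeats the selection over random 10-vs-9 subject splits and summarizes,
per POI, how often it lands in the best-fitting component set, its mean
contributing weight, and the hold-out fit -- the table layout used to
characterize each region of interest.
"""

from rsapcm import MCCVConfig, default_poi_library, mt_like_config, run_mccv, simulate_dataset
from rsapcm.mccv import summarize

library = default_poi_library()
cfg = mt_like_config(rng_seed=11)
ds = simulate_dataset(cfg, library)

res = run_mccv(ds, cfg.roi, MCCVConfig(n_iter=100, rs_size=10, rng_seed=12), library)
table = summarize(res)
print(table.to_string(index=False))
print("\nchance rate = mean best-path size / 13 =", round(res.chance_rate, 3))
print("planted POIs (RM_NS, Set, IV_All, IV_Lin) are identified far above"
      " chance; weights in parentheses appear only where the rate beats"
      " chance (one-sided exact binomial, alpha = 0.05).")
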