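"""Build the 13-POI model library and inspect its structure.

Each pattern of interest (POI) is a 12x12 hypothesis similarity matrix over
the task conditions (9 motion-aftereffect conditions = 3 perceived
directions x 3 image valences, plus 3 adaptation videos), with entries in
{-1, 0, 1}: the correlations a region would show if it represented exactly
one source of information.
"""

import numpy as np

from rsapcm import build_condition_scheme, default_poi_library, library_collinearity
from rsapcm.poi_models import poi_to_table

scheme = build_condition_scheme()
library = default_poi_library(scheme)

print("conditions:", ", ".join(scheme.labels))
print(f"\n{len(library)} POIs:", ", ".join(p.name for p in library))

# one compiled matrix in full: the linear image-valence spectrum
iv_lin = next(p for p in library if p.name == "IV_Lin")
print("\nIV_Lin (positive and negative images anticorrelated):")
print(poi_to_table(iv_lin, scheme).to_string())

# the library is deliberately collinear; the audit quantifies the overlap
cs = library_collinearity(library)
off = np.abs(cs[~np.eye(len(library), dtype=bool)])
print(f"\ncollinearity audit: max |cosine| between distinct POIs = {off.max():.3f}")
print("(high overlap is why selection uses a greedy BIC search, not one big"
      " regression)")
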