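import numpy as np
import pytest

from rsapcm import build_condition_scheme, default_poi_library
from rsapcm.poi_models import POISpec, compile_poi
from rsapcm.rsa_core import SimilarityCells


@pytest.fixture(scope="session")
def scheme():
    return build_condition_scheme()


@pytest.fixture(scope="session")
def library(scheme):
    return default_poi_library(scheme)


@pytest.fixture(scope="session")
def orthogonal_library(scheme):
    """Five POIs with disjoint condition blocks: their 78-vectors are
    mutually orthogonal (no shared cells)."""
    specs = [
        POISpec(f"ORTH{k}", blocks=(({"indices": [2 * k, 2 * k + 1]}, None, 1),))
        for k in range(5)
    ]
    lib = [compile_poi(s, scheme) for s in specs]
    vecs = np.stack([p.vector() for p in lib])
    assert np.allclose(vecs @ vecs.T, np.diag((vecs ** 2).sum(1)))
    return lib


def make_cells(values, n_subjects, noise_sd=0.0, subject_sd=0.0, seed=0):
    """Stack of SimilarityCells equal to `values` plus optional noise and
    per-subject offsets."""
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        v = np.asarray(values, dtype=float).copy()
        if subject_sd:
            v = v + rng.normal(0.0, subject_sd)
        if noise_sd:
            v = v + rng.normal(0.0, noise_sd, size=v.shape)
        out.append(SimilarityCells(subject=f"s{s}", roi="roi", values=v))
    return out
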