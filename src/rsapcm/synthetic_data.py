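"""Synthetic voxel-pattern generator with planted POI structure.

Betas are drawn directly from a condition-level Gaussian model: a weighted sum
of POI matrices (plus a within-condition baseline) defines the 12x12 condition
covariance of the true voxel signal, each voxel's 12-vector signal is an
independent draw from that covariance, and each run observes the signal plus
independent Gaussian run noise. Because the planted weights are known, every
downstream stage (similarity, component selection, cross-validation) can be
tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .poi_models import N_CONDITIONS, POIMatrix, build_condition_scheme, default_poi_library

__all__ = [
    "GeneratorConfig",
    "BetaDataset",
    "model_covariance",
    "simulate_dataset",
    "expected_similarity",
    "mt_like_config",
    "MT_LIKE_WEIGHTS",
]

#: Planted weight mixture emulating the motion-sensitive area V5/MT+:
#: nonspecific real-motion, image-set, all-salience valence and linear
#: valence components.
MT_LIKE_WEIGHTS = {"RM_NS": 0.370, "Set": 0.099, "IV_All": 0.150, "IV_Lin": -0.038}

PSD_TOL = 1e-10


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic beta generator.

    poi_weights
        Map POI name -> covariance contribution w_i (dimensionless).
    baseline_weight
        Shared within-condition signal w0 added to the covariance diagonal;
        this is what makes a condition's pattern reproducible across runs.
    run_noise_sd
        Per-voxel, per-run independent noise sigma.
    subject_weight_sd
        Between-subject SD tau of a Gaussian jitter applied to each w_i.
    """

    n_subjects: int = 19
    n_runs: int = 6
    n_voxels: int = 800
    poi_weights: Mapping[str, float] = field(default_factory=dict)
    baseline_weight: float = 1.0
    run_noise_sd: float = 1.0
    subject_weight_sd: float = 0.0
    rng_seed: int = 0
    roi: str = "ROI"

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_runs < 2 or self.n_voxels < 2:
            raise ValueError("need n_subjects >= 2, n_runs >= 2, n_voxels >= 2")
        if self.run_noise_sd < 0 or self.subject_weight_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.baseline_weight < 0:
            raise ValueError("baseline_weight must be non-negative")


def mt_like_config(**overrides) -> GeneratorConfig:
    """The default study-like configuration: 19 subjects, 6 runs, an
    MT-like planted mixture, unit run noise and mild subject jitter."""
    kw = dict(
        n_subjects=19, n_runs=6, n_voxels=800,
        poi_weights=dict(MT_LIKE_WEIGHTS),
        baseline_weight=1.0, run_noise_sd=1.0, subject_weight_sd=0.05,
        roi="MT-like",
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


@dataclass
class BetaDataset:
    """Per-subject, per-ROI run-specific condition voxel patterns.

    ``data[(subject, roi)]`` is an array of shape (n_runs, 12, n_voxels);
    the condition axis follows the canonical scheme order.
    """

    scheme: object
    data: dict
    subjects: list
    rois: list
    n_runs: int
    provenance: dict = field(default_factory=dict)

    def patterns(self, subject, roi) -> np.ndarray:
        return self.data[(subject, roi)]

    def n_voxels(self, roi) -> int:
        return self.data[(self.subjects[0], roi)].shape[2]

    def validate(self) -> None:
        for (s, r), arr in self.data.items():
            if arr.shape[:2] != (self.n_runs, N_CONDITIONS):
                raise ValueError(f"({s}, {r}): expected (runs, 12, voxels), got {arr.shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"({s}, {r}): non-finite beta values")


def model_covariance(
    poi_weights: Mapping[str, float],
    baseline_weight: float,
    library: Sequence[POIMatrix],
) -> tuple[np.ndarray, bool]:
    """Condition covariance implied by a weight mixture.

    C = w0*I + sum_i w_i * P_i, followed by positive-semidefinite repair
    (negative eigenvalues clipped to zero). Returns (C, repaired) where
    ``repaired`` flags whether clipping changed C by more than 1e-10.
    """
    by_name = {p.name: p for p in library}
    unknown = set(poi_weights) - set(by_name)
    if unknown:
        raise KeyError(f"unknown POI name(s): {sorted(unknown)}")
    c = baseline_weight * np.eye(N_CONDITIONS)
    for name, w in poi_weights.items():
        c = c + float(w) * by_name[name].matrix
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= -PSD_TOL:
        return c, False
    clipped = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    clipped = (clipped + clipped.T) / 2
    repaired = bool(np.abs(clipped - c).max() > PSD_TOL)
    return clipped, repaired


def _covariance_sqrt(c: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(c)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_dataset(
    config: GeneratorConfig,
    library: Sequence[POIMatrix] | None = None,
) -> BetaDataset:
    """Draw a BetaDataset from the generative model.

    Per subject: jitter the weights (w_s,i ~ N(w_i, tau^2)), build the
    subject covariance C_s, draw each voxel's condition signal from
    N(0, C_s), then observe signal + N(0, sigma^2) noise independently per
    run. Fully reproducible from ``config.rng_seed``.
    """
    library = library if library is not None else default_poi_library()
    scheme = build_condition_scheme()
    rng = np.random.default_rng(config.rng_seed)
    names = list(config.poi_weights)
    base_w = np.array([config.poi_weights[n] for n in names], dtype=float)

    subjects = [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]
    data = {}
    for subj in subjects:
        w_s = base_w + rng.normal(0.0, config.subject_weight_sd, size=base_w.shape)
        c_s, _ = model_covariance(dict(zip(names, w_s)), config.baseline_weight, library)
        if names and np.abs(c_s).max() <= PSD_TOL and np.abs(base_w).max() > 0:
            raise ValueError("PSD repair removed all signal (all eigenvalues clipped)")
        # (12, V) signal shared by all runs of this subject
        signal = _covariance_sqrt(c_s) @ rng.standard_normal((N_CONDITIONS, config.n_voxels))
        betas = np.repeat(signal[None, :, :], config.n_runs, axis=0)
        if config.run_noise_sd > 0:
            betas = betas + rng.normal(
                0.0, config.run_noise_sd,
                size=(config.n_runs, N_CONDITIONS, config.n_voxels),
            )
        data[(subj, config.roi)] = betas

    ds = BetaDataset(
        scheme=scheme,
        data=data,
        subjects=subjects,
        rois=[config.roi],
        n_runs=config.n_runs,
        provenance={"generator": "rsapcm.synthetic_data", "config": _config_dict(config)},
    )
    ds.validate()
    return ds


def _config_dict(config: GeneratorConfig) -> dict:
    d = dict(config.__dict__)
    d["poi_weights"] = dict(d["poi_weights"])
    return d


def expected_similarity(
    config: GeneratorConfig,
    library: Sequence[POIMatrix] | None = None,
) -> np.ndarray:
    """Analytic expected Fisher-z similarity matrix (test oracle).

    Valid for tau = 0 (population weights). Cross-condition cells use the
    population correlation across runs, z_ij = atanh(C_ij /
    sqrt((C_ii+s^2)(C_jj+s^2))); within-condition cells use cross-run pairs,
    z_ii = atanh(C_ii / (C_ii + s^2)).
    """
    if config.subject_weight_sd != 0:
        raise ValueError("analytic expectation requires subject_weight_sd == 0")
    library = library if library is not None else default_poi_library()
    c, _ = model_covariance(config.poi_weights, config.baseline_weight, library)
    s2 = config.run_noise_sd ** 2
    denom = np.sqrt(np.outer(np.diag(c) + s2, np.diag(c) + s2))
    rho = c / denom
    np.fill_diagonal(rho, np.diag(c) / (np.diag(c) + s2))
    if np.abs(rho).max() >= 1.0:
        raise ValueError("expected correlation reaches |1|; add run noise")
    return np.arctanh(rho)
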