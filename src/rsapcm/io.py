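"""Readers and writers for beta datasets and results.

Two beta-data routes are supported: a long-format delimited table with
columns (subject, roi, run, condition_label, voxel, beta) -- runs 1-based,
voxels 0-based, condition labels the canonical strings -- and a NIfTI
manifest mapping one 3-D beta volume per (subject, run, condition) plus one
ROI mask per ROI.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .poi_models import N_CONDITIONS, build_condition_scheme
from .synthetic_data import BetaDataset

__all__ = ["write_long_table", "load_betas", "write_provenance"]

TABLE_COLUMNS = ["subject", "roi", "run", "condition_label", "voxel", "beta"]


def write_long_table(dataset: BetaDataset, path) -> None:
    """Write a BetaDataset as a long-format CSV (runs 1-based, voxels
    0-based, canonical condition labels)."""
    labels = dataset.scheme.labels
    frames = []
    for (subj, roi), arr in dataset.data.items():
        n_runs, n_cond, n_vox = arr.shape
        run_idx, cond_idx, vox_idx = np.meshgrid(
            np.arange(n_runs), np.arange(n_cond), np.arange(n_vox), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject": subj,
                    "roi": roi,
                    "run": run_idx.ravel() + 1,
                    "condition_label": np.asarray(labels)[cond_idx.ravel()],
                    "voxel": vox_idx.ravel(),
                    "beta": arr.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _load_long_table(path) -> BetaDataset:
    scheme = build_condition_scheme()
    labels = scheme.labels
    df = pd.read_csv(path)
    missing_cols = set(TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"beta table missing columns: {sorted(missing_cols)}")
    bad = set(df["condition_label"]) - set(labels)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    df = df.assign(_cond=df["condition_label"].map({l: i for i, l in enumerate(labels)}))

    data = {}
    n_runs_global = None
    subjects, rois = [], []
    for (subj, roi), grp in df.groupby(["subject", "roi"], sort=True):
        runs = np.sort(grp["run"].unique())
        voxels = np.sort(grp["voxel"].unique())
        n_runs, n_vox = len(runs), len(voxels)
        expected = n_runs * N_CONDITIONS * n_vox
        if not np.array_equal(runs, np.arange(1, n_runs + 1)):
            raise ValueError(f"({subj}, {roi}): runs must be 1..{n_runs}, got {runs.tolist()}")
        if not np.array_equal(voxels, np.arange(n_vox)):
            raise ValueError(f"({subj}, {roi}): voxels must be 0..{n_vox - 1}")
        if len(grp) != expected or grp.duplicated(["run", "_cond", "voxel"]).any():
            have = set(zip(grp["run"], grp["_cond"], grp["voxel"]))
            for r in runs:
                for c in range(N_CONDITIONS):
                    for v in voxels:
                        if (r, c, v) not in have:
                            raise ValueError(
                                f"({subj}, {roi}): missing cell run={r} "
                                f"condition={labels[c]!r} voxel={v}"
                            )
            raise ValueError(f"({subj}, {roi}): duplicated rows in beta table")
        arr = np.full((n_runs, N_CONDITIONS, n_vox), np.nan)
        arr[grp["run"] - 1, grp["_cond"], grp["voxel"]] = grp["beta"]
        data[(subj, roi)] = arr
        if n_runs_global is None:
            n_runs_global = n_runs
        elif n_runs_global != n_runs:
            raise ValueError("inconsistent run counts across subjects")
        if subj not in subjects:
            subjects.append(subj)
        if roi not in rois:
            rois.append(roi)

    if not data:
        raise ValueError("beta table is empty")
    ds = BetaDataset(
        scheme=scheme, data=data, subjects=subjects, rois=rois,
        n_runs=n_runs_global, provenance={"source": str(path)},
    )
    ds.validate()
    return ds


def _load_manifest(path) -> BetaDataset:
    """NIfTI route: one 3-D beta volume per (subject, run, condition) and one
    mask per ROI; voxel order is the C-order scan of the mask's nonzero
    entries (stable for a fixed mask)."""
    import nibabel as nib

    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    base = path.parent
    scheme = build_condition_scheme()

    masks = {}
    for roi, mask_path in manifest["rois"].items():
        mp = base / mask_path
        if not mp.exists():
            raise FileNotFoundError(f"ROI mask not found: {mp}")
        mask_img = nib.load(str(mp))
        mask = np.asarray(mask_img.dataobj)
        masks[roi] = (mask > 0, mask.shape)

    entries = manifest["betas"]
    by_cell = {}
    for e in entries:
        fp = base / e["path"]
        if not fp.exists():
            raise FileNotFoundError(f"beta volume not found: {fp}")
        cond = scheme.index_of(e["condition"])
        by_cell[(e["subject"], int(e["run"]), cond)] = fp

    subjects = sorted({s for s, _, _ in by_cell})
    runs = sorted({r for _, r, _ in by_cell})
    if runs != list(range(1, len(runs) + 1)):
        raise ValueError(f"runs must be 1..{len(runs)}, got {runs}")

    data = {}
    for roi, (mask, shape) in masks.items():
        flat = np.flatnonzero(mask.ravel(order="C"))
        for subj in subjects:
            arr = np.full((len(runs), N_CONDITIONS, flat.size), np.nan)
            for run in runs:
                for cond in range(N_CONDITIONS):
                    key = (subj, run, cond)
                    if key not in by_cell:
                        raise ValueError(
                            f"manifest missing volume for subject={subj} run={run} "
                            f"condition={scheme.labels[cond]!r}"
                        )
                    vol = np.asarray(nib.load(str(by_cell[key])).dataobj)
                    if vol.shape != shape:
                        raise ValueError(
                            f"grid mismatch: {by_cell[key]} has shape {vol.shape}, "
                            f"mask for {roi!r} has {shape}"
                        )
                    arr[run - 1, cond] = vol.ravel(order="C")[flat]
            data[(subj, roi)] = arr

    ds = BetaDataset(
        scheme=scheme, data=data, subjects=subjects, rois=list(masks),
        n_runs=len(runs), provenance={"source": str(path)},
    )
    ds.validate()
    return ds


def load_betas(source) -> BetaDataset:
    """Load a BetaDataset from a long-format table (.csv/.tsv) or a NIfTI
    run manifest (.json)."""
    source = Path(source)
    if source.suffix.lower() == ".json":
        return _load_manifest(source)
    return _load_long_table(source)


def write_provenance(path, seed, config: dict, inputs: dict | None = None) -> None:
    """Record how a result was produced: seed, config, package versions and
    input digests."""
    import hashlib

    from . import __version__

    digests = {}
    for name, fp in (inputs or {}).items():
        h = hashlib.sha256()
        with open(fp, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        digests[name] = h.hexdigest()
    record = {
        "seed": seed,
        "config": config,
        "versions": {
            "rsapcm": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_digests": digests,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
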