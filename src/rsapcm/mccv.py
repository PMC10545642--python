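"""Monte-Carlo cross-validation of the pattern-component selection.

Each iteration draws a random sample (RS) of subjects, runs the greedy
best-first BIC selection on the stacked RS similarity cells, rebuilds the
reconstructed component from the selected POIs and their weights, and fits
it to the held-out (HO) subjects. Aggregates follow the study's table
layout: per-POI identification rate and mean contributing weight, the mean
number of completed equivalent search paths ("Av. n-path"), the chance
identification rate, and hold-out fit statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pcm_select import (
    DEFAULT_DELTA,
    HoldoutFit,
    gbfs_select,
    holdout_fit,
    reconstruct_component,
)
from .poi_models import POIMatrix
from .rsa_core import dataset_cells

__all__ = ["MCCVConfig", "MCCVIteration", "MCCVResult", "run_mccv", "summarize"]


@dataclass(frozen=True)
class MCCVConfig:
    """Monte-Carlo cross-validation parameters.

    The defaults mirror the study design: 1,000 random splits of the
    subject pool into a random sample of 10 and a hold-out of the rest.
    """

    n_iter: int = 1000
    rs_size: int = 10
    delta: float = DEFAULT_DELTA
    method: str = "mixed"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.rs_size < 2:
            raise ValueError("rs_size must be >= 2")


@dataclass
class MCCVIteration:
    rs_subjects: tuple
    best_path: tuple[str, ...]   # empty when no POI beat the null model
    weights: dict
    n_paths: int
    holdout: HoldoutFit | None   # None when the selection was empty


@dataclass
class MCCVResult:
    roi: object
    poi_names: list[str]
    iterations: list[MCCVIteration]
    identification_rate: dict       # POI -> fraction of iterations in best path
    mean_weight: dict               # POI -> mean beta over identifying iterations (nan if never)
    mean_n_paths: float
    chance_rate: float
    mean_holdout_r2: float
    sd_holdout_r2: float
    mean_holdout_slope: float
    sd_holdout_slope: float
    median_holdout_p: float
    config: MCCVConfig = None

    @property
    def n_iter(self) -> int:
        return len(self.iterations)


def run_mccv(
    dataset,
    roi,
    config: MCCVConfig,
    library: Sequence[POIMatrix],
    cells=None,
) -> MCCVResult:
    """Run the full MCCV loop for one ROI.

    Similarity cells are computed once per subject and reused across
    iterations; splits are drawn without replacement within an iteration and
    independently across iterations, all from ``config.rng_seed``.
    Precomputed ``cells`` (one SimilarityCells per subject, dataset order)
    may be supplied to skip the similarity stage.
    """
    subjects = list(dataset.subjects)
    if config.rs_size >= len(subjects):
        raise ValueError(
            f"rs_size={config.rs_size} must be smaller than the "
            f"{len(subjects)}-subject pool (hold-out would be empty)"
        )
    if cells is None:
        cells = dataset_cells(dataset, roi)
    by_subject = dict(zip(subjects, cells))

    rng = np.random.default_rng(config.rng_seed)
    # draw all splits up front so iteration order cannot affect the stream
    splits = [
        tuple(rng.choice(len(subjects), size=config.rs_size, replace=False))
        for _ in range(config.n_iter)
    ]

    names = [p.name for p in library]
    iterations: list[MCCVIteration] = []
    for split in splits:
        rs = [subjects[i] for i in split]
        ho = [s for s in subjects if s not in rs]
        sel = gbfs_select(
            [by_subject[s] for s in rs], library, delta=config.delta, method=config.method
        )
        if sel.contributing:
            recon = reconstruct_component(sel, library)
            ho_fit = holdout_fit(recon, [by_subject[s] for s in ho])
        else:
            ho_fit = None
        iterations.append(
            MCCVIteration(
                rs_subjects=tuple(rs),
                best_path=sel.best_path,
                weights=dict(sel.weights),
                n_paths=sel.n_paths,
                holdout=ho_fit,
            )
        )

    n_iter = len(iterations)
    counts = {n: sum(n in it.best_path for it in iterations) for n in names}
    rates = {n: counts[n] / n_iter for n in names}
    mean_w = {}
    for n in names:
        betas = [it.weights[n] for it in iterations if n in it.best_path]
        mean_w[n] = float(np.mean(betas)) if betas else float("nan")
    sizes = [len(it.best_path) for it in iterations]
    # hold-out statistics aggregate over iterations with a non-empty selection
    fitted = [it.holdout for it in iterations if it.holdout is not None]
    r2s = [h.r2 for h in fitted] or [np.nan]
    slopes = [h.slope for h in fitted] or [np.nan]
    ps = [h.p_value for h in fitted] or [np.nan]
    return MCCVResult(
        roi=roi,
        poi_names=names,
        iterations=iterations,
        identification_rate=rates,
        mean_weight=mean_w,
        mean_n_paths=float(np.mean([it.n_paths for it in iterations])),
        chance_rate=float(np.mean(sizes)) / len(names),
        mean_holdout_r2=float(np.mean(r2s)),
        sd_holdout_r2=float(np.std(r2s)),
        mean_holdout_slope=float(np.mean(slopes)),
        sd_holdout_slope=float(np.std(slopes)),
        median_holdout_p=float(np.median(ps)),
        config=config,
    )


def identification_significant(
    result: MCCVResult, poi: str, alpha: float = 0.05
) -> bool:
    """One-sided exact binomial test of a POI's identification count against
    the chance rate (identified more often than chance at level alpha)."""
    n = result.n_iter
    k = round(result.identification_rate[poi] * n)
    p0 = min(max(result.chance_rate, 1e-12), 1 - 1e-12)
    test = stats.binomtest(k, n, p0, alternative="greater")
    return bool(test.pvalue < alpha)


def summarize(results: MCCVResult | Sequence[MCCVResult], alpha: float = 0.05) -> pd.DataFrame:
    """Table-style summary: one row per ROI.

    Per-POI cells show the identification percentage, with the mean
    contributing weight in parentheses only for POIs identified
    significantly more often than chance (one-sided exact binomial test at
    ``alpha``); otherwise the weight is blank.
    """
    if isinstance(results, MCCVResult):
        results = [results]
    rows = []
    for res in results:
        row = {"ROI": res.roi, "Av. n-path": round(res.mean_n_paths, 3)}
        for name in res.poi_names:
            pct = 100.0 * res.identification_rate[name]
            if identification_significant(res, name, alpha=alpha):
                cell = f"{pct:.1f} ({res.mean_weight[name]:.3f})"
            else:
                cell = f"{pct:.1f} -"
            row[name] = cell
        row["chance %"] = round(100.0 * res.chance_rate, 1)
        row["HO R2"] = round(res.mean_holdout_r2, 3)
        row["HO p (median)"] = res.median_holdout_p
        row["Recon. slope"] = round(res.mean_holdout_slope, 3)
        rows.append(row)
    return pd.DataFrame(rows)
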