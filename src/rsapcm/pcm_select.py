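"""Pattern-component model fitting and greedy best-first BIC selection.

The observed similarity cells of a stack of subjects are regressed on
vectorized POI matrices. Model comparison uses BIC = -2*loglik + k*ln(n).
The default estimator is a linear mixed model with a per-subject random
intercept, fitted by maximum likelihood (ML, not REML, so likelihoods are
comparable across fixed-effect structures); a pooled ordinary-least-squares
estimator is available for oracles and degenerate cases.

Within-condition (diagonal) cells measure a condition's cross-run pattern
*reliability*, which is related to -- but not linearly exchangeable with --
the between-condition similarity structure a POI hypothesises: any region
with reproducible signal has elevated diagonal cells regardless of what it
represents, and the Fisher-z of a reliability is a different (nonlinear)
function of signal strength than the z of a between-condition correlation.
The default design therefore (a) always carries a *within-condition
baseline* component (the vectorized identity), the usual noise/baseline
component of pattern-component modelling, together with a shared
*reliability dictionary* -- the deduplicated diagonal-support patterns of
the whole library -- present in every candidate model including the null
model, and (b) enters each candidate POI through its between-condition
(off-diagonal) part only, whose coefficient is the reported contributing
weight. Model comparison is then driven purely by between-condition
structure, never by how well a candidate's diagonal support happens to
absorb reliability variance. ``include_baseline=False`` /
``split_diagonal=False`` recover the raw one-column-per-POI design.

Selection is a greedy best-first search: the best single POI seeds the
search provided it improves BIC by more than Delta (default 2) over the
null (no-POI) model -- otherwise the contributing set is empty -- and each
path repeatedly adds the POI that improves BIC the most, stopping when no
addition improves by more than Delta. Additions or level-1 seeds whose BIC
lies within Delta of the best are treated as statistically equivalent and
expanded as parallel search paths; the contributing set is read from the
completed path with the lowest end BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .poi_models import POIMatrix
from .rsa_core import N_CELLS, SimilarityCells

__all__ = [
    "ComponentFit",
    "SelectionResult",
    "HoldoutFit",
    "RankDeficientError",
    "fit_component_model",
    "gbfs_select",
    "reconstruct_component",
    "holdout_fit",
]

DEFAULT_DELTA = 2.0


class RankDeficientError(ValueError):
    """The candidate predictor set is not identifiable (collinear POIs)."""


@dataclass
class ComponentFit:
    """A fitted linear component model on stacked similarity cells."""

    poi_names: tuple[str, ...]
    weights: np.ndarray          # between-condition beta per POI (order of poi_names)
    intercept: float
    bic: float
    loglik: float
    n_obs: int
    method: str                  # "mixed" | "pooled"
    sigma2: float = math.nan     # residual variance (ML)
    tau2: float = math.nan       # random-intercept variance (mixed only)
    baseline: float = math.nan   # within-condition baseline weight (nan if excluded)
    diag_patterns: tuple = ()    # per-POI-group diagonal indicator 78-vectors
    diag_weights: np.ndarray = None  # reliability coefficient per diag pattern
    component_vector: np.ndarray = None  # fitted 78-cell prediction minus intercept

    @property
    def weights_by_name(self) -> dict[str, float]:
        return dict(zip(self.poi_names, self.weights))


@dataclass
class SelectionResult:
    """Outcome of the greedy best-first search.

    ``best_path`` (and hence ``contributing``) is empty when no single POI
    improved BIC by more than delta over the null model.
    """

    paths: list                     # list of (ordered poi-name tuple, end BIC)
    best_path: tuple[str, ...]
    best_bic: float
    contributing: tuple[str, ...]   # POIs of the best path
    best_fit: ComponentFit
    n_paths: int
    delta: float
    null_bic: float = math.nan      # BIC of the no-POI (reliability-only) model
    tie_broken: bool = False

    @property
    def weights(self) -> dict[str, float]:
        return self.best_fit.weights_by_name


@dataclass
class HoldoutFit:
    """Simple regression of held-out cells on the reconstructed component."""

    r2: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    slope: float
    intercept: float
    n_obs: int


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _stack(cells_stack: Sequence[SimilarityCells]) -> tuple[np.ndarray, np.ndarray]:
    y = np.concatenate([np.asarray(c.values, dtype=float) for c in cells_stack])
    groups = np.repeat(np.arange(len(cells_stack)), [len(c.values) for c in cells_stack])
    return y, groups

def _diag_indicator() -> np.ndarray:
    """Vectorized identity matrix: 1 on within-condition cells, 0 elsewhere."""
    from .poi_models import N_CONDITIONS

    iu = np.triu_indices(N_CONDITIONS)
    return (iu[0] == iu[1]).astype(float)


def reliability_dictionary(library: Sequence[POIMatrix]) -> tuple[np.ndarray, ...]:
    """Deduplicated within-condition (diagonal) support patterns of a POI
    library, in library order, keeping only patterns that add rank beyond
    the uniform baseline."""
    d = _diag_indicator()
    is_diag = d.astype(bool)
    cols = [d]
    seen = {tuple(d)}
    kept: list[np.ndarray] = []
    for p in library:
        pat = np.where(is_diag, p.vector(), 0.0)
        key = tuple(pat)
        if not pat.any() or key in seen:
            continue
        seen.add(key)
        cand = np.column_stack(cols + [pat])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            cols.append(pat)
            kept.append(pat)
    return tuple(kept)


def _design_single(
    pois: Sequence[POIMatrix],
    include_baseline: bool,
    split_diagonal: bool,
    reliability: Sequence[np.ndarray] | None,
) -> tuple[np.ndarray, dict]:
    """One subject's 78-row design matrix and column bookkeeping.

    Columns: intercept | [baseline d] | reliability columns | one
    between-condition column per POI (diagonal entries zeroed when
    splitting). ``reliability`` defaults to the candidate set's own
    dictionary; selection passes the library-wide dictionary so every
    candidate model shares it. Raises :class:`RankDeficientError` if the
    columns are collinear.
    """
    d = _diag_indicator()
    is_diag = d.astype(bool)
    cols = [np.ones(N_CELLS)]
    if include_baseline:
        cols.append(d)
    if split_diagonal:
        if reliability is None:
            reliability = reliability_dictionary(pois)
        cols.extend(np.asarray(pat, dtype=float) for pat in reliability)
    else:
        reliability = ()
    n_head = len(cols)
    for p in pois:
        v = p.vector()
        if split_diagonal:
            v = np.where(is_diag, 0.0, v)
        cols.append(v)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficientError(
            f"collinear predictor set: {[p.name for p in pois]}"
        )
    meta = {
        "off_slice": slice(n_head, n_head + len(pois)),
        "baseline_idx": 1 if include_baseline else None,
        "diag_patterns": tuple(np.asarray(p, dtype=float) for p in reliability),
        "diag_slice": slice(1 + int(include_baseline), n_head),
    }
    return x, meta


def _ols_ml(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS coefficients, ML residual variance and Gaussian log-likelihood."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise RankDeficientError(f"design rank {rank} < {x.shape[1]} columns")
    resid = y - x @ beta
    n = y.size
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return beta, sigma2, loglik


def _random_intercept_ml(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, float, float, float]:
    """Exact ML fit of y = X b + u_group + e via the profiled likelihood.

    With V_g = sigma2 * (I + theta * J) per group (theta = tau2/sigma2), the
    GLS solution and sigma2 profile out, leaving a 1-D concentrated
    log-likelihood in theta, minimised by bounded scalar search. Whitening
    uses (I + theta*J)^(-1/2) y = y - c * ybar per group with
    c = 1 - 1/sqrt(1 + theta*m).

    Returns (beta, sigma2, tau2, loglik).
    """
    n = y.size
    uniq, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    m = counts.astype(float)

    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficientError(f"design has {x.shape[1]} columns but lower rank")

    # group sums for fast whitening
    def _whiten(a: np.ndarray, theta: float) -> np.ndarray:
        c = 1.0 - 1.0 / np.sqrt(1.0 + theta * m)           # per group
        if a.ndim == 1:
            means = np.bincount(inv, weights=a) / m
            return a - (c * means)[inv]
        out = np.empty_like(a)
        for k in range(a.shape[1]):
            means = np.bincount(inv, weights=a[:, k]) / m
            out[:, k] = a[:, k] - (c * means)[inv]
        return out

    def neg2ll(theta: float) -> float:
        yw = _whiten(y, theta)
        xw = _whiten(x, theta)
        beta, _, _, _ = np.linalg.lstsq(xw, yw, rcond=None)
        resid = yw - xw @ beta
        sigma2 = float(resid @ resid) / n
        sigma2 = max(sigma2, np.finfo(float).tiny)
        logdet = float(np.sum(np.log1p(theta * m)))
        return n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet

    # optimise on log1p scale for better conditioning; include theta = 0
    res = optimize.minimize_scalar(
        lambda t: neg2ll(math.expm1(t)),
        bounds=(0.0, math.log1p(1e6)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = math.expm1(res.x)
    cand = min((neg2ll(0.0), 0.0), (res.fun, theta))
    theta = cand[1]

    yw = _whiten(y, theta)
    xw = _whiten(x, theta)
    beta, _, _, _ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    sigma2 = max(float(resid @ resid) / n, np.finfo(float).tiny)
    loglik = -0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0)
                     + float(np.sum(np.log1p(theta * m))))
    return beta, sigma2, theta * sigma2, loglik


def fit_component_model(
    cells_stack: Sequence[SimilarityCells],
    pois: Sequence[POIMatrix],
    method: str = "mixed",
    include_baseline: bool = True,
    split_diagonal: bool = True,
    reliability: Sequence[np.ndarray] | None = None,
) -> ComponentFit:
    """Fit cells ~ intercept [+ baseline + reliability] + sum_i beta_i *
    POI_i (+ subject random intercept for the mixed method) by maximum
    likelihood.

    With ``split_diagonal`` (the default) each POI contributes a
    between-condition column -- whose coefficient is the reported weight --
    while within-condition structure is carried by the shared reliability
    columns; see the module docstring. BIC counts every estimated
    parameter: all fixed effects plus the residual variance, and for the
    mixed method the random-intercept variance. Raises
    :class:`RankDeficientError` when the candidate POIs are collinear.
    An empty ``pois`` fits the null (reliability-only) model.
    """
    if len(cells_stack) < 2:
        raise ValueError("need at least 2 subjects")
    y, groups = _stack(cells_stack)
    x1, meta = _design_single(pois, include_baseline, split_diagonal, reliability)
    x = np.tile(x1, (len(cells_stack), 1))
    n = y.size

    if method == "pooled":
        beta, sigma2, loglik = _ols_ml(y, x)
        k = x.shape[1] + 1
        tau2 = math.nan
    elif method == "mixed":
        beta, sigma2, tau2, loglik = _random_intercept_ml(y, x, groups)
        k = x.shape[1] + 2
    else:
        raise ValueError(f"unknown method {method!r}")

    bic = -2.0 * loglik + k * math.log(n)
    base_idx = meta["baseline_idx"]
    return ComponentFit(
        poi_names=tuple(p.name for p in pois),
        weights=np.asarray(beta[meta["off_slice"]], dtype=float),
        intercept=float(beta[0]),
        bic=float(bic),
        loglik=float(loglik),
        n_obs=int(n),
        method=method,
        sigma2=float(sigma2),
        tau2=float(tau2),
        baseline=float(beta[base_idx]) if base_idx is not None else math.nan,
        diag_patterns=meta["diag_patterns"],
        diag_weights=np.asarray(beta[meta["diag_slice"]], dtype=float),
        component_vector=x1[:, 1:] @ beta[1:],
    )


# ---------------------------------------------------------------------------
# Greedy best-first search
# ---------------------------------------------------------------------------

def gbfs_select(
    cells_stack: Sequence[SimilarityCells],
    library: Sequence[POIMatrix],
    delta: float = DEFAULT_DELTA,
    method: str = "mixed",
    include_baseline: bool = True,
    split_diagonal: bool = True,
) -> SelectionResult:
    """Greedy best-first BIC search with equivalent-path expansion.

    Level 1 fits every single POI; the minimum-BIC model and every model
    within ``delta`` of it seed parallel paths, provided they improve BIC
    by more than ``delta`` over the null (no-POI) model -- otherwise the
    search ends with an empty contributing set. Each path then repeatedly
    adds the remaining POI giving the lowest BIC, provided the addition
    improves the path BIC by more than ``delta``; admissible additions
    within ``delta`` of the best one branch into parallel paths. A path
    completes when no admissible addition remains. Paths that reach an
    identical POI set are merged. The contributing set is the completed
    path with the lowest end BIC; exact ties prefer fewer POIs, then
    lexicographic name order.
    """
    if not library:
        raise ValueError("POI library is empty")
    by_name = {p.name: p for p in library}
    if len(by_name) != len(library):
        raise ValueError("library contains duplicate POI names")
    names = [p.name for p in library]
    reliability = reliability_dictionary(library) if split_diagonal else None

    cache: dict[frozenset, ComponentFit | None] = {}

    def fit(subset: frozenset) -> ComponentFit | None:
        if subset not in cache:
            pois = [by_name[n] for n in names if n in subset]  # library order
            try:
                cache[subset] = fit_component_model(
                    cells_stack, pois, method=method,
                    include_baseline=include_baseline,
                    split_diagonal=split_diagonal,
                    reliability=reliability,
                )
            except RankDeficientError:
                cache[subset] = None
        return cache[subset]

    null_fit = fit(frozenset())
    if null_fit is None:
        raise RankDeficientError("null (no-POI) model is not identifiable")

    # level 1: every single POI, gated against the null model
    singles = [(fit(frozenset([n])), n) for n in names]
    singles = [(f.bic, n) for f, n in singles if f is not None]
    if not singles:
        raise RankDeficientError("no single-POI model is identifiable")
    best1 = min(b for b, _ in singles)
    active = {
        frozenset([n]): ((n,), b)
        for b, n in singles
        if b <= best1 + delta and b < null_fit.bic - delta
    }
    if not active:
        # no POI is predictive: the null model is the completed search
        return SelectionResult(
            paths=[((), null_fit.bic)],
            best_path=(),
            best_bic=float(null_fit.bic),
            contributing=(),
            best_fit=null_fit,
            n_paths=1,
            delta=delta,
            null_bic=float(null_fit.bic),
        )

    completed: dict[frozenset, tuple[tuple[str, ...], float]] = {}
    while active:
        next_active: dict[frozenset, tuple[tuple[str, ...], float]] = {}
        for subset, (path, bic) in active.items():
            cands = []
            for n in names:
                if n in subset:
                    continue
                f = fit(subset | {n})
                if f is not None and f.bic < bic - delta:
                    cands.append((f.bic, n))
            if not cands:
                if subset not in completed or completed[subset][1] > bic:
                    completed[subset] = (path, bic)
                continue
            best_add = min(b for b, _ in cands)
            for b, n in cands:
                if b <= best_add + delta:
                    new = subset | {n}
                    if new not in next_active or next_active[new][1] > b:
                        next_active[new] = (path + (n,), b)
        active = next_active

    paths = sorted(completed.values(), key=lambda pb: (pb[1], len(pb[0]), tuple(sorted(pb[0]))))
    best_path, best_bic = paths[0]
    ties = [p for p, b in paths if b == best_bic]
    best_fit = fit(frozenset(best_path))
    return SelectionResult(
        paths=paths,
        best_path=best_path,
        best_bic=float(best_bic),
        contributing=tuple(n for n in names if n in best_path),
        best_fit=best_fit,
        n_paths=len(paths),
        delta=delta,
        null_bic=float(null_fit.bic),
        tie_broken=len(ties) > 1,
    )


def reconstruct_component(
    selection: SelectionResult, library: Sequence[POIMatrix]
) -> np.ndarray:
    """Weighted combination of the contributing component vectors (no
    intercept): the POI weights times their vectors, plus -- whenever they
    were part of the fitted model -- the within-condition baseline and
    reliability terms, so the reconstruction predicts diagonal and
    off-diagonal cells on the same footing. The global intercept is always
    left out (the hold-out fit estimates a fresh one).
    """
    if not selection.contributing:
        raise ValueError("selection has no contributing POIs")
    fit = selection.best_fit
    if fit.component_vector is not None:
        return np.asarray(fit.component_vector, dtype=float).copy()
    by_name = {p.name: p for p in library}
    recon = np.zeros(N_CELLS)
    if math.isfinite(fit.baseline):
        recon += fit.baseline * _diag_indicator()
    for name, beta in selection.weights.items():
        recon += beta * by_name[name].vector()
    return recon


def holdout_fit(recon: np.ndarray, ho_cells_stack: Sequence[SimilarityCells]) -> HoldoutFit:
    """Fit the reconstructed component to held-out subjects.

    Ordinary least squares of the stacked hold-out cells on the recon vector
    with a fresh intercept; reports R^2, F(1, 78*n_HO - 2), p, slope and
    intercept. With 9 hold-out subjects the denominator df is 700.
    """
    if len(ho_cells_stack) < 1:
        raise ValueError("need at least one hold-out subject")
    recon = np.asarray(recon, dtype=float)
    if recon.std() == 0:
        raise ValueError("reconstructed component has zero variance")
    y = np.concatenate([np.asarray(c.values, dtype=float) for c in ho_cells_stack])
    x = np.tile(recon, len(ho_cells_stack))
    n = y.size
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    df_den = n - 2
    if r2 >= 1.0:
        f = math.inf
        p = 0.0
    else:
        f = r2 / (1.0 - r2) * df_den
        p = float(stats.f.sf(f, 1, df_den))
    return HoldoutFit(
        r2=float(r2),
        f_stat=float(f),
        df_num=1,
        df_den=int(df_den),
        p_value=p,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_obs=int(n),
    )
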