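"""Component fitting, BIC, greedy best-first selection, hold-out fits."""

import itertools
import math

import numpy as np
import pytest

from rsapcm import GeneratorConfig, simulate_dataset
from rsapcm.pcm_select import (
    RankDeficientError,
    fit_component_model,
    gbfs_select,
    holdout_fit,
    reconstruct_component,
)
from rsapcm.pcm_select import (
    _design_single,
    _diag_indicator,
    reliability_dictionary,
)
from rsapcm.rsa_core import dataset_cells

from conftest import make_cells


class TestFitComponentModel:
    def test_exact_linear_recovery(self, library):
        """Noise-free cells equal to one POI's vector: beta = 1."""
        rm_ns = {p.name: p for p in library}["RM_NS"]
        cells = make_cells(rm_ns.vector(), n_subjects=3)
        for method in ("pooled", "mixed"):
            fit = fit_component_model(cells, [rm_ns], method=method)
            assert fit.weights[0] == pytest.approx(1.0, abs=1e-8)
            assert fit.intercept == pytest.approx(0.0, abs=1e-8)
            assert fit.baseline == pytest.approx(0.0, abs=1e-8)

    def test_pooled_bic_matches_hand_computed_gaussian(self, library):
        """BIC = -2*loglik + 3*ln(156) for 2 subjects x 78 cells, one POI,
        intercept, and the ML residual variance -- against an explicit
        normal-equations oracle."""
        poi = {p.name: p for p in library}["Set"]
        cells = make_cells(0.4 * poi.vector(), 2, noise_sd=0.1, seed=4)
        fit = fit_component_model(cells, [poi], method="pooled",
                                  include_baseline=False, split_diagonal=False)

        y = np.concatenate([c.values for c in cells])
        x = np.column_stack([np.ones(156), np.tile(poi.vector(), 2)])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        sigma2 = resid @ resid / 156
        loglik = -0.5 * 156 * (math.log(2 * math.pi * sigma2) + 1)
        assert fit.loglik == pytest.approx(loglik, abs=1e-9)
        assert fit.bic == pytest.approx(-2 * loglik + 3 * math.log(156), abs=1e-9)
        assert fit.n_obs == 156

    def test_duplicate_poi_is_rank_deficient(self, library):
        poi = library[9]
        cells = make_cells(poi.vector(), 2, noise_sd=0.1, seed=5)
        with pytest.raises(RankDeficientError):
            fit_component_model(cells, [poi, poi], method="pooled")
        with pytest.raises(RankDeficientError):
            fit_component_model(cells, [poi, poi], method="mixed")

    def test_mixed_ml_agrees_with_statsmodels(self, library):
        """Independent oracle: statsmodels MixedLM with ML estimation."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(6)
        pois = [library[4], library[6]]
        truth = 0.2 * pois[0].vector() + 0.1 * pois[1].vector()
        cells = make_cells(truth, 8, noise_sd=0.05, subject_sd=0.1, seed=6)
        fit = fit_component_model(cells, pois, method="mixed")

        y = np.concatenate([c.values for c in cells])
        x1, meta = _design_single(pois, include_baseline=True,
                                  split_diagonal=True, reliability=None)
        x = np.tile(x1, (8, 1))
        groups = np.repeat(np.arange(8), 78)
        sm_fit = MixedLM(y, x, groups).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-5)
        assert fit.intercept == pytest.approx(sm_fit.fe_params[0], abs=1e-5)
        assert np.allclose(fit.weights, sm_fit.fe_params[meta["off_slice"]], atol=1e-5)
        assert fit.sigma2 == pytest.approx(sm_fit.scale, rel=1e-4)
        assert fit.tau2 == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), abs=1e-4)

    def test_adding_a_poi_never_decreases_loglik(self, library):
        rng = np.random.default_rng(7)
        cells = make_cells(rng.normal(0, 0.2, 78), 4, noise_sd=0.1, seed=7)
        for method in ("pooled", "mixed"):
            lls = []
            for k in (1, 2, 3):
                fit = fit_component_model(cells, library[:k], method=method)
                lls.append(fit.loglik)
            assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6


def brute_force_best_bic(cells, library, method="pooled"):
    """Exhaustive minimum BIC over every POI subset (including the empty
    null model), using the same shared reliability dictionary as the
    greedy search."""
    reliability = reliability_dictionary(library)
    best = (math.inf, None)
    for r in range(0, len(library) + 1):
        for combo in itertools.combinations(library, r):
            try:
                fit = fit_component_model(cells, list(combo), method=method,
                                          reliability=reliability)
            except RankDeficientError:
                continue
            if fit.bic < best[0]:
                best = (fit.bic, tuple(p.name for p in combo))
    return best


class TestGBFS:
    def test_deterministic(self, library):
        cells = make_cells(0.3 * library[5].vector(), 6, noise_sd=0.05, seed=8)
        a = gbfs_select(cells, library)
        b = gbfs_select(cells, library)
        assert a.best_path == b.best_path
        assert a.paths == b.paths

    def test_empty_library_rejected(self, library):
        cells = make_cells(np.zeros(78), 3, noise_sd=0.1, seed=8)
        with pytest.raises(ValueError):
            gbfs_select(cells, [])

    def test_best_path_has_lowest_end_bic_and_valid_prefixes(self, library):
        cells = make_cells(
            0.2 * library[4].vector() + 0.1 * library[6].vector(),
            8, noise_sd=0.05, subject_sd=0.05, seed=9,
        )
        sel = gbfs_select(cells, library)
        assert all(sel.best_bic <= b for _, b in sel.paths)
        # each prefix of each path improved by more than delta, starting
        # from the null (no-POI) model
        reliability = reliability_dictionary(library)
        for path, _ in sel.paths:
            prev = sel.null_bic
            for k in range(1, len(path) + 1):
                fit = fit_component_model(
                    cells, [p for p in library if p.name in path[:k]],
                    reliability=reliability,
                )
                assert fit.bic < prev - sel.delta
                prev = fit.bic

    @pytest.mark.parametrize("seed", range(5))
    def test_orthogonal_library_matches_exhaustive_search(
        self, orthogonal_library, seed
    ):
        """On mutually orthogonal POIs greedy selection reaches the global
        BIC minimum (brute-force subset enumeration oracle)."""
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 3)
        chosen = rng.choice(5, size=k, replace=False)
        truth = sum(0.3 * orthogonal_library[i].vector() for i in chosen)
        cells = make_cells(truth, 5, noise_sd=0.08, seed=100 + seed)
        sel = gbfs_select(cells, orthogonal_library, method="pooled")
        best_bic, best_set = brute_force_best_bic(cells, orthogonal_library)
        assert sel.best_bic == pytest.approx(best_bic, abs=1e-9)
        assert set(sel.contributing) == set(best_set)

    def test_pure_noise_yields_empty_selection(self, library):
        """With no POI structure the null model wins and the contributing
        set is empty."""
        rng = np.random.default_rng(12)
        cells = make_cells(np.zeros(78), 8, noise_sd=0.05, seed=12)
        sel = gbfs_select(cells, library)
        assert sel.contributing == ()
        assert sel.best_bic == sel.null_bic
        assert sel.n_paths == 1
        with pytest.raises(ValueError, match="no contributing POIs"):
            reconstruct_component(sel, library)

    def test_selection_invariant_to_common_rescaling(self, library):
        cells = make_cells(0.3 * library[5].vector(), 6, noise_sd=0.05, seed=10)
        sel1 = gbfs_select(cells, library)
        scaled = make_cells(0.3 * library[5].vector(), 6, noise_sd=0.05, seed=10)
        for c in scaled:
            c.values = 2.0 * c.values
        sel2 = gbfs_select(scaled, library)
        assert sel1.best_path == sel2.best_path


class TestReconstruct:
    def _selection(self, cells, library):
        return gbfs_select(cells, library)

    def test_single_poi_identity_combination(self, library):
        poi = {p.name: p for p in library}["RM_NS"]
        cells = make_cells(poi.vector(), 3)
        sel = gbfs_select(cells, [poi])
        recon = reconstruct_component(sel, [poi])
        assert np.allclose(recon, poi.vector(), atol=1e-8)

    def test_matches_matrix_multiplication_oracle(self, library):
        cells = make_cells(
            0.25 * library[4].vector() + 0.12 * library[6].vector(),
            8, noise_sd=0.04, seed=11,
        )
        sel = gbfs_select(cells, library)
        recon = reconstruct_component(sel, library)
        # independent linear-algebra oracle over the fit's stored pieces:
        # between-condition POI parts + baseline + reliability columns
        d = _diag_indicator()
        chosen = [p for p in library if p.name in sel.contributing]
        off = np.stack([np.where(d > 0, 0.0, p.vector()) for p in chosen])
        betas = np.array([sel.weights[p.name] for p in chosen])
        oracle = off.T @ betas + sel.best_fit.baseline * d
        for pat, gamma in zip(sel.best_fit.diag_patterns,
                              sel.best_fit.diag_weights):
            oracle = oracle + gamma * pat
        assert np.allclose(recon, oracle, atol=1e-10)

    def test_disjoint_support_arithmetic(self, orthogonal_library):
        from rsapcm.pcm_select import SelectionResult, ComponentFit

        a, b = orthogonal_library[0], orthogonal_library[1]
        fit = ComponentFit(poi_names=(a.name, b.name),
                           weights=np.array([0.3, -0.1]), intercept=0.0,
                           bic=0.0, loglik=0.0, n_obs=78, method="pooled",
                           baseline=math.nan)
        sel = SelectionResult(paths=[((a.name, b.name), 0.0)],
                              best_path=(a.name, b.name), best_bic=0.0,
                              contributing=(a.name, b.name), best_fit=fit,
                              n_paths=1, delta=2.0)
        recon = reconstruct_component(sel, orthogonal_library)
        assert set(np.round(np.unique(recon), 12)) == {-0.1, 0.0, 0.3}


class TestHoldoutFit:
    def test_nine_subjects_df_700(self, library):
        recon = 0.3 * library[4].vector()
        ho = make_cells(recon, 9, noise_sd=0.1, seed=12)
        fit = holdout_fit(recon, ho)
        assert fit.df_num == 1 and fit.df_den == 700
        assert 0.0 <= fit.r2 <= 1.0

    def test_perfect_fit(self, library):
        recon = 0.3 * library[4].vector() + 0.1 * library[6].vector()
        ho = make_cells(recon, 2)
        fit = holdout_fit(recon, ho)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_recon_rejected(self, library):
        ho = make_cells(np.zeros(78), 2, noise_sd=0.1, seed=13)
        with pytest.raises(ValueError, match="variance"):
            holdout_fit(np.ones(78), ho)

    def test_agrees_with_statsmodels_ols(self, library):
        import statsmodels.api as sm

        recon = 0.3 * library[4].vector()
        ho = make_cells(recon, 4, noise_sd=0.1, seed=14)
        fit = holdout_fit(recon, ho)
        y = np.concatenate([c.values for c in ho])
        x = sm.add_constant(np.tile(recon, 4))
        res = sm.OLS(y, x).fit()
        assert fit.r2 == pytest.approx(res.rsquared, abs=1e-10)
        assert fit.slope == pytest.approx(res.params[1], abs=1e-10)
        assert fit.p_value == pytest.approx(res.f_pvalue, rel=1e-6)


class TestEndToEndSelection:
    def test_planted_mixture_recovered_from_simulated_betas(self, library):
        """Betas -> similarity -> GBFS recovers the planted components."""
        cfg = GeneratorConfig(
            n_subjects=8, n_voxels=1500,
            poi_weights={"RM_NS": 0.4, "IV_All": 0.3}, rng_seed=15,
        )
        ds = simulate_dataset(cfg, library)
        cells = dataset_cells(ds, "ROI")
        sel = gbfs_select(cells, library)
        assert set(sel.contributing) == {"RM_NS", "IV_All"}
        assert sel.weights["RM_NS"] > 0 and sel.weights["IV_All"] > 0
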