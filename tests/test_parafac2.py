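"""PARAFAC2 fitting: recovery, diagnostics, invariants, independent oracle."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from chromdecon.parafac2 import (
    FitSettings,
    core_consistency,
    fit_parafac2,
    residual_summary,
)
from conftest import generic_cube


def best_match_cosines(est, truth):
    """Cosine of each true column vs its best-assigned estimated column."""
    est = est / np.maximum(np.linalg.norm(est, axis=0), 1e-300)
    truth = truth / np.maximum(np.linalg.norm(truth, axis=0), 1e-300)
    cos = truth.T @ est
    rows, cols = linear_sum_assignment(-cos)
    return cos[rows, cols]


class TestRecovery:
    def test_rank_one_cube_recovers_multipliers(self):
        """Sample loadings of a noiseless multiplier-only set recover the
        applied multipliers (no retention shifts, so no interpolation
        attenuation)."""
        from chromdecon.augment import ReplicateSpec, make_replicate_set
        from chromdecon.intervals import Interval, build_cube
        from conftest import MULTIPLIERS, make_single_analyte

        chrom, _ = make_single_analyte()
        specs = [ReplicateSpec(0.0, m) for m in MULTIPLIERS[1:]]
        repset = make_replicate_set(chrom, specs=specs)
        cube = build_cube(repset, Interval(0.175, 0.24, "mult-only"))
        mults = MULTIPLIERS
        model = fit_parafac2(cube, 1, FitSettings(rng_seed=0))
        assert model.fit_percent >= 99.99
        loadings = model.sample_loadings[:, 0]
        scaled = loadings / loadings[0]
        rel_dev = np.abs(scaled - np.array(mults)) / np.array(mults)
        assert rel_dev.max() < 0.01

    def test_two_component_generic_cube_recovers_spectra(self):
        """Orthogonal spectra come back at cosine >= 0.999 (full-rank C)."""
        cube, _, spectra, amounts = generic_cube(2, seed=3)
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        cos = best_match_cosines(model.spectral_loadings, spectra)
        assert cos.min() >= 0.999
        assert model.fit_percent >= 99.99

    def test_two_component_pseudo_replicate_cube(self, coelution_cube):
        """Co-eluting disjoint spectra resolved despite rank-one amounts."""
        cube, mults = coelution_cube
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        assert model.fit_percent > 99.9
        truth = np.zeros((cube.mz_axis.size, 2))
        from conftest import SPEC_A, SPEC_B

        truth[:, 0] = SPEC_A.normalize().to_dense(cube.mz_axis)
        truth[:, 1] = SPEC_B.normalize().to_dense(cube.mz_axis)
        cos = best_match_cosines(model.spectral_loadings, truth)
        assert cos.min() >= 0.999
        for r in range(2):
            corr = np.corrcoef(model.sample_loadings[:, r], mults)[0, 1]
            assert corr >= 0.999

    def test_fit_is_nested_in_component_count(self, coelution_cube):
        cube, _ = coelution_cube
        fits = [
            fit_parafac2(cube, r, FitSettings(rng_seed=1)).fit_percent
            for r in (1, 2)
        ]
        assert fits[0] <= fits[1]


class TestInvariants:
    def test_sse_history_monotone_nonincreasing(self, coelution_cube):
        cube, _ = coelution_cube
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        hist = model.sse_history
        assert np.all(np.diff(hist) <= 1e-9 * hist[0])

    def test_cross_product_constraint_holds(self, coelution_cube):
        cube, _ = coelution_cube
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        profiles = model.elution_profiles()
        ref = profiles[0].T @ profiles[0]
        scale = np.abs(ref).max()
        for p in profiles[1:]:
            assert np.abs(p.T @ p - ref).max() <= 1e-6 * scale

    def test_spectral_columns_unit_norm_and_nonnegative(self, coelution_cube):
        cube, _ = coelution_cube
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        norms = np.linalg.norm(model.spectral_loadings, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert model.spectral_loadings.min() >= 0
        assert model.sample_loadings.min() >= 0

    def test_fit_percent_matches_sse_bookkeeping(self, coelution_cube):
        cube, _ = coelution_cube
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        expected = 100.0 * (1.0 - model.sse / cube.total_sumsq())
        assert model.fit_percent == pytest.approx(expected, abs=1e-9)

    def test_deterministic_given_seed(self, single_analyte_cube):
        cube, _ = single_analyte_cube
        a = fit_parafac2(cube, 1, FitSettings(rng_seed=5))
        b = fit_parafac2(cube, 1, FitSettings(rng_seed=5))
        np.testing.assert_array_equal(a.spectral_loadings, b.spectral_loadings)
        assert a.sse == b.sse


class TestErrors:
    def test_component_count_out_of_range(self, single_analyte_cube):
        cube, _ = single_analyte_cube
        with pytest.raises(ValueError, match="n_components"):
            fit_parafac2(cube, 0)
        with pytest.raises(ValueError, match="n_components"):
            fit_parafac2(cube, 10_000)

    def test_all_zero_cube_rejected(self, single_analyte_cube):
        cube, _ = single_analyte_cube
        import copy

        dead = copy.deepcopy(cube)
        dead.slabs = [np.zeros_like(s) for s in dead.slabs]
        with pytest.raises(ValueError, match="all-zero"):
            fit_parafac2(dead, 1)


class TestCoreConsistency:
    def test_single_component_is_exactly_100(self, single_analyte_cube):
        cube, _ = single_analyte_cube
        model = fit_parafac2(cube, 1, FitSettings(rng_seed=0))
        assert model.core_consistency == pytest.approx(100.0, abs=1e-6)

    def test_correct_rank_generic_cube_above_99(self):
        cube, *_ = generic_cube(3, seed=5)
        model = fit_parafac2(cube, 3, FitSettings(rng_seed=0))
        assert model.core_consistency >= 99.0

    def test_overfactoring_detected_below_90(self, single_analyte_cube):
        """R=3 on one-component data collapses the diagnostic."""
        cube, _ = single_analyte_cube
        model = fit_parafac2(cube, 3, FitSettings(rng_seed=0))
        assert model.core_consistency < 90.0

    def test_pseudo_replicate_branch_stable_and_high(self, coelution_cube):
        """Rank-one sample mode uses the collapsed diagnostic, near 100."""
        cube, _ = coelution_cube
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        assert 90.0 <= model.core_consistency <= 100.0

    def test_never_exceeds_100(self):
        cube, *_ = generic_cube(2, seed=9, noise_sd=0.02)
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=2))
        assert model.core_consistency <= 100.0


class TestResidualSummary:
    def test_exact_fit_residuals_negligible(self, single_analyte_cube):
        cube, _ = single_analyte_cube
        model = fit_parafac2(cube, 1, FitSettings(rng_seed=0))
        resid = residual_summary(model, cube)
        cube_norm = np.sqrt(cube.total_sumsq())
        assert resid["per_member_norm"].max() < 1e-4 * cube_norm

    def test_sse_accounting_identity(self, coelution_cube):
        cube, _ = coelution_cube
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        resid = residual_summary(model, cube)
        assert resid["per_member_sq"].sum() == pytest.approx(
            model.sse, rel=1e-6, abs=1e-9 * cube.total_sumsq()
        )

    def test_noisy_cube_residuals_balanced(self):
        cube, *_ = generic_cube(2, seed=4, noise_sd=0.02)
        model = fit_parafac2(cube, 2, FitSettings(rng_seed=0))
        resid = residual_summary(model, cube)
        assert resid["balanced"]


def _reference_parafac2_sse(slabs, r, n_starts=4, iters=400, seed=0):
    """Independent brute-force direct-fit PARAFAC2 (unconstrained).

    Plain ALS written with explicit dense least squares (np.linalg.lstsq on
    full Khatri-Rao designs) and its own restart loop; shares no code with
    the package fitter.
    """
    rng = np.random.default_rng(seed)
    k = len(slabs)
    i, j = slabs[0].shape
    best = np.inf
    for _ in range(n_starts):
        h = rng.normal(size=(r, r))
        s = rng.normal(size=(j, r))
        c = np.abs(rng.normal(size=(k, r))) + 0.5
        for _ in range(iters):
            p = []
            y = np.empty((k, r, j))
            for kk in range(k):
                f = h @ np.diag(c[kk]) @ s.T
                u, _, vt = np.linalg.svd(slabs[kk] @ f.T,
                                         full_matrices=False)
                p.append(u @ vt)
                y[kk] = p[kk].T @ slabs[kk]
            # H: rows of Y unfolded against khatri-rao(C, S)
            design = np.vstack(
                [s * c[kk][None, :] for kk in range(k)]
            )  # (K J) x R
            target = np.vstack([y[kk].T for kk in range(k)])  # (K J) x R
            h = np.linalg.lstsq(design, target, rcond=None)[0].T
            design_s = np.vstack(
                [h * c[kk][None, :] for kk in range(k)]
            )  # (K R) x R
            target_s = np.vstack([y[kk] for kk in range(k)])  # (K R) x J
            s = np.linalg.lstsq(design_s, target_s, rcond=None)[0].T
            for kk in range(k):
                design_c = np.stack(
                    [np.outer(h[:, q], s[:, q]).ravel() for q in range(r)],
                    axis=1,
                )
                c[kk] = np.linalg.lstsq(design_c, y[kk].ravel(),
                                        rcond=None)[0]
        sse = sum(
            float(np.sum((x - pp @ h @ np.diag(cc) @ s.T) ** 2))
            for x, pp, cc in zip(slabs, p, c)
        )
        best = min(best, sse)
    return best


def test_sse_agrees_with_independent_reference_fit():
    """Package SSE within 1% of a brute-force reference on random cubes."""
    cube, *_ = generic_cube(2, seed=12, k=4, i=16, j=24, noise_sd=0.05)
    settings = FitSettings(
        rng_seed=0, nonneg_elution=False, nonneg_spectral=False,
        nonneg_sample=False, n_starts=4,
    )
    model = fit_parafac2(cube, 2, settings)
    ref_sse = _reference_parafac2_sse(
        [np.asarray(s) for s in cube.slabs], 2, seed=1
    )
    denom = max(ref_sse, 1e-300)
    assert abs(model.sse - ref_sse) / denom < 0.01
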