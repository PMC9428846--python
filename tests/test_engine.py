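import numpy as np
import pytest
import scipy.linalg as sla
from scipy.stats import multivariate_normal

from blmemap.design import (
    AugmentedSystem,
    TrajectorySpec,
    build_augmented_system,
    build_level1_design,
    build_level2_design,
)
from blmemap.engine import (
    CovarianceComponents,
    compute_posterior,
    estimate_hyperparameters,
    fit_voxel_field,
    marginal_log_likelihood,
)
from blmemap.io import ImageSeries, ValidationError

from conftest import manifest_from, simulate_lme_cohort


def _build(manifest, y, spec=None):
    spec = spec or TrajectorySpec(covariates=())
    l1 = build_level1_design(manifest, spec)
    l2 = build_level2_design(manifest, spec)
    return build_augmented_system(l1, l2, y), l1, l2


def scalar_conjugate_system():
    """One parameter, prior N(0, 1), single unit-design observation y = 2."""
    return AugmentedSystem(
        y_bar=np.array([2.0, 0.0]),
        X_bar=np.array([[1.0], [1.0]]),
        component_masks=[np.array([True, False]), np.array([False, True])],
        component_names=["noise", "intercept"],
        flat_prior_var=0.0,
        n_obs=1, n_random=1, n_fixed=0,
    )


def noise_only_system(n=24, q=2, seed=4):
    """Polynomial regression with a flat coefficient prior; only the scan
    noise variance is estimable."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 3, n)
    X = np.vander(t, N=q, increasing=True)
    y = X @ np.array([1.0, -0.4][:q]) + rng.normal(0, 0.7, n)
    X_bar = np.vstack([X, np.eye(q)])
    mask = np.zeros(n + q, dtype=bool)
    mask[:n] = True
    return AugmentedSystem(
        y_bar=np.concatenate([y, np.zeros(q)]),
        X_bar=X_bar,
        component_masks=[mask],
        component_names=["noise"],
        flat_prior_var=1e8 * float(np.var(y)),
        n_obs=n, n_random=0, n_fixed=q,
    )


class TestPosterior:
    def test_scalar_conjugate_closed_form(self):
        sys = scalar_conjugate_system()
        comps = CovarianceComponents([1.0, 1.0], sys.component_names, 0.0)
        post = compute_posterior(sys, comps)
        assert post.eta[0] == pytest.approx(1.0, abs=1e-12)
        assert post.C[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_flat_prior_matches_gls(self):
        # one subject, five scans, essentially flat priors everywhere
        man = manifest_from([("a", t) for t in [0.0, 0.6, 1.1, 2.0, 2.8]])
        rng = np.random.default_rng(2)
        t = man.times_for("a")
        y = 1.5 - 0.3 * t + rng.normal(0, 0.2, 5)
        sys, l1, l2 = _build(man, y)
        comps = CovarianceComponents(
            [0.04, 1e8, 1e8], sys.component_names, 1e8
        )
        post = compute_posterior(sys, comps)
        X = l1.X1
        beta_gls = np.linalg.solve(X.T @ X, X.T @ y)
        fitted = post.eta_random + l2.X2 @ post.eta_fixed
        np.testing.assert_allclose(fitted, beta_gls, rtol=1e-4)

    def test_zero_data_gives_zero_mean(self, two_subject_manifest):
        sys, *_ = _build(two_subject_manifest, np.zeros(5))
        comps = CovarianceComponents([0.1, 0.2, 0.3], sys.component_names,
                                     sys.flat_prior_var)
        post = compute_posterior(sys, comps)
        np.testing.assert_allclose(post.eta, 0.0, atol=1e-14)

    def test_precision_decomposition(self, two_subject_manifest):
        rng = np.random.default_rng(3)
        sys, *_ = _build(two_subject_manifest, rng.normal(size=5))
        comps = CovarianceComponents([0.3, 0.5, 0.4], sys.component_names,
                                     sys.flat_prior_var)
        post = compute_posterior(sys, comps)
        d = np.concatenate(
            [np.full(5, 0.3), [0.5, 0.4, 0.5, 0.4],
             [sys.flat_prior_var] * 2]
        )
        A = sys.X_bar.T @ (sys.X_bar / d[:, None])
        np.testing.assert_allclose(np.linalg.inv(post.C), A, rtol=1e-8,
                                   atol=1e-8)


class TestMarginalLikelihood:
    def test_matches_dense_marginal_gaussian(self):
        man = manifest_from([("a", 0.0), ("a", 1.0), ("b", 0.0), ("b", 1.0)])
        rng = np.random.default_rng(0)
        y = rng.normal(size=4)
        sys, l1, l2 = _build(man, y)
        comps = CovarianceComponents([0.5, 0.3, 0.2], sys.component_names,
                                     sys.flat_prior_var)
        value = marginal_log_likelihood(sys, comps)
        X_top = np.hstack([l1.X1, l1.X1 @ l2.X2])
        C_theta = np.diag([0.3, 0.2, 0.3, 0.2,
                           sys.flat_prior_var, sys.flat_prior_var])
        V = X_top @ C_theta @ X_top.T + 0.5 * np.eye(4)
        direct = multivariate_normal(mean=np.zeros(4), cov=V).logpdf(y)
        assert value == pytest.approx(direct, abs=1e-7)

    def test_invariant_to_subject_order(self):
        # relabel subjects so the canonically sorted system stacks the
        # same subjects' blocks in the opposite order
        recs = [("a", 0.0), ("a", 1.0), ("b", 0.0), ("b", 1.0), ("b", 2.0)]
        rng = np.random.default_rng(1)
        y = rng.normal(size=5)
        sys, *_ = _build(manifest_from(recs), y)
        swapped = [("b", 0.0), ("b", 1.0), ("a", 0.0), ("a", 1.0), ("a", 2.0)]
        perm_y = np.concatenate([y[2:], y[:2]])
        sys_p, *_ = _build(manifest_from(swapped), perm_y)
        comps = CovarianceComponents(
            [0.4, 0.2, 0.1], sys.component_names, sys.flat_prior_var
        )
        a = marginal_log_likelihood(sys, comps)
        b = marginal_log_likelihood(sys_p, comps)
        assert a == pytest.approx(b, abs=1e-9)

    def test_singular_covariance_reported(self):
        sys = scalar_conjugate_system()
        with pytest.raises(Exception, match="singular"):
            marginal_log_likelihood(
                sys,
                CovarianceComponents([0.0, 0.0], sys.component_names, 0.0),
            )


class TestEM:
    def test_ascent_property(self):
        man, y, _ = simulate_lme_cohort(20, 4, (1.0, 0.5, 0.2))
        sys, *_ = _build(man, y)
        comps = estimate_hyperparameters(sys)
        diffs = np.diff(comps.log_evidence_trace)
        assert np.all(diffs >= -1e-8)
        assert comps.converged

    def test_noise_only_matches_grid_search(self):
        sys = noise_only_system()
        comps = estimate_hyperparameters(sys, max_iter=256)
        grid = np.logspace(-3, 3, 61)
        values = [
            marginal_log_likelihood(
                sys, CovarianceComponents([g], ["noise"], sys.flat_prior_var)
            )
            for g in grid
        ]
        best = grid[int(np.argmax(values))]
        step = np.log10(grid[1] / grid[0])
        assert abs(np.log10(comps.lambdas[0] / best)) <= step + 1e-9

    def test_scale_equivariance(self):
        man, y, _ = simulate_lme_cohort(15, 4, (1.0, 0.5, 0.2))
        sys, *_ = _build(man, y)
        comps = estimate_hyperparameters(sys)
        c = 3.0
        sys2, *_ = _build(man, c * y)
        comps2 = estimate_hyperparameters(sys2)
        # stopping tests depend weakly on the data scale; the fixed point
        # itself is exactly equivariant
        np.testing.assert_allclose(comps2.lambdas, c**2 * comps.lambdas,
                                   rtol=2e-2)

    def test_recovery_within_quarter(self):
        # single replicate sanity check; the multi-replicate median version
        # lives in the acceptance suite
        man, y, _ = simulate_lme_cohort(
            60, 4, (1.0, 0.5, 0.2), rng=np.random.default_rng(42)
        )
        sys, *_ = _build(man, y)
        lam = estimate_hyperparameters(sys, max_iter=512).lambdas
        assert lam[0] == pytest.approx(1.0, rel=0.35)

    def test_posterior_slopes_track_truth(self):
        man, y, slopes = simulate_lme_cohort(
            60, 4, (1.0, 0.5, 0.2), rng=np.random.default_rng(9)
        )
        sys, l1, l2 = _build(man, y)
        comps = estimate_hyperparameters(sys)
        post = compute_posterior(sys, comps)
        fitted = (post.eta_random + l2.X2 @ post.eta_fixed)[1::2]
        assert np.corrcoef(fitted, slopes)[0, 1] > 0.8

    def test_mixedlm_cross_check(self):
        # independent route: statsmodels MixedLM restricted to the same
        # diagonal random-effects structure should produce nearly the same
        # variance components and fixed effects
        import statsmodels.formula.api as smf
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        man, y, _ = simulate_lme_cohort(
            40, 4, (1.0, 0.4, 0.15), rng=np.random.default_rng(11)
        )
        sys, l1, l2 = _build(man, y)
        comps = estimate_hyperparameters(sys, max_iter=2000, tol=1e-12)
        df = man.data.copy()
        df["y"] = y
        df["t"] = df["scan_time"]
        model = smf.mixedlm("y ~ t", df, groups=df["subject_id"],
                            re_formula="~t")
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2)
        )
        fit = model.fit(reml=True, free=free)
        assert comps.lambdas[0] == pytest.approx(fit.scale, rel=0.02)
        np.testing.assert_allclose(comps.lambdas[1:], np.diag(fit.cov_re),
                                   rtol=0.05)
        post = compute_posterior(sys, comps)
        np.testing.assert_allclose(
            post.eta_fixed, [fit.params["Intercept"], fit.params["t"]],
            rtol=0.02, atol=0.02,
        )

    def test_too_small_system_rejected(self):
        sys = noise_only_system(n=1, q=2)
        with pytest.raises(ValidationError):
            estimate_hyperparameters(sys)

    def test_shrinkage_between_ols_and_group_mean(self):
        # With centered (orthogonal) time columns and a diagonal
        # random-effect covariance, shrinkage is coordinate-wise: every
        # subject's posterior slope lies between its own OLS slope and the
        # group mean slope.
        from blmemap.design import Level1Design, Level2Design

        rng = np.random.default_rng(21)
        S, n = 12, 4
        t = np.array([-1.5, -0.5, 0.5, 1.5])
        block = np.column_stack([np.ones(n), t])
        X1 = sla.block_diag(*([block] * S))
        slices = [(slice(i * n, (i + 1) * n), slice(2 * i, 2 * i + 2))
                  for i in range(S)]
        l1 = Level1Design(X1=X1, subject_slices=slices,
                          subjects=[f"s{i}" for i in range(S)], p=2)
        l2 = Level2Design(X2=np.tile(np.eye(2), (S, 1)),
                          covariate_values=np.empty((S, 0)),
                          covariate_names=(), p=2)
        y = np.concatenate([
            rng.normal(2.0, np.sqrt(0.5))
            + (rng.normal(0.5, np.sqrt(0.2))) * t
            + rng.normal(0, 1.0, n)
            for _ in range(S)
        ])
        sys = build_augmented_system(l1, l2, y)
        comps = estimate_hyperparameters(sys)
        post = compute_posterior(sys, comps)
        fitted = post.eta_random + l2.X2 @ post.eta_fixed
        group_slope = post.eta_fixed[1]
        for i, (r, c) in enumerate(l1.subject_slices):
            ols = np.linalg.lstsq(X1[r, c], y[r], rcond=None)[0]
            lo, hi = sorted([ols[1], group_slope])
            assert lo - 1e-9 <= fitted[2 * i + 1] <= hi + 1e-9


class TestVoxelField:
    @staticmethod
    def _series_from_matrix(Y, man):
        """Wrap an (N, V) matrix as an ImageSeries on a flat 1-D grid."""
        V = Y.shape[1]
        values = {}
        row = 0
        for s in man.subjects:
            n = len(man.rows_for(s))
            values[s] = Y[row:row + n]
            row += n
        return ImageSeries(
            values=values, grid_shape=(V, 1, 1), voxel_dims=(1.0, 1.0, 1.0),
            mask_index=np.stack(
                [np.arange(V), np.zeros(V, int), np.zeros(V, int)], axis=1
            ),
        )

    def test_single_voxel_matches_dense_path(self, no_cov_spec):
        from blmemap.deviation import collapse_to_subject

        man, y, _ = simulate_lme_cohort(
            10, 4, (0.5, 0.3, 0.1), rng=np.random.default_rng(8)
        )
        series = self._series_from_matrix(y[:, None], man)
        fld = fit_voxel_field(series, man, no_cov_spec, max_iter=2000,
                              tol=1e-12)
        sys, l1, l2 = _build(man, y)
        comps = estimate_hyperparameters(sys, max_iter=2000, tol=1e-12)
        post = compute_posterior(sys, comps)
        np.testing.assert_allclose(fld.lambdas[0], comps.lambdas, rtol=2e-3)
        for i in range(3):
            sp = collapse_to_subject(post, l2, i, comps.lambdas[0])
            np.testing.assert_allclose(fld.eta1[0, i], sp.eta1, rtol=1e-3,
                                       atol=1e-6)
            np.testing.assert_allclose(fld.C1[0, i], sp.C1, rtol=5e-3,
                                       atol=1e-8)

    def test_voxel_exchangeability(self, no_cov_spec):
        rng = np.random.default_rng(13)
        man, y0, _ = simulate_lme_cohort(8, 3, (0.5, 0.3, 0.1), rng=rng)
        Y = np.column_stack([y0, y0 + rng.normal(0, 1, y0.size),
                             2 * y0, y0 - 1])
        perm = [2, 0, 3, 1]
        a = fit_voxel_field(self._series_from_matrix(Y, man), man, no_cov_spec)
        b = fit_voxel_field(
            self._series_from_matrix(Y[:, perm], man), man, no_cov_spec
        )
        np.testing.assert_allclose(b.eta1, a.eta1[perm], rtol=1e-10)
        np.testing.assert_allclose(b.lambdas, a.lambdas[perm], rtol=1e-10)

    def test_constant_zero_voxel_flagged(self, no_cov_spec):
        man, y, _ = simulate_lme_cohort(8, 3, (0.5, 0.3, 0.1))
        Y = np.column_stack([y, np.zeros_like(y)])
        fld = fit_voxel_field(self._series_from_matrix(Y, man), man,
                              no_cov_spec)
        assert not fld.flagged[0] and fld.flagged[1]
        assert np.isnan(fld.eta1[1]).all()

    def test_phantom_grid_returns_all_posteriors(self, no_cov_spec):
        rng = np.random.default_rng(17)
        man, y, _ = simulate_lme_cohort(10, 4, (0.3, 0.2, 0.05), rng=rng)
        Y = y[:, None] + rng.normal(0, 0.5, size=(y.size, 512))
        fld = fit_voxel_field(self._series_from_matrix(Y, man), man,
                              no_cov_spec, max_iter=256)
        assert fld.n_voxels == 512
        assert np.isfinite(fld.eta1).all()
        assert fld.converged.mean() > 0.9
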