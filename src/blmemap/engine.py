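"""Parametric-empirical-Bayes estimation for the two-level trajectory model.

The stacked system ``y_bar = X_bar @ theta + eps_bar`` has block-diagonal
error covariance ``C_eps = sum_k lambda_k Q_k`` (plus a fixed, effectively
flat prior block on the second-level coefficients).  Hyperparameters
``lambda`` are estimated by expectation-maximization on the marginal
likelihood of the data; because the flat prior keeps the fixed effects
essentially unregularized, the objective behaves like a restricted (REML)
criterion for the variance components.  Given ``lambda``, the posterior
over ``theta`` is Gaussian:

    C_post = (X_bar' C_eps^-1 X_bar)^-1
    eta    = C_post @ X_bar' C_eps^-1 y_bar

Two code paths compute the same fixed point:

* a dense path operating on one :class:`~blmemap.design.AugmentedSystem`
  (used for small systems and as the reference in tests), and
* a batched path (:func:`fit_voxel_field`) that exploits the per-subject
  block structure through a Schur complement on the small second-level
  block, vectorized over all masked voxels of an image series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .design import (
    AugmentedSystem,
    TrajectorySpec,
    build_augmented_system,
    build_level1_design,
    build_level2_design,
)
from .io import CohortManifest, ImageSeries, ValidationError


class NumericalError(RuntimeError):
    """A covariance became singular or indefinite during estimation."""


@dataclass
class CovarianceComponents:
    """Estimated covariance-component scales for one augmented system.

    ``lambdas`` aligns with the system's ``component_masks`` (scan noise
    first, then one variance per trajectory coordinate).  The second-level
    prior variance is carried separately in ``flat_prior_var`` and is held
    fixed during EM.
    """

    lambdas: np.ndarray
    names: list[str]
    flat_prior_var: float
    n_iter: int = 0
    converged: bool = True
    log_evidence_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if (self.lambdas < 0).any():
            raise ValidationError("component scales must be non-negative")


@dataclass
class GroupPosterior:
    """Gaussian posterior over the stacked parameters [eps2; theta2]."""

    eta: np.ndarray          # (S*p + q2,)
    C: np.ndarray            # (S*p + q2, S*p + q2), symmetric PD
    n_random: int
    n_fixed: int

    @property
    def eta_fixed(self) -> np.ndarray:
        return self.eta[self.n_random:]

    @property
    def eta_random(self) -> np.ndarray:
        return self.eta[: self.n_random]


@dataclass
class PosteriorField:
    """Per-voxel posterior summaries for every subject in one group fit.

    Only subject-level means/covariances and hyperparameters are kept, to
    bound memory at image scale.  Axes: voxel, subject, coordinate.
    """

    subjects: list[str]
    p: int
    eta1: np.ndarray         # (V, S, p) subject trajectory posterior means
    C1: np.ndarray           # (V, S, p, p) subject posterior covariances
    noise_var: np.ndarray    # (V,)
    lambdas: np.ndarray      # (V, K)
    group_eta: np.ndarray    # (V, q2)
    group_cov: np.ndarray    # (V, q2, q2)
    converged: np.ndarray    # (V,) bool
    n_iter: np.ndarray       # (V,) int
    flagged: np.ndarray      # (V,) bool — constant/zero voxels skipped
    log_evidence: np.ndarray  # (V,)

    @property
    def n_voxels(self) -> int:
        return self.eta1.shape[0]

    def subject_index(self, subject_id: str) -> int:
        return self.subjects.index(subject_id)


def _error_diag(sys: AugmentedSystem, comps: CovarianceComponents) -> np.ndarray:
    """Diagonal of C_eps over the augmented rows."""
    d = np.zeros(sys.y_bar.shape[0])
    for lam, mask in zip(comps.lambdas, sys.component_masks):
        d[mask] += lam
    d[sys.fixed_rows()] += comps.flat_prior_var
    if (d <= 0).any():
        raise NumericalError(
            "singular error covariance: zero diagonal entries "
            f"(min lambda = {comps.lambdas.min():.3e})"
        )
    return d


def _posterior_factors(sys, d):
    """Cholesky of the posterior precision plus the weighted projections."""
    Xw = sys.X_bar / d[:, None]
    A = sys.X_bar.T @ Xw
    A = 0.5 * (A + A.T)
    try:
        cho = sla.cho_factor(A, lower=True)
    except sla.LinAlgError as exc:
        raise NumericalError(
            f"indefinite posterior precision (cond={np.linalg.cond(A):.3e})"
        ) from exc
    b = Xw.T @ sys.y_bar
    eta = sla.cho_solve(cho, b)
    return A, cho, b, eta


def marginal_log_likelihood(sys: AugmentedSystem, comps: CovarianceComponents) -> float:
    """Log-density of the data under the marginal Gaussian, theta integrated out.

    Equals ``log N(y; 0, X C_theta X' + C_eps1)`` where ``C_theta`` stacks
    the random-effect variances and the (large but finite) flat prior;
    evaluated through the augmented system without forming the N x N
    marginal covariance.
    """
    d = _error_diag(sys, comps)
    A, cho, b, eta = _posterior_factors(sys, d)
    logdet_A = 2.0 * np.sum(np.log(np.diag(cho[0])))
    quad = float(sys.y_bar @ (sys.y_bar / d)) - float(eta @ b)
    return -0.5 * (
        sys.n_obs * np.log(2 * np.pi) + np.sum(np.log(d)) + logdet_A + quad
    )


def compute_posterior(sys: AugmentedSystem, comps: CovarianceComponents) -> GroupPosterior:
    """Gaussian posterior mean and covariance over the stacked parameters.

    Solved through a Cholesky factorization of the posterior precision;
    the output covariance is explicitly symmetrized.
    """
    d = _error_diag(sys, comps)
    A, cho, b, eta = _posterior_factors(sys, d)
    C = sla.cho_solve(cho, np.eye(A.shape[0]))
    C = 0.5 * (C + C.T)
    return GroupPosterior(
        eta=eta, C=C, n_random=sys.n_random, n_fixed=sys.n_fixed
    )


def _default_init(var_y: float, names: list[str]) -> np.ndarray:
    """Moment-flavoured starting values: split the data variance between
    noise and intercepts, start higher-order coordinates smaller."""
    init = []
    for name in names:
        if name in ("noise", "intercept"):
            init.append(0.5 * var_y)
        else:
            init.append(0.1 * var_y)
    return np.asarray(init)


def estimate_hyperparameters(
    sys: AugmentedSystem,
    *,
    init: np.ndarray | None = None,
    max_iter: int = 128,
    tol: float = 1e-6,
) -> CovarianceComponents:
    """EM estimation of the covariance-component scales.

    Each iteration computes the Gaussian posterior at the current scales
    (E-step) and re-estimates every scale from the expected squared error
    on its support (M-step); the update keeps scales positive by
    construction and monotonically increases the marginal likelihood.
    Convergence: relative change in log-evidence below ``tol``.  The flat
    second-level prior is held fixed throughout.
    """
    if not sys.component_masks:
        raise ValidationError("component basis is empty")
    if sys.n_obs <= sys.n_fixed:
        raise ValidationError(
            f"system with {sys.n_obs} observations cannot identify "
            f"{sys.n_fixed} second-level coefficients"
        )
    y = sys.y
    var_y = float(np.var(y))
    if var_y <= 0:
        var_y = 1.0
    floor = 1e-10 * var_y
    lam = _default_init(var_y, sys.component_names) if init is None else np.asarray(
        init, dtype=float
    ).copy()
    sizes = np.array([int(m.sum()) for m in sys.component_masks])

    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        comps = CovarianceComponents(lam, sys.component_names, sys.flat_prior_var)
        d = _error_diag(sys, comps)
        A, cho, b, eta = _posterior_factors(sys, d)
        logdet_A = 2.0 * np.sum(np.log(np.diag(cho[0])))
        quad = float(sys.y_bar @ (sys.y_bar / d)) - float(eta @ b)
        F = -0.5 * (
            sys.n_obs * np.log(2 * np.pi) + np.sum(np.log(d)) + logdet_A + quad
        )
        trace.append(F)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (1 + abs(F)):
            converged = True
            break
        # M-step: expected squared augmented error on each component's support.
        C = sla.cho_solve(cho, np.eye(A.shape[0]))
        r = sys.y_bar - sys.X_bar @ eta
        row_quad = np.einsum("ij,jk,ik->i", sys.X_bar, C, sys.X_bar)
        e2 = r**2 + row_quad
        lam = np.maximum(
            np.array([e2[m].sum() for m in sys.component_masks]) / sizes, floor
        )

    return CovarianceComponents(
        lambdas=lam,
        names=list(sys.component_names),
        flat_prior_var=sys.flat_prior_var,
        n_iter=n_iter,
        converged=converged,
        log_evidence_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# Batched voxelwise path
# ---------------------------------------------------------------------------

def _batch_inv(M: np.ndarray) -> np.ndarray:
    """Inverse of stacked symmetric matrices; analytic fast path for 2x2."""
    p = M.shape[-1]
    if p == 1:
        return 1.0 / M
    if p == 2:
        a = M[..., 0, 0]
        b = M[..., 0, 1]
        d = M[..., 1, 1]
        det = a * d - b * b
        out = np.empty_like(M)
        out[..., 0, 0] = d
        out[..., 1, 1] = a
        out[..., 0, 1] = -b
        out[..., 1, 0] = -b
        return out / det[..., None, None]
    return np.linalg.inv(M)


def _batch_logdet(M: np.ndarray) -> np.ndarray:
    p = M.shape[-1]
    if p == 1:
        return np.log(M[..., 0, 0])
    if p == 2:
        det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] ** 2
        return np.log(det)
    return np.linalg.slogdet(M)[1]


def fit_voxel_field(
    series: ImageSeries,
    manifest: CohortManifest,
    spec: TrajectorySpec | None = None,
    *,
    flat_prior_scale: float = 1e6,
    max_iter: int = 64,
    tol: float = 1e-6,
    init_lambdas: np.ndarray | None = None,
) -> PosteriorField:
    """Fit the two-level model independently at every masked voxel.

    All voxels share the design matrices; per-voxel EM runs vectorized
    across the voxel axis, with each subject's p x p precision block
    inverted analytically and the small second-level block handled by a
    Schur complement, so cost scales with ``S * p^3`` per voxel rather
    than with the cube of the full parameter count.  Voxels whose signal
    is constant (e.g. all zero) are skipped and flagged.
    """
    spec = spec or TrajectorySpec()
    level1 = build_level1_design(manifest, spec)
    level2 = build_level2_design(manifest, spec)
    p, S, q = level1.p, level1.n_subjects, level2.q2
    blocks = level1.blocks()
    X2b = np.stack([level2.subject_block(i) for i in range(S)])  # (S, p, q)

    Y = series.stacked(manifest)                                  # (N, V)
    N, V = Y.shape
    if N != level1.n_obs:
        raise ValidationError("image series and manifest row counts disagree")

    # Per-subject fixed reductions.
    G = np.stack([b.T @ b for b in blocks])                       # (S, p, p)
    GX2 = np.einsum("sij,sjk->sik", G, X2b)                       # (S, p, q)
    X2GX2 = np.einsum("sji,sjk->ik", X2b, GX2)                    # (q, q)
    starts = np.cumsum([0] + [b.shape[0] for b in blocks])
    Ysub = [Y[starts[i]:starts[i + 1]] for i in range(S)]
    B1 = np.stack([blocks[i].T @ Ysub[i] for i in range(S)])      # (S, p, V)
    B1v = np.ascontiguousarray(B1.transpose(2, 0, 1))             # (V, S, p)
    X2tb = np.einsum("sji,sjv->iv", X2b, B1).T                    # (V, q)
    yty = np.einsum("nv,nv->v", Y, Y)

    var_v = Y.var(axis=0)
    flagged = var_v <= 0
    var_safe = np.where(flagged, 1.0, var_v)
    flat_v = flat_prior_scale * var_safe                          # (V,)
    floor_v = 1e-10 * var_safe

    names = ["noise", "intercept", "slope"][: p + 1] + [
        f"t^{k}" for k in range(2, p)
    ]
    K = 1 + p
    # Method-of-moments start: pooled residual variance around per-subject
    # OLS lines for the noise, between-subject spread of the OLS
    # coefficients (minus their estimation noise) for the random effects.
    # Subjects with no residual degrees of freedom are left out.
    lam = np.empty((V, K))
    ols_full = [i for i in range(S) if blocks[i].shape[0] > p]
    if init_lambdas is not None:
        if init_lambdas.shape != (V, K):
            raise ValidationError(
                f"init_lambdas shape {init_lambdas.shape} != ({V}, {K})"
            )
        lam[:] = np.maximum(init_lambdas, floor_v[:, None])
    elif len(ols_full) >= 2:
        rss0 = np.zeros(V)
        dof = 0
        coefs = np.empty((len(ols_full), p, V))
        unc = np.empty((len(ols_full), p))
        for j, i in enumerate(ols_full):
            pinv = np.linalg.pinv(blocks[i])
            coefs[j] = pinv @ Ysub[i]
            resid = Ysub[i] - blocks[i] @ coefs[j]
            rss0 += np.einsum("nv,nv->v", resid, resid)
            dof += blocks[i].shape[0] - p
            unc[j] = np.diag(pinv @ pinv.T)
        lam0 = np.maximum(rss0 / max(dof, 1), 1e-3 * var_safe)
        lam[:, 0] = lam0
        spread = coefs.var(axis=0, ddof=1)            # (p, V)
        est_noise = lam0[None, :] * unc.mean(axis=0)[:, None]
        lam[:, 1:] = np.maximum(spread - est_noise, 0.05 * var_safe[None]).T
    else:
        for k, name in enumerate(names):
            lam[:, k] = (0.5 if name in ("noise", "intercept") else 0.1) * var_safe
    log_floor = np.log(floor_v)

    # Outputs.
    eta1_out = np.full((V, S, p), np.nan)
    C1_out = np.full((V, S, p, p), np.nan)
    geta_out = np.full((V, q), np.nan)
    gcov_out = np.full((V, q, q), np.nan)
    conv_out = np.zeros(V, dtype=bool)
    iter_out = np.zeros(V, dtype=int)
    F_out = np.full(V, np.nan)

    active = np.flatnonzero(~flagged)
    F_prev = np.full(V, -np.inf)
    diag_idx = np.arange(p)

    def e_step(idx):
        l0 = lam[idx, 0]
        lre = lam[idx, 1:]
        Aee = G[None] / l0[:, None, None, None]
        Aee[:, :, diag_idx, diag_idx] += (1.0 / lre)[:, None, :]
        invAee = _batch_inv(Aee)
        Aet = GX2[None] / l0[:, None, None, None]
        M = invAee @ Aet                                     # (V, S, p, q)
        Ssch = X2GX2[None] / l0[:, None, None] - (
            np.swapaxes(Aet, -1, -2) @ M
        ).sum(axis=1)
        Ssch[:, np.arange(q), np.arange(q)] += 1.0 / flat_v[idx, None]
        be = B1v[idx] / l0[:, None, None]
        bt = X2tb[idx] / l0[:, None]
        rhs = bt - (np.swapaxes(M, -1, -2) @ be[..., None])[..., 0].sum(axis=1)
        Cth = np.linalg.inv(Ssch)
        Cth = 0.5 * (Cth + np.swapaxes(Cth, -1, -2))
        etat = (Cth @ rhs[..., None])[..., 0]
        etae = (invAee @ be[..., None])[..., 0] - (
            M @ etat[:, None, :, None]
        )[..., 0]
        theta1 = (X2b[None] @ etat[:, None, :, None])[..., 0] + etae
        L = X2b[None] - M
        LC = L @ Cth[:, None]
        C1 = invAee + LC @ np.swapaxes(L, -1, -2)
        MC = M @ Cth[:, None]
        Cee_diag = invAee[:, :, diag_idx, diag_idx] + (MC * M).sum(axis=-1)
        # Log evidence.
        logdet_A = _batch_logdet(Aee).sum(axis=1) + _batch_logdet(Ssch)
        eta_b = (etae * be).sum(axis=(1, 2)) + (etat * bt).sum(axis=1)
        logdet_d = (
            N * np.log(l0)
            + S * np.log(lre).sum(axis=1)
            + q * np.log(flat_v[idx])
        )
        F = -0.5 * (
            N * np.log(2 * np.pi) + logdet_d + logdet_A + yty[idx] / l0 - eta_b
        )
        return invAee, M, Cth, etat, etae, theta1, C1, Cee_diag, F

    # Guarded over-relaxation: plain EM converges geometrically but slowly
    # when a component sits near zero, so the log-space EM step is
    # lengthened by an adaptive factor, falling back to the guaranteed-
    # ascent plain EM target whenever the evidence drops.
    gamma = np.log(lam)
    fallback = gamma.copy()
    omega = np.ones(V)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if active.size == 0:
            break
        idx = active
        lam[idx] = np.exp(gamma[idx])
        invAee, M, Cth, etat, etae, theta1, C1, Cee_diag, F = e_step(idx)
        rejected = F < F_prev[idx] - 1e-12 * (1 + np.abs(F_prev[idx]))
        done = ~rejected & (np.abs(F - F_prev[idx]) <= tol * (1 + np.abs(F)))
        if n_iter == max_iter:
            done = np.ones_like(done)
        store = np.flatnonzero(done)
        if store.size:
            g = idx[store]
            eta1_out[g] = theta1[store]
            C1_out[g] = C1[store]
            geta_out[g] = etat[store]
            gcov_out[g] = Cth[store]
            conv_out[g] = n_iter < max_iter
            iter_out[g] = n_iter
            F_out[g] = F[store]

        keep = ~done
        if not keep.any():
            active = idx[:0]
            break
        ki = idx[keep]
        rej = rejected[keep]

        # Rejected overshoots restart from the stored plain-EM target,
        # whose evidence is guaranteed not to fall below the last accepted.
        back = ki[rej]
        gamma[back] = fallback[back]
        omega[back] = 1.0

        upd = ki[~rej]
        if upd.size:
            sel = np.flatnonzero(keep)[~rej]   # positions within the E-step batch
            th = theta1[sel]
            rss = np.zeros(upd.size)
            for i in range(S):
                fit = blocks[i] @ th[:, i, :].T        # (n_i, V')
                resid = Ysub[i][:, upd] - fit
                rss += np.einsum("nv,nv->v", resid, resid)
            tr_noise = (G[None] * C1[sel]).sum(axis=(1, 2, 3))
            lam_em = np.empty((upd.size, K))
            lam_em[:, 0] = np.maximum((rss + tr_noise) / N, floor_v[upd])
            e_coord = (etae[sel] ** 2 + Cee_diag[sel]).sum(axis=1)
            lam_em[:, 1:] = np.maximum(e_coord / S, floor_v[upd, None])
            gamma_em = np.log(lam_em)
            fallback[upd] = gamma_em
            step = gamma_em - gamma[upd]
            gamma[upd] = np.maximum(
                gamma[upd] + omega[upd, None] * step, log_floor[upd, None]
            )
            omega[upd] = np.minimum(omega[upd] * 1.5, 16.0)
            F_prev[upd] = F[sel]
        active = ki

    return PosteriorField(
        subjects=level1.subjects,
        p=p,
        eta1=eta1_out,
        C1=C1_out,
        noise_var=lam[:, 0],
        lambdas=lam,
        group_eta=geta_out,
        group_cov=gcov_out,
        converged=conv_out,
        n_iter=iter_out,
        flagged=flagged,
        log_evidence=F_out,
    )


def fit_system(
    manifest: CohortManifest,
    y: np.ndarray,
    spec: TrajectorySpec | None = None,
    *,
    flat_prior_scale: float = 1e6,
    **em_kwargs,
) -> tuple[AugmentedSystem, CovarianceComponents, GroupPosterior]:
    """Convenience: build the augmented system for one voxel and fit it."""
    spec = spec or TrajectorySpec()
    level1 = build_level1_design(manifest, spec)
    level2 = build_level2_design(manifest, spec)
    sys = build_augmented_system(level1, level2, y, flat_prior_scale=flat_prior_scale)
    comps = estimate_hyperparameters(sys, **em_kwargs)
    post = compute_posterior(sys, comps)
    return sys, comps, post
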