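"""Design matrices for the two-level hierarchical trajectory model.

Level 1 models each subject's voxel trajectory as a polynomial in time
(default: straight line, random intercept and slope).  Level 2 expresses
the stacked subject trajectory parameters as a group mean plus
contributions from standardized subject-level covariates (default: total
intracranial volume).  The two levels are stacked into a single augmented
linear system

    y_bar = X_bar @ [eps2; theta2] + eps_bar

whose Gaussian posterior is computed by :mod:`blmemap.engine`.  Priors on
the random effects and on the second-level coefficients enter the
augmented system as pseudo-observations of zero, so the full error
covariance is block diagonal:

    C_eps = blockdiag( C_eps1 (scan noise), C_eps2 (random effects),
                       C_theta2 (second-level prior) )

All default covariance components are diagonal, which the engine exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CohortManifest, ValidationError


@dataclass(frozen=True)
class TrajectorySpec:
    """Shape of the per-subject temporal model.

    poly_order
        Order of the temporal polynomial (1 = random intercept + slope);
        p = poly_order + 1 trajectory parameters per subject.
    covariates
        Manifest columns entering level 2 as subject covariates.  Per-scan
        values are reduced to a per-subject mean and standardized across
        subjects.  Empty tuple = group mean only.
    """

    poly_order: int = 1
    covariates: tuple[str, ...] = ("tiv_mm3",)

    def __post_init__(self):
        if self.poly_order < 1:
            raise ValidationError("poly_order must be >= 1")

    @property
    def p(self) -> int:
        return self.poly_order + 1


@dataclass
class Level1Design:
    """Block-diagonal temporal design, one polynomial block per subject."""

    X1: np.ndarray                      # (N, S*p), block diagonal
    subject_slices: list[tuple[slice, slice]]   # (row, column) extent per subject
    subjects: list[str]
    p: int

    @property
    def n_obs(self) -> int:
        return self.X1.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def blocks(self) -> list[np.ndarray]:
        """Per-subject (n_scans_i, p) design blocks."""
        return [self.X1[r, c] for r, c in self.subject_slices]


@dataclass
class Level2Design:
    """Map from second-level coefficients to stacked subject parameters.

    Columns: p group-mean columns (stacked identities), then p columns per
    covariate (standardized covariate value times the identity block).
    """

    X2: np.ndarray                      # (S*p, q2)
    covariate_values: np.ndarray        # (S, n_cov), standardized
    covariate_names: tuple[str, ...]
    p: int

    @property
    def q2(self) -> int:
        return self.X2.shape[1]

    def subject_block(self, i: int) -> np.ndarray:
        """Subject i's (p, q2) row block."""
        return self.X2[i * self.p:(i + 1) * self.p]


@dataclass
class AugmentedSystem:
    """The stacked two-level system plus its covariance-component basis.

    ``component_masks`` lists, for every estimable variance component, the
    boolean support of its (diagonal) basis matrix over the augmented rows:
    one scan-noise component over the N data rows, then one component per
    trajectory coordinate (intercept, slope, ...) over the matching
    random-effect rows.  The second-level prior is held fixed at
    ``flat_prior_var`` (effectively flat) and is not estimated.
    """

    y_bar: np.ndarray                   # (N + S*p + q2,)
    X_bar: np.ndarray                   # (N + S*p + q2, S*p + q2)
    component_masks: list[np.ndarray]
    component_names: list[str]
    flat_prior_var: float
    n_obs: int
    n_random: int
    n_fixed: int
    level1: "Level1Design | None" = None
    level2: "Level2Design | None" = None

    @property
    def n_params(self) -> int:
        return self.n_random + self.n_fixed

    @property
    def y(self) -> np.ndarray:
        """The data block of ``y_bar`` (the tail is zero by construction)."""
        return self.y_bar[: self.n_obs]

    def component_matrix(self, k: int) -> np.ndarray:
        """Dense symmetric basis matrix Q_k (diagonal indicator)."""
        return np.diag(self.component_masks[k].astype(float))

    def fixed_rows(self) -> np.ndarray:
        """Boolean mask of augmented rows carrying the fixed flat prior."""
        n = self.y_bar.shape[0]
        mask = np.zeros(n, dtype=bool)
        mask[n - self.n_fixed:] = True
        return mask


def _poly_rows(t: np.ndarray, order: int) -> np.ndarray:
    return np.vander(np.asarray(t, dtype=float), N=order + 1, increasing=True)


def build_level1_design(manifest: CohortManifest, spec: TrajectorySpec) -> Level1Design:
    """Assemble the block-diagonal temporal design from per-subject scan times.

    Times are fractional years since each subject's first scan, so block i
    rows are ``[1, t_ij, ..., t_ij**poly_order]``.
    """
    subjects = manifest.subjects
    if not subjects:
        raise ValidationError("empty manifest")
    p = spec.p
    blocks = [_poly_rows(manifest.times_for(s), spec.poly_order) for s in subjects]
    for s, b in zip(subjects, blocks):
        if b.shape[0] < p:
            warnings.warn(
                f"subject {s!r} has {b.shape[0]} scans < {p} trajectory "
                "parameters; its block is under-determined on its own "
                "(identifiability comes from pooling)",
                stacklevel=2,
            )
    N = sum(b.shape[0] for b in blocks)
    X1 = np.zeros((N, len(subjects) * p))
    slices = []
    row = 0
    for i, b in enumerate(blocks):
        r = slice(row, row + b.shape[0])
        c = slice(i * p, (i + 1) * p)
        X1[r, c] = b
        slices.append((r, c))
        row += b.shape[0]
    return Level1Design(X1=X1, subject_slices=slices, subjects=subjects, p=p)


def build_level2_design(manifest: CohortManifest, spec: TrajectorySpec) -> Level2Design:
    """Assemble the subject-covariate design mapping theta2 to stacked parameters.

    Per-scan covariates (e.g. TIV per image) are reduced to per-subject means
    and standardized to zero mean / unit SD across subjects; each covariate
    scales a p x p identity block so it can shift every trajectory coordinate.
    """
    subjects = manifest.subjects
    S, p = len(subjects), spec.p
    cov_cols = []
    for name in spec.covariates:
        if name not in manifest.data.columns:
            raise ValidationError(f"covariate column {name!r} not in manifest")
        per_subject = np.array(
            [manifest.rows_for(s)[name].astype(float).mean() for s in subjects]
        )
        if np.isnan(per_subject).any():
            raise ValidationError(f"covariate {name!r} missing for some subject")
        sd = per_subject.std(ddof=1) if S > 1 else 0.0
        if sd == 0:
            warnings.warn(
                f"covariate {name!r} is constant across subjects; its level-2 "
                "columns are rank deficient",
                stacklevel=2,
            )
            cov_cols.append(per_subject - per_subject.mean())
        else:
            cov_cols.append((per_subject - per_subject.mean()) / sd)
    values = np.column_stack(cov_cols) if cov_cols else np.empty((S, 0))

    q2 = p * (1 + values.shape[1])
    X2 = np.zeros((S * p, q2))
    eye = np.eye(p)
    for i in range(S):
        X2[i * p:(i + 1) * p, :p] = eye
        for j in range(values.shape[1]):
            X2[i * p:(i + 1) * p, (1 + j) * p:(2 + j) * p] = values[i, j] * eye
    return Level2Design(
        X2=X2, covariate_values=values, covariate_names=tuple(spec.covariates), p=p
    )


def build_augmented_system(
    level1: Level1Design,
    level2: Level2Design,
    y: np.ndarray,
    *,
    flat_prior_scale: float = 1e6,
) -> AugmentedSystem:
    """Stack data rows and zero-mean prior pseudo-observations.

    The second-level prior variance is ``flat_prior_scale`` times the sample
    variance of ``y`` (effectively flat, never EM-estimated), so fixed
    effects are essentially unregularized.
    """
    y = np.asarray(y, dtype=float)
    N, Sp = level1.X1.shape
    if y.shape != (N,):
        raise ValidationError(f"y has shape {y.shape}, expected ({N},)")
    q2 = level2.q2
    if level2.X2.shape[0] != Sp:
        raise ValidationError("level-1 and level-2 designs disagree on S*p")

    X_top = np.hstack([level1.X1, level1.X1 @ level2.X2])
    X_bar = np.vstack(
        [
            X_top,
            np.hstack([np.eye(Sp), np.zeros((Sp, q2))]),
            np.hstack([np.zeros((q2, Sp)), np.eye(q2)]),
        ]
    )
    y_bar = np.concatenate([y, np.zeros(Sp + q2)])

    n_rows = N + Sp + q2
    p = level1.p
    masks, names = [], []
    noise = np.zeros(n_rows, dtype=bool)
    noise[:N] = True
    masks.append(noise)
    names.append("noise")
    coord_labels = ["intercept", "slope"] + [f"t^{k}" for k in range(2, p)]
    for c in range(p):
        m = np.zeros(n_rows, dtype=bool)
        m[N + c:N + Sp:p] = True
        masks.append(m)
        names.append(coord_labels[c])

    var_y = float(np.var(y)) if np.var(y) > 0 else 1.0
    return AugmentedSystem(
        y_bar=y_bar,
        X_bar=X_bar,
        component_masks=masks,
        component_names=names,
        flat_prior_var=flat_prior_scale * var_y,
        n_obs=N,
        n_random=Sp,
        n_fixed=q2,
        level1=level1,
        level2=level2,
    )
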