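"""Posterior predictive deviation scores and atrophy-cluster quantification.

The group posterior is collapsed to one subject's trajectory parameters,
turned into a Gaussian posterior predictive distribution at new scan
times, and each observed gray-matter-density value is scored with

    score = erf( (observed - predicted mean) / sqrt(2 * predictive var) )

a signed statistic in [-1, 1]: near 0 when the observation matches the
prediction, near -1 when gray matter is far lower than expected.
Thresholding the negative tail of a score map yields a binary atrophy
cluster whose volume (cc) and between-scan growth rate (cc/year) track
emerging neurodegeneration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .design import Level2Design
from .engine import GroupPosterior
from .io import ValidationError


@dataclass
class SubjectPosterior:
    """One subject's trajectory-parameter posterior plus the scan-noise level."""

    eta1: np.ndarray      # (p,) intercept, slope, ...
    C1: np.ndarray        # (p, p) symmetric PSD
    noise_var: float

    def __post_init__(self):
        self.eta1 = np.atleast_1d(np.asarray(self.eta1, dtype=float))
        self.C1 = np.atleast_2d(np.asarray(self.C1, dtype=float))
        if self.noise_var <= 0:
            raise ValidationError("noise variance must be positive")


@dataclass
class PredictiveDistribution:
    """Gaussian posterior predictive at a set of new scan times."""

    X_hat: np.ndarray     # (m, p) polynomial rows at the new times
    mean: np.ndarray      # (m,)
    var: np.ndarray       # (m,) includes the scan-noise floor


@dataclass
class DeviationMap:
    """Per-voxel erf deviation scores for one subject at one scan."""

    scores: np.ndarray    # in [-1, 1]; NaN at flagged voxels
    z: np.ndarray         # standardized residuals behind the scores

    @property
    def flagged(self) -> np.ndarray:
        return ~np.isfinite(self.scores)


@dataclass
class ClusterSeries:
    """Thresholded atrophy-cluster volumes over a subject's post-model scans.

    ``baseline_time`` anchors the first growth rate: cluster volume is
    defined as 0 at the last scan that entered the model (configurable to
    ``None``, in which case the first post-model scan has no rate).
    """

    times: np.ndarray     # years, strictly increasing
    volumes: np.ndarray   # cc, aligned with times
    threshold: float
    baseline_time: float | None = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.shape != self.volumes.shape:
            raise ValidationError("times and volumes must align")
        if (self.volumes < 0).any():
            raise ValidationError("cluster volumes must be non-negative")


def collapse_to_subject(
    post: GroupPosterior, X2: Level2Design, subject_index: int, noise_var: float
) -> SubjectPosterior:
    """Collapse the group posterior to one subject's trajectory parameters.

    The subject's parameters are the linear map ``theta1_i = X2_i theta2 +
    eps2_i`` of the stacked posterior, so the mean and covariance follow
    by propagating that map through the joint Gaussian.
    """
    p = X2.p
    S = post.n_random // p
    if not 0 <= subject_index < S:
        raise IndexError(f"subject index {subject_index} out of range [0, {S})")
    rows = slice(subject_index * p, (subject_index + 1) * p)
    fixed = slice(post.n_random, post.n_random + post.n_fixed)
    X2i = X2.subject_block(subject_index)

    eta1 = X2i @ post.eta[fixed] + post.eta[rows]
    C_ee = post.C[rows, rows.start:rows.stop]
    C_et = post.C[rows, fixed.start:fixed.stop]
    C_tt = post.C[fixed, fixed.start:fixed.stop]
    C1 = C_ee + X2i @ C_tt @ X2i.T + X2i @ C_et.T + C_et @ X2i.T
    return SubjectPosterior(eta1=eta1, C1=0.5 * (C1 + C1.T), noise_var=noise_var)


def predictive_distribution(
    sp: SubjectPosterior, new_times: np.ndarray
) -> PredictiveDistribution:
    """Posterior predictive mean and variance at new scan times.

    Variance is the scan-noise level plus the parameter-uncertainty
    quadratic form ``x' C1 x``, so it never falls below the noise floor
    and grows when extrapolating away from the modeled scans.
    """
    t = np.atleast_1d(np.asarray(new_times, dtype=float))
    if not np.isfinite(t).all():
        raise ValidationError("new times must be finite")
    p = sp.eta1.shape[0]
    X_hat = np.vander(t, N=p, increasing=True)
    mean = X_hat @ sp.eta1
    var = sp.noise_var + np.einsum("ij,jk,ik->i", X_hat, sp.C1, X_hat)
    return PredictiveDistribution(X_hat=X_hat, mean=mean, var=var)


def deviation_score(
    mean: np.ndarray, var: np.ndarray, observed: np.ndarray
) -> DeviationMap:
    """erf of the standardized residual of each observation.

    ``score = erf((observed - mean) / sqrt(2 var))``: 0 at the predictive
    mean, approaching -1 (+1) as the observation falls far below (above)
    expectation.  Non-finite observations are flagged (score NaN).
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any(var <= 0):
        raise ValidationError("predictive variance must be positive")
    z = (observed - mean) / np.sqrt(var)
    z = np.where(np.isfinite(observed), z, np.nan)
    return DeviationMap(scores=erf(z / np.sqrt(2.0)), z=z)


def score_observation(pred: PredictiveDistribution, observed: np.ndarray) -> DeviationMap:
    """Score observed values against a predictive distribution."""
    return deviation_score(pred.mean, pred.var, observed)


def cluster_volume(
    scores: np.ndarray, threshold: float, voxel_dims
) -> tuple[np.ndarray, float]:
    """Binarize a deviation map at a negative threshold and measure it in cc.

    A voxel belongs to the atrophy cluster when ``score <= threshold``
    (inclusive).  Volume is the voxel count times the voxel volume,
    converted from mm^3 to cc; no connected-component filtering is
    applied.
    """
    if not -1.0 <= threshold < 0.0:
        raise ValidationError(f"threshold must lie in [-1, 0), got {threshold}")
    scores = np.asarray(scores, dtype=float)
    binary = np.where(np.isfinite(scores), scores <= threshold, False)
    vox_mm3 = float(np.prod(voxel_dims))
    volume_cc = float(binary.sum()) * vox_mm3 / 1000.0
    return binary, volume_cc


def cluster_growth_rate(series: ClusterSeries) -> np.ndarray:
    """Between-scan growth rates (cc/year) as plain difference quotients.

    With a baseline, the first post-model scan's rate is taken against
    volume 0 at the last modeled scan; otherwise rates start at the
    second measurement.  Negative rates (shrinking clusters) are allowed.
    """
    t = series.times
    v = series.volumes
    if series.baseline_time is not None:
        t = np.concatenate([[series.baseline_time], t])
        v = np.concatenate([[0.0], v])
    if t.size < 2:
        raise ValidationError("need at least two cluster measurements")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValidationError("cluster measurement times must be strictly increasing")
    return np.diff(v) / dt


#: erf thresholds examined for atrophy-cluster quantification.
DEFAULT_THRESHOLDS = (-0.7, -0.8, -0.9, -0.95, -0.99, -0.999)
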