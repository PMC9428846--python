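"""Group-by-time mixed models, time-varying Cox regression, and ROI measures.

Cluster volumes (or hippocampal ROI measures) from the deviation pipeline
feed two complementary analyses:

* a linear mixed-effects model ``V_ij = a0_i + a1_i * D_j + e_ij`` over
  time-to-last-event ``D_j`` (0 at conversion for converters, 0 at the
  last visit for non-converters, negative before), with the slope
  decomposed as ``a1_i = b10 + b11 * G + u1_i`` so ``b11`` is the
  group-by-time interaction and the per-group rates are
  ``b10 + b11`` (converters) and ``b10`` (non-converters); and
* time-varying Cox proportional-hazards models of conversion to dementia,
  with z-scored predictors so hazard ratios read per predictor SD, and
  age and sex as covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ImageSeries, ValidationError


@dataclass
class GroupTimeResult:
    """Fixed-effect estimates from the group-by-time mixed model."""

    beta10: float                 # time slope in the reference group
    beta11: float                 # group-by-time interaction
    beta11_ci: tuple[float, float]
    beta11_p: float
    rate_group1: float            # beta10 + beta11 (e.g. converters)
    rate_group0: float            # beta10 (e.g. +ACN)
    rate_group1_ci: tuple[float, float]
    rate_group0_ci: tuple[float, float]
    singular: bool
    model: object = None


@dataclass
class HazardResult:
    """Hazard ratio per predictor SD from a (time-varying) Cox model."""

    predictor: str
    hazard_ratio: float
    ci: tuple[float, float]
    p_value: float
    n_events: int
    flagged: bool = False

    def __post_init__(self):
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard ratio must be positive")


def zscore_standardize(values) -> np.ndarray:
    """z-score a pooled set of measurements (n-1 SD denominator)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise ValidationError("cannot z-score constant or near-empty input")
    mean = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    return (x - mean) / sd


def fit_group_time_lme(data: pd.DataFrame, *, response: str = "volume",
                       reml: bool = True) -> GroupTimeResult:
    """Fit the group-by-time mixed model with random intercept and slope.

    ``data`` needs columns ``subject_id``, ``delta`` (years to the last
    event; 0 at the event, negative before), ``group`` (0/1 indicator,
    1 = converter), and the response column.  Fixed effects: intercept,
    delta, group, group x delta; random intercept and slope per subject.
    A singular random-effects fit is reported with a warning flag rather
    than raised.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = data.dropna(subset=["delta", "group", response]).copy()
    if df["group"].nunique() < 2:
        raise ValidationError("need both groups present to estimate the interaction")
    df["_y"] = df[response].astype(float)

    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            "_y ~ delta * group", df, groups=df["subject_id"], re_formula="~delta"
        )
        try:
            fit = model.fit(reml=reml, method="lbfgs")
        except Exception:
            fit = model.fit(reml=reml)
        singular = any(
            issubclass(w.category, (ConvergenceWarning, RuntimeWarning))
            for w in caught
        )

    params = fit.params
    beta10 = float(params["delta"])
    beta11 = float(params["delta:group"])
    ci = fit.conf_int()
    b11_ci = (float(ci.loc["delta:group", 0]), float(ci.loc["delta:group", 1]))

    # Per-group rates with delta-method CIs from the fixed-effect covariance.
    cov = fit.cov_params()
    var_b10 = float(cov.loc["delta", "delta"])
    var_sum = float(
        cov.loc["delta", "delta"]
        + cov.loc["delta:group", "delta:group"]
        + 2 * cov.loc["delta", "delta:group"]
    )
    zcrit = 1.959963984540054
    rate1 = beta10 + beta11
    return GroupTimeResult(
        beta10=beta10,
        beta11=beta11,
        beta11_ci=b11_ci,
        beta11_p=float(fit.pvalues["delta:group"]),
        rate_group1=rate1,
        rate_group0=beta10,
        rate_group1_ci=(rate1 - zcrit * np.sqrt(var_sum), rate1 + zcrit * np.sqrt(var_sum)),
        rate_group0_ci=(beta10 - zcrit * np.sqrt(var_b10), beta10 + zcrit * np.sqrt(var_b10)),
        singular=singular,
        model=fit,
    )


def fit_time_varying_cox(records: pd.DataFrame, predictor: str,
                         *, covariates: tuple[str, ...] = ("age", "sex"),
                         penalizer: float = 0.0) -> HazardResult:
    """Time-varying Cox model of conversion with interval-format records.

    ``records`` needs ``subject_id``, ``start``, ``stop`` (years), the
    predictor column (already z-scored), an ``event`` flag at ``stop``,
    and the covariate columns (sex coded 0/1).  Ties use the Efron
    approximation (lifelines' default).  Perfect separation or failed
    convergence is reported via ``flagged``.
    """
    from lifelines import CoxTimeVaryingFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    df = records.dropna(subset=[predictor, "start", "stop"]).copy()
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValidationError("no conversion events; Cox model cannot be fitted")
    if (df["start"] >= df["stop"]).any():
        raise ValidationError("interval start must precede stop")

    cols = ["subject_id", "start", "stop", "event", predictor, *covariates]
    df = df[cols]
    flagged = False
    ctv = CoxTimeVaryingFitter(penalizer=penalizer)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            ctv.fit(
                df, id_col="subject_id", start_col="start", stop_col="stop",
                event_col="event", show_progress=False,
            )
        except ConvergenceError:
            # Likely separation: refit with a small ridge penalty and flag it.
            flagged = True
            ctv = CoxTimeVaryingFitter(penalizer=max(penalizer, 0.1))
            ctv.fit(
                df, id_col="subject_id", start_col="start", stop_col="stop",
                event_col="event", show_progress=False,
            )
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            flagged = True

    ci_df = ctv.confidence_intervals_
    with np.errstate(over="ignore"):   # CI can overflow under separation
        hr = float(np.exp(ctv.params_[predictor]))
        lo = float(np.exp(ci_df.loc[predictor].iloc[0]))
        hi = float(np.exp(ci_df.loc[predictor].iloc[1]))
    return HazardResult(
        predictor=predictor,
        hazard_ratio=hr,
        ci=(lo, hi),
        p_value=float(ctv.summary.loc[predictor, "p"]),
        n_events=n_events,
        flagged=flagged,
    )


def roi_measures(series: ImageSeries, labels: np.ndarray, label_ids,
                 manifest) -> pd.DataFrame:
    """Per-scan ROI gray-matter volume and TIV-normalized change measures.

    ``labels`` is a label image on the series grid; voxels whose label is
    in ``label_ids`` (e.g. left+right hippocampus) define the ROI.
    Columns: ``hv`` (cc, density-weighted ROI volume), ``hvt`` (hv/TIV),
    ``hr_rate`` (cc change from the prior scan), ``hrt`` (hr_rate/TIV).
    """
    labels = np.asarray(labels)
    if labels.shape != tuple(series.grid_shape):
        raise ValidationError("label image grid does not match the series grid")
    ix, iy, iz = series.mask_index.T
    in_roi = np.isin(labels[ix, iy, iz], np.asarray(label_ids))
    if not in_roi.any():
        raise ValidationError(f"no masked voxels carry labels {label_ids}")

    rows = []
    for subject in manifest.subjects:
        sub = manifest.rows_for(subject)
        vals = series.values[subject]
        hv = vals[:, in_roi].sum(axis=1) * series.voxel_volume_mm3 / 1000.0
        tiv = sub["tiv_mm3"].to_numpy(float)
        hr_rate = np.concatenate([[np.nan], np.diff(hv)])
        for j in range(len(sub)):
            rows.append(
                {
                    "subject_id": subject,
                    "scan_time": float(sub["scan_time"].iloc[j]),
                    "hv": float(hv[j]),
                    "hvt": float(hv[j] / (tiv[j] / 1000.0)),
                    "hr_rate": float(hr_rate[j]),
                    "hrt": float(hr_rate[j] / (tiv[j] / 1000.0)),
                }
            )
    return pd.DataFrame(rows)
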