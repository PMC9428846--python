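"""End-to-end orchestration: fit -> predict -> cluster -> survival.

For every participant of interest, the group model is fitted on the full
control set plus that participant's first ``n_model`` scans (default 2),
voxelwise.  Later scans are scored against the posterior predictive
distribution, thresholded into atrophy clusters, and summarized as a long
table ``subject_id, scan_time, threshold, volume_cc, growth_cc_per_year``
that feeds the group-by-time and time-varying Cox analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .design import TrajectorySpec
from .deviation import DEFAULT_THRESHOLDS, ClusterSeries, cluster_growth_rate, cluster_volume
from .engine import fit_voxel_field
from .io import CohortManifest, ImageSeries, ValidationError
from .outcomes import fit_group_time_lme, fit_time_varying_cox, zscore_standardize

log = logging.getLogger("blmemap")


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    spec: TrajectorySpec = dc_field(default_factory=TrajectorySpec)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_model: int = 2
    flat_prior_scale: float = 1e6
    em_max_iter: int = 64
    em_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.n_model < 2:
            raise ValidationError("at least two scans must enter the model")
        if any(t >= 0 for t in self.thresholds):
            raise ValidationError("erf thresholds must be negative")


def _subset_for_subject(series: ImageSeries, manifest: CohortManifest,
                        subject: str, n_model: int):
    """Controls (all scans) plus the subject's first ``n_model`` scans."""
    df = manifest.data
    keep = (df["group"] == "control") | (
        (df["subject_id"] == subject)
        & (df.groupby("subject_id").cumcount() < n_model)
    )
    sub_manifest = CohortManifest(df[keep].reset_index(drop=True))
    values = {
        s: (series.values[s] if s != subject else series.values[s][:n_model])
        for s in sub_manifest.subjects
    }
    sub_series = ImageSeries(
        values=values,
        grid_shape=series.grid_shape,
        voxel_dims=series.voxel_dims,
        mask_index=series.mask_index,
        affine=series.affine,
    )
    return sub_series, sub_manifest


def run_fit_predict(
    series: ImageSeries,
    manifest: CohortManifest,
    cfg: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Fit each participant of interest and score their later scans.

    Returns the long cluster table and, per subject, the stacked deviation
    scores for their post-model scans (``(n_post, n_voxels)``).  Subjects
    of interest with no post-model scans are fitted but contribute no rows;
    subjects with fewer than ``n_model`` scans are excluded with a warning.
    """
    cfg = cfg or RunConfig()
    interest = [
        s for s in manifest.subjects
        if manifest.rows_for(s)["group"].iloc[0] == "interest"
    ]
    rows = []
    maps: dict[str, np.ndarray] = {}
    warm = None   # hyperparameters carry over between fits sharing the controls
    for subject in interest:
        times = manifest.times_for(subject)
        if len(times) < cfg.n_model:
            log.warning("subject %s has %d < %d scans; excluded from modeling",
                        subject, len(times), cfg.n_model)
            warnings.warn(f"subject {subject!r} excluded: fewer than "
                          f"{cfg.n_model} scans", stacklevel=2)
            continue
        sub_series, sub_manifest = _subset_for_subject(
            series, manifest, subject, cfg.n_model
        )
        fld = fit_voxel_field(
            sub_series, sub_manifest, cfg.spec,
            flat_prior_scale=cfg.flat_prior_scale,
            max_iter=cfg.em_max_iter, tol=cfg.em_tol,
            init_lambdas=warm,
        )
        warm = fld.lambdas
        log.info(
            "fitted %s: %d voxels, %.1f%% EM-converged, median %d iterations",
            subject, fld.n_voxels, 100 * fld.converged.mean(),
            int(np.median(fld.n_iter)),
        )
        si = fld.subject_index(subject)
        eta1 = fld.eta1[:, si, :]              # (V, p)
        C1 = fld.C1[:, si, :, :]               # (V, p, p)
        noise = fld.noise_var                  # (V,)

        post_times = times[cfg.n_model:]
        if post_times.size == 0:
            continue
        obs = series.values[subject][cfg.n_model:]   # (n_post, V)
        scores = np.empty_like(obs)
        from scipy.special import erf
        p = eta1.shape[1]
        for j, t in enumerate(post_times):
            x = np.array([t**k for k in range(p)])
            mean = eta1 @ x
            var = noise + np.einsum("i,vij,j->v", x, C1, x)
            z = (obs[j] - mean) / np.sqrt(var)
            z = np.where(fld.flagged, np.nan, z)
            scores[j] = erf(z / np.sqrt(2.0))
        maps[subject] = scores

        baseline_time = float(times[cfg.n_model - 1])
        for thr in cfg.thresholds:
            vols = np.array(
                [cluster_volume(scores[j], thr, series.voxel_dims)[1]
                 for j in range(len(post_times))]
            )
            rates = cluster_growth_rate(
                ClusterSeries(times=post_times, volumes=vols, threshold=thr,
                              baseline_time=baseline_time)
            )
            for j, t in enumerate(post_times):
                rows.append(
                    {
                        "subject_id": subject,
                        "scan_time": float(t),
                        "threshold": thr,
                        "volume_cc": float(vols[j]),
                        "growth_cc_per_year": float(rates[j]),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["subject_id", "scan_time", "threshold", "volume_cc",
                       "growth_cc_per_year"],
    )
    return table, maps


def conversion_times(manifest: CohortManifest) -> pd.DataFrame:
    """First dementia visit (CDR >= 1) per participant of interest.

    Visits with missing CDR are ignored for outcome determination; the
    censor time is the last visit with an available CDR.
    """
    out = []
    for subject in manifest.subjects:
        rows = manifest.rows_for(subject)
        if rows["group"].iloc[0] != "interest":
            continue
        with_cdr = rows.dropna(subset=["cdr"])
        if with_cdr.empty:
            continue
        dem = with_cdr[with_cdr["cdr"] >= 1]
        out.append(
            {
                "subject_id": subject,
                "converter": not dem.empty,
                "event_time": float(dem["scan_time"].iloc[0]) if not dem.empty
                else float(with_cdr["scan_time"].iloc[-1]),
            }
        )
    return pd.DataFrame(out)


def build_group_time_data(cluster_df: pd.DataFrame, outcomes: pd.DataFrame,
                          threshold: float) -> pd.DataFrame:
    """Assemble the group-by-time table: delta is years to the last event
    (conversion or last visit), 0 at the event and negative before."""
    sub = cluster_df[cluster_df["threshold"] == threshold].merge(
        outcomes, on="subject_id"
    )
    sub = sub[sub["scan_time"] <= sub["event_time"]].copy()
    sub["delta"] = sub["scan_time"] - sub["event_time"]
    sub["group"] = sub["converter"].astype(int)
    return sub


def build_survival_records(measure_df: pd.DataFrame, manifest: CohortManifest,
                           outcomes: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Interval-format records with the predictor updated at each scan.

    Each interval runs from one post-model scan to the next; the predictor
    is the (z-scored) measurement at the interval start, the event flag is
    set when the interval ends at the conversion visit, and intervals at
    or beyond conversion are dropped.  Covariates: age at interval start
    and sex (0 = F, 1 = M).
    """
    demo = manifest.data.groupby("subject_id").first()[["age", "sex"]]
    records = []
    for _, out_row in outcomes.iterrows():
        subject = out_row["subject_id"]
        sub = measure_df[measure_df["subject_id"] == subject].sort_values(
            "scan_time"
        )
        if sub.empty:
            continue
        t = sub["scan_time"].to_numpy(float)
        v = sub[value_col].to_numpy(float)
        event_time = out_row["event_time"]
        is_conv = bool(out_row["converter"])
        stop_times = np.append(t[1:], np.nan)
        for k in range(len(t)):
            start = t[k]
            stop = stop_times[k]
            if np.isnan(stop):
                stop = event_time if event_time > start else np.nan
            if np.isnan(stop) or start >= event_time:
                continue
            stop = min(stop, event_time)
            if stop <= start:
                continue
            records.append(
                {
                    "subject_id": subject,
                    "start": start,
                    "stop": stop,
                    "value": v[k],
                    "event": bool(is_conv and np.isclose(stop, event_time)),
                    "age": float(demo.loc[subject, "age"]) + start,
                    "sex": 1.0 if demo.loc[subject, "sex"] == "M" else 0.0,
                }
            )
    df = pd.DataFrame(records)
    if df.empty:
        return df
    df["predictor"] = zscore_standardize(df["value"])
    return df


def run_survival(
    cluster_df: pd.DataFrame,
    manifest: CohortManifest,
    cfg: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Group-by-time rate table and hazard-ratio table across thresholds.

    Returns ``{"group_time": ..., "cox": ...}``: one group-rate row per
    threshold (response in raw cc, so rates read in cc/year) and one
    hazard-ratio row per threshold x {volume, growth} predictor, with
    z-scored predictors and age/sex covariates.  With no conversion
    events the Cox table is empty and a notice is logged.
    """
    cfg = cfg or RunConfig()
    outcomes = conversion_times(manifest)
    if outcomes.empty:
        raise ValidationError("no participants of interest with CDR data")

    gt_rows, cox_rows = [], []
    any_events = bool(outcomes["converter"].any())
    if not any_events:
        log.info("no conversion events; survival models skipped")
    for thr in cfg.thresholds:
        data = build_group_time_data(cluster_df, outcomes, thr)
        try:
            res = fit_group_time_lme(data, response="volume_cc")
            gt_rows.append(
                {
                    "threshold": thr,
                    "beta_interaction": res.beta11,
                    "beta_interaction_lo": res.beta11_ci[0],
                    "beta_interaction_hi": res.beta11_ci[1],
                    "beta_interaction_p": res.beta11_p,
                    "rate_converters": res.rate_group1,
                    "rate_nonconverters": res.rate_group0,
                    "singular": res.singular,
                }
            )
        except ValidationError as exc:
            log.warning("group-time model skipped at %s: %s", thr, exc)

        if not any_events:
            continue
        sub = cluster_df[cluster_df["threshold"] == thr]
        for name, col in (("volume", "volume_cc"), ("growth", "growth_cc_per_year")):
            records = build_survival_records(sub, manifest, outcomes, col)
            if records.empty:
                continue
            try:
                hz = fit_time_varying_cox(records, "predictor")
            except ValidationError as exc:
                log.warning("cox model skipped (%s, %s): %s", thr, name, exc)
                continue
            cox_rows.append(
                {
                    "threshold": thr,
                    "predictor": name,
                    "hazard_ratio": hz.hazard_ratio,
                    "ci_lo": hz.ci[0],
                    "ci_hi": hz.ci[1],
                    "p": hz.p_value,
                    "n_events": hz.n_events,
                    "flagged": hz.flagged,
                }
            )
    return {
        "group_time": pd.DataFrame(gt_rows),
        "cox": pd.DataFrame(cox_rows),
    }


def run_roi_survival(
    roi_df: pd.DataFrame,
    manifest: CohortManifest,
) -> pd.DataFrame:
    """Cox models of conversion from TIV-normalized hippocampal measures.

    ``roi_df`` comes from :func:`blmemap.outcomes.roi_measures`; one
    hazard-ratio row is fitted per predictor (``hvt``, volume ratio;
    ``hrt``, TIV-normalized between-scan change), z-scored across the
    participants of interest, with age/sex covariates.
    """
    outcomes = conversion_times(manifest)
    rows = []
    for col in ("hvt", "hrt"):
        records = build_survival_records(roi_df, manifest, outcomes, col)
        if records.empty:
            continue
        try:
            hz = fit_time_varying_cox(records, "predictor")
        except ValidationError as exc:
            log.warning("ROI cox model skipped (%s): %s", col, exc)
            continue
        rows.append(
            {
                "predictor": col,
                "hazard_ratio": hz.hazard_ratio,
                "ci_lo": hz.ci[0],
                "ci_hi": hz.ci[1],
                "p": hz.p_value,
                "n_events": hz.n_events,
                "flagged": hz.flagged,
            }
        )
    return pd.DataFrame(rows)
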