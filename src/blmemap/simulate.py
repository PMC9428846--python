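"""Phantom longitudinal cohorts with known ground truth.

Each subject's voxel trajectories are linear in time — spatially smooth
random intercept and slope fields plus i.i.d. Gaussian scan noise and a
TIV-like covariate shift — emulating modulated gray-matter-density maps
from a longitudinal VBM pipeline.  A designated spherical region in
"converter" subjects loses density faster after a per-subject onset time
(a piecewise-linear hinge), and conversion/censoring outcomes are drawn
from a discrete-time hazard that increases with the true extra loss rate,
so every downstream stage can be checked against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import CohortManifest, ImageSeries, build_manifest, write_manifest
from .io import ValidationError


@dataclass
class SimConfig:
    """Generative settings for a phantom cohort.

    Defaults describe a desk-scale study: a 16^3 grid of 2 mm voxels,
    40 controls and 20 participants of interest scanned roughly yearly,
    gray-matter density ~0.55 declining ~0.005/year with 0.02 scan noise,
    and converters accelerating by an extra 0.05/year inside a ~1.4 cc
    spherical region from an onset 2-3 years after baseline.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_controls: int = 40
    n_interest: int = 20
    control_scans: tuple[int, int] = (3, 5)
    interest_scans: tuple[int, int] = (6, 8)
    interval_years: tuple[float, float] = (0.8, 1.2)
    baseline_mean: float = 0.55
    baseline_sd: float = 0.08
    slope_mean: float = -0.005
    slope_sd: float = 0.003
    noise_sd: float = 0.02
    field_smooth_vox: float = 2.0
    noise_smooth_vox: float = 0.0
    tiv_mean: float = 1.45e6
    tiv_sd: float = 1.3e5
    tiv_effect: float = 0.02
    region_center: tuple[float, float, float] | None = None
    region_radius_vox: float = 3.5
    accel_slope: float = 0.05
    accel_jitter: float = 0.4
    onset_range: tuple[float, float] = (2.0, 3.0)
    converter_fraction: float = 0.5
    baseline_hazard: float = 0.25
    hazard_link: float = 20.0
    age_mean: float = 70.0
    age_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        for sd in (self.baseline_sd, self.slope_sd, self.noise_sd,
                   self.tiv_sd, self.age_sd):
            if sd < 0:
                raise ValidationError("standard deviations must be non-negative")
        if not 0.0 <= self.converter_fraction <= 1.0:
            raise ValidationError("converter_fraction must lie in [0, 1]")
        center = self.region_center or tuple((s - 1) / 2 for s in self.grid_shape)
        for c, r, s in zip(center, [self.region_radius_vox] * 3, self.grid_shape):
            if c - r < -0.5 or c + r > s - 0.5:
                raise ValidationError("injected region extends outside the grid")


@dataclass
class GroundTruth:
    """Per-subject generative truth for a phantom cohort."""

    intercepts: dict[str, np.ndarray]
    slopes: dict[str, np.ndarray]
    converter: dict[str, bool]
    onset: dict[str, float]
    accel: dict[str, float] = field(default_factory=dict)
    conversion_time: dict[str, float | None] = field(default_factory=dict)
    censor_time: dict[str, float] = field(default_factory=dict)
    region_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    region_volume_cc: float = 0.0


def _smooth_unit_field(rng, grid_shape, sigma_vox) -> np.ndarray:
    """Zero-mean, unit-variance spatially smooth random field, flattened."""
    f = rng.standard_normal(grid_shape)
    if sigma_vox > 0:
        f = gaussian_filter(f, sigma_vox, mode="nearest")
        sd = f.std()
        if sd > 0:
            f = f / sd
    return f.ravel()


def _region_mask(config: SimConfig) -> np.ndarray:
    center = config.region_center or tuple(
        (s - 1) / 2 for s in config.grid_shape
    )
    coords = np.indices(config.grid_shape).reshape(3, -1).T
    d2 = ((coords - np.asarray(center)) ** 2).sum(axis=1)
    return d2 <= config.region_radius_vox**2


def generate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ImageSeries, CohortManifest, GroundTruth]:
    """Draw a phantom cohort (no acceleration, no outcomes yet).

    Voxel values are ``intercept + slope * t + tiv_effect * z_tiv + noise``
    clipped at 0; controls are labelled amyloid-negative and participants
    of interest amyloid-positive.  Reproducible given ``config.seed``.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_vox = int(np.prod(config.grid_shape))
    region = _region_mask(config)
    region_cc = float(region.sum()) * float(np.prod(config.voxel_dims)) / 1000.0

    subjects = [f"C{i:03d}" for i in range(config.n_controls)] + [
        f"P{i:03d}" for i in range(config.n_interest)
    ]
    n_conv = int(round(config.converter_fraction * config.n_interest))

    rows = []
    values: dict[str, np.ndarray] = {}
    truth = GroundTruth(
        intercepts={}, slopes={}, converter={}, onset={},
        region_mask=region, region_volume_cc=region_cc,
    )
    for si, subject in enumerate(subjects):
        is_interest = subject.startswith("P")
        lo, hi = config.interest_scans if is_interest else config.control_scans
        n_scans = int(rng.integers(lo, hi + 1))
        gaps = rng.uniform(*config.interval_years, size=n_scans - 1)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        tiv = rng.normal(config.tiv_mean, config.tiv_sd)
        z_tiv = (tiv - config.tiv_mean) / config.tiv_sd if config.tiv_sd else 0.0
        age = rng.normal(config.age_mean, config.age_sd)
        sex = "M" if rng.random() < 0.5 else "F"

        intercept = (
            config.baseline_mean
            + config.baseline_sd * _smooth_unit_field(rng, config.grid_shape,
                                                      config.field_smooth_vox)
            + config.tiv_effect * z_tiv
        )
        slope = config.slope_mean + config.slope_sd * _smooth_unit_field(
            rng, config.grid_shape, config.field_smooth_vox
        )
        truth.intercepts[subject] = intercept
        truth.slopes[subject] = slope
        if is_interest:
            idx = int(subject[1:])
            truth.converter[subject] = idx < n_conv
            truth.onset[subject] = float(rng.uniform(*config.onset_range))
            jit = rng.uniform(1 - config.accel_jitter, 1 + config.accel_jitter)
            truth.accel[subject] = (
                float(config.accel_slope * jit) if truth.converter[subject] else 0.0
            )
        else:
            truth.converter[subject] = False

        imgs = np.empty((n_scans, n_vox))
        for j, t in enumerate(times):
            noise = rng.standard_normal(config.grid_shape)
            if config.noise_smooth_vox > 0:
                noise = gaussian_filter(noise, config.noise_smooth_vox,
                                        mode="nearest")
                noise /= noise.std()
            imgs[j] = np.clip(
                intercept + slope * t + config.noise_sd * noise.ravel(), 0, None
            )
        values[subject] = imgs

        for j, t in enumerate(times):
            rows.append(
                {
                    "subject_id": subject,
                    "scan_date": round(float(t), 6),
                    "tiv_mm3": tiv,
                    "group": "interest" if is_interest else "control",
                    "cdr": 0.0,
                    "tracer": "PIB",
                    "suvr": 1.7 if is_interest else 1.2,
                    "age": age,
                    "sex": sex,
                }
            )

    manifest = build_manifest(pd.DataFrame(rows))
    series = ImageSeries(
        values=values,
        grid_shape=tuple(config.grid_shape),
        voxel_dims=tuple(config.voxel_dims),
        mask_index=np.indices(config.grid_shape).reshape(3, -1).T,
        affine=np.diag([*config.voxel_dims, 1.0]),
    )
    return series, manifest, truth


def inject_acceleration(
    series: ImageSeries,
    manifest: CohortManifest,
    truth: GroundTruth,
    config: SimConfig,
) -> ImageSeries:
    """Apply the post-onset hinge to converter subjects' region voxels.

    Region voxels of a converter lose an extra ``accel_slope *
    max(0, t - onset)`` of density; pre-onset scans are untouched, and a
    zero acceleration returns values identical to the input.
    """
    import warnings as _warnings

    region = truth.region_mask
    values = {s: v.copy() for s, v in series.values.items()}
    for subject, is_conv in truth.converter.items():
        if not is_conv:
            continue
        times = manifest.times_for(subject)
        onset = truth.onset[subject]
        if onset >= times[-1]:
            _warnings.warn(
                f"converter {subject!r} onset {onset:.2f}y after last scan; "
                "no acceleration injected",
                stacklevel=2,
            )
            continue
        hinge = np.maximum(0.0, times - onset)
        accel = truth.accel.get(subject, config.accel_slope)
        values[subject][:, region] = np.clip(
            values[subject][:, region] - accel * hinge[:, None],
            0,
            None,
        )
    return ImageSeries(
        values=values,
        grid_shape=series.grid_shape,
        voxel_dims=series.voxel_dims,
        mask_index=series.mask_index,
        affine=series.affine,
    )


def generate_outcomes(
    manifest: CohortManifest,
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> CohortManifest:
    """Sample conversion visits and write CDR trajectories into the manifest.

    Every participant of interest carries a post-onset hazard
    ``baseline_hazard * exp(hazard_link * true_loss_rate_cc_per_year)``
    where the true loss rate is ``accel_slope * region_volume_cc`` for
    converters and 0 otherwise; with a zero link, conversion is therefore
    independent of the injected acceleration.  The CDR trajectory steps
    0 -> 0.5 (visit before conversion) -> 1 (conversion onward);
    subjects without a sampled event are censored at their last visit.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    df = manifest.data.copy()
    for subject in manifest.subjects:
        rows = manifest.rows_for(subject)
        times = rows["scan_time"].to_numpy(float)
        truth.censor_time[subject] = float(times[-1])
        if subject not in truth.onset:
            truth.conversion_time[subject] = None
            continue
        onset = truth.onset[subject]
        loss_rate = truth.accel.get(subject, 0.0) * truth.region_volume_cc
        hazard = config.baseline_hazard * np.exp(config.hazard_link * loss_rate)
        exposure = np.maximum(0.0, times - onset)
        cum_haz = hazard * exposure
        e = rng.exponential()
        crossed = np.flatnonzero(cum_haz >= e)
        if crossed.size == 0:
            truth.conversion_time[subject] = None
            continue
        k = int(crossed[0])
        truth.conversion_time[subject] = float(times[k])
        cdr = np.zeros_like(times)
        cdr[k:] = 1.0
        # The intermediate MCI visit never overwrites the first two
        # (cognitively normal) scans that feed the trajectory model.
        if k - 1 >= 2:
            cdr[k - 1] = 0.5
        df.loc[rows.index, "cdr"] = cdr
    return CohortManifest(df)


def simulate_cohort(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[ImageSeries, CohortManifest, GroundTruth]:
    """Generate, accelerate, and attach outcomes; optionally write to disk.

    When ``out_dir`` is given, writes one NIfTI per scan, a mask, the
    manifest CSV, and a ground-truth JSON summary, all readable back
    through :mod:`blmemap.io`.
    """
    series, manifest, truth = generate_cohort(config)
    series = inject_acceleration(series, manifest, truth, config)
    manifest = generate_outcomes(manifest, truth, config)
    if out_dir is not None:
        _write_cohort(series, manifest, truth, config, Path(out_dir))
    return series, manifest, truth


def _write_cohort(series, manifest, truth, config, out_dir: Path) -> None:
    import json

    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    img_dir = out_dir / "images"
    img_dir.mkdir(exist_ok=True)
    mask = np.ones(series.grid_shape, dtype=np.uint8)
    nib.save(nib.Nifti1Image(mask, series.affine), str(out_dir / "mask.nii.gz"))
    paths = []
    for subject in manifest.subjects:
        for j in range(series.values[subject].shape[0]):
            vol = np.zeros(series.grid_shape, dtype=np.float32)
            ix, iy, iz = series.mask_index.T
            vol[ix, iy, iz] = series.values[subject][j]
            p = img_dir / f"{subject}_scan{j:02d}.nii.gz"
            nib.save(nib.Nifti1Image(vol, series.affine), str(p))
            paths.append(str(p.relative_to(out_dir)))
    write_manifest(manifest, out_dir / "manifest.csv")
    pd.Series(paths).to_csv(out_dir / "images.csv", index=False, header=["path"])
    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "converter": truth.converter,
        "onset": truth.onset,
        "conversion_time": truth.conversion_time,
        "censor_time": truth.censor_time,
        "region_volume_cc": truth.region_volume_cc,
    }
    (out_dir / "truth.json").write_text(json.dumps(summary, indent=2))
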