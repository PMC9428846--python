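"""Cohort manifests, longitudinal image series, and deviation-map I/O.

A cohort manifest is a long-format table with one row per scan:

    subject_id, scan_date, tiv_mm3, group, cdr, tracer, suvr, age, sex

``scan_date`` may be an ISO date or a plain number of years; on ingestion
each subject's scan times are converted to fractional years since that
subject's first scan, so the intercept of a linear trajectory is always
the subject's baseline level.

Images are co-registered, modulated gray-matter-density NIfTI volumes on
one common grid, reduced to an ``(n_scans, n_masked_voxels)`` matrix per
subject by a binary mask.  Voxel geometry (the affine) is carried opaquely
from input to output and never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "subject_id", "scan_date", "tiv_mm3", "group", "cdr",
    "tracer", "suvr", "age", "sex",
]

GROUP_LABELS = ("control", "interest")

#: Published amyloid-PET SUVR positivity cutoffs per tracer.
SUVR_CUTOFFS = {"PIB": 1.5, "AV45": 1.11, "FBB": 1.08}

_DAYS_PER_YEAR = 365.25


class SchemaError(ValueError):
    """A required manifest column is absent."""


class ValidationError(ValueError):
    """A manifest or map value violates its contract."""


class GeometryError(ValueError):
    """Images do not share a common voxel grid."""


@dataclass
class CohortManifest:
    """Validated long-format cohort table.

    ``data`` has the canonical columns plus ``scan_time`` (fractional years
    since each subject's first scan), sorted by ``(subject_id, scan_time)``.
    """

    data: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.data["subject_id"]))

    def rows_for(self, subject_id: str) -> pd.DataFrame:
        return self.data[self.data["subject_id"] == subject_id]

    def times_for(self, subject_id: str) -> np.ndarray:
        return self.rows_for(subject_id)["scan_time"].to_numpy(float)

    def subset(self, keep: "pd.Series | np.ndarray") -> "CohortManifest":
        """Row-subset preserving ordering; re-validates scan counts lazily."""
        return CohortManifest(self.data[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ImageSeries:
    """Masked longitudinal gray-matter-density series on a common grid.

    ``values`` maps subject id to an ``(n_scans, n_masked_voxels)`` array in
    manifest scan order.  ``mask_index`` maps masked-voxel column to its
    3-D grid coordinate (rows of an ``(n_vox, 3)`` integer array).
    """

    values: dict[str, np.ndarray]
    grid_shape: tuple[int, int, int]
    voxel_dims: tuple[float, float, float]
    mask_index: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def n_voxels(self) -> int:
        return self.mask_index.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    def stacked(self, manifest: CohortManifest) -> np.ndarray:
        """All scans stacked in manifest row order, shape (N, n_voxels)."""
        return np.vstack([self.values[s] for s in manifest.subjects])


def _scan_times_years(dates: pd.Series) -> np.ndarray:
    """Fractional years since the first entry, from dates or plain numbers."""
    numeric = pd.to_numeric(dates, errors="coerce")
    if numeric.notna().all():
        t = numeric.to_numpy(float)
        return t - t[0]
    parsed = pd.to_datetime(dates, errors="coerce")
    if parsed.isna().any():
        bad = dates[parsed.isna()].iloc[0]
        raise ValidationError(f"unparseable scan_date value: {bad!r}")
    delta = (parsed - parsed.iloc[0]).dt.days.to_numpy(float)
    return delta / _DAYS_PER_YEAR


def build_manifest(frame: pd.DataFrame) -> CohortManifest:
    """Validate a raw manifest frame and derive per-subject scan times."""
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"manifest missing required columns: {missing}")
    df = frame.copy()

    tiv = pd.to_numeric(df["tiv_mm3"], errors="coerce")
    bad_tiv = ~(tiv > 0)
    if bad_tiv.any():
        idx = int(np.flatnonzero(bad_tiv.to_numpy())[0])
        raise ValidationError(
            f"non-positive TIV at manifest row {idx} "
            f"(subject {df['subject_id'].iloc[idx]!r})"
        )
    df["tiv_mm3"] = tiv

    bad_group = ~df["group"].isin(GROUP_LABELS)
    if bad_group.any():
        raise ValidationError(
            f"unknown group label(s): {sorted(df['group'][bad_group].unique())}"
        )

    # Canonical order: subject id, then scan time.
    raw = pd.Series(np.nan, index=df.index, dtype=float)
    for _, g in df.groupby("subject_id", sort=False):
        raw.loc[g.index] = _scan_times_years(g["scan_date"])
    df["_raw_time"] = raw
    # _scan_times_years is relative to the group's *first listed* scan, which
    # may not be the earliest; recentre after sorting.
    df = df.sort_values(["subject_id", "_raw_time"], kind="stable")
    df["scan_time"] = df.groupby("subject_id")["_raw_time"].transform(
        lambda t: t - t.iloc[0]
    )
    df = df.drop(columns=["_raw_time"]).reset_index(drop=True)

    for subject, g in df.groupby("subject_id", sort=False):
        t = g["scan_time"].to_numpy(float)
        if len(t) < 2:
            raise ValidationError(f"subject {subject!r} has fewer than 2 scans")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"subject {subject!r} has duplicate or non-increasing scan times"
            )
    return CohortManifest(df)


def read_manifest(path) -> CohortManifest:
    """Read a cohort manifest CSV and validate it."""
    return build_manifest(pd.read_csv(path))


def write_manifest(manifest: CohortManifest, path) -> None:
    """Write the canonical manifest columns back to CSV (round-trippable)."""
    manifest.data[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_image_series(
    manifest: CohortManifest,
    image_paths: list,
    mask_path,
) -> ImageSeries:
    """Load per-scan NIfTI volumes and reduce them to masked matrices.

    ``image_paths`` must align with the (sorted) manifest rows.
    """
    import nibabel as nib

    if len(image_paths) != len(manifest):
        raise ValidationError(
            f"{len(image_paths)} image paths for {len(manifest)} manifest rows"
        )
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    grid_shape = tuple(int(s) for s in mask.shape)
    zooms = mask_img.header.get_zooms()[:3]
    voxel_dims = tuple(float(z) for z in zooms)
    mask_index = np.argwhere(mask)

    flat = np.empty((len(image_paths), mask_index.shape[0]))
    for i, p in enumerate(image_paths):
        img = nib.load(str(p))
        if tuple(img.shape[:3]) != grid_shape:
            raise GeometryError(
                f"image {p} grid {tuple(img.shape[:3])} != mask grid {grid_shape}"
            )
        vol = np.asarray(img.dataobj, dtype=float)
        if not np.isfinite(vol[mask]).all():
            raise ValidationError(f"non-finite voxel values in {p}")
        flat[i] = vol[mask]

    values: dict[str, np.ndarray] = {}
    row = 0
    for subject in manifest.subjects:
        n = len(manifest.rows_for(subject))
        values[subject] = flat[row:row + n]
        row += n
    return ImageSeries(
        values=values,
        grid_shape=grid_shape,
        voxel_dims=voxel_dims,
        mask_index=mask_index,
        affine=np.asarray(mask_img.affine),
    )


def write_deviation_map(scores: np.ndarray, series: ImageSeries, path,
                        fill_value: float = 0.0) -> None:
    """Write per-voxel deviation scores as a 32-bit float NIfTI volume.

    Scores are placed at ``series.mask_index`` coordinates; voxels outside
    the mask receive ``fill_value``.
    """
    import nibabel as nib

    scores = np.asarray(scores, dtype=float)
    if scores.shape != (series.n_voxels,):
        raise ValidationError(
            f"map length {scores.shape} != mask size ({series.n_voxels},)"
        )
    finite = scores[np.isfinite(scores)]
    if finite.size and (np.abs(finite) > 1 + 1e-12).any():
        raise ValidationError("deviation scores must lie in [-1, 1]")
    vol = np.full(series.grid_shape, fill_value, dtype=np.float32)
    ix, iy, iz = series.mask_index.T
    vol[ix, iy, iz] = scores.astype(np.float32)
    nib.save(nib.Nifti1Image(vol, series.affine), str(path))


def classify_visit(cdr_global: float) -> str:
    """Map a CDR global score to a diagnostic category.

    0 is cognitively normal, 0.5 is MCI, and 1 or greater is dementia.
    """
    if cdr_global == 0:
        return "normal"
    if cdr_global == 0.5:
        return "MCI"
    if cdr_global in (1, 2, 3):
        return "dementia"
    raise ValidationError(f"CDR global score must be in {{0, 0.5, 1, 2, 3}}, got {cdr_global!r}")


def amyloid_status(tracer: str, suvr: float, *, inclusive: bool = False) -> str:
    """Classify amyloid positivity from a tracer-specific SUVR cutoff.

    Cutoffs: PIB 1.5 (cerebellar gray normalization), AV45 1.11 and FBB 1.08
    (whole-cerebellum normalization).  A SUVR exactly at the cutoff counts as
    negative unless ``inclusive`` is set.
    """
    if tracer not in SUVR_CUTOFFS:
        raise ValidationError(f"unknown amyloid tracer {tracer!r}")
    if not suvr > 0:
        raise ValidationError("SUVR must be positive")
    cutoff = SUVR_CUTOFFS[tracer]
    positive = suvr >= cutoff if inclusive else suvr > cutoff
    return "positive" if positive else "negative"
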