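import numpy as np
import pandas as pd
import pytest

from blmemap import SimConfig, TrajectorySpec, build_manifest, simulate_cohort


def manifest_from(records):
    """Build a manifest from (subject, time, tiv) tuples or full dicts."""
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            row = {
                "subject_id": "s0", "scan_date": 0.0, "tiv_mm3": 1.4e6,
                "group": "control", "cdr": 0.0, "tracer": "PIB",
                "suvr": 1.2, "age": 70.0, "sex": "F",
            }
            row.update(rec)
        else:
            subject, t, *rest = rec
            row = {
                "subject_id": subject, "scan_date": float(t),
                "tiv_mm3": rest[0] if rest else 1.4e6,
                "group": "control", "cdr": 0.0, "tracer": "PIB",
                "suvr": 1.2, "age": 70.0, "sex": "F",
            }
        rows.append(row)
    return build_manifest(pd.DataFrame(rows))


@pytest.fixture
def two_subject_manifest():
    return manifest_from(
        [("a", 0.0), ("a", 1.0), ("b", 0.0), ("b", 1.0), ("b", 2.0)]
    )


def simulate_lme_cohort(n_subjects, n_scans, lambdas, *, mean=(2.0, 0.5),
                        rng=None):
    """Direct draw from the two-level generative model at one voxel.

    Returns (manifest, y) with per-subject random intercept/slope around
    the given group mean and i.i.d. scan noise; ``lambdas`` =
    (noise, intercept, slope) variances.
    """
    rng = rng or np.random.default_rng(0)
    noise, v0, v1 = lambdas
    records, ys, truth_slopes = [], [], []
    for s in range(n_subjects):
        t = np.arange(float(n_scans))
        b0 = rng.normal(0, np.sqrt(v0))
        b1 = rng.normal(0, np.sqrt(v1))
        y = mean[0] + b0 + (mean[1] + b1) * t + rng.normal(0, np.sqrt(noise), n_scans)
        ys.append(y)
        truth_slopes.append(mean[1] + b1)
        records += [(f"s{s:03d}", tt) for tt in t]
    return manifest_from(records), np.concatenate(ys), np.array(truth_slopes)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small phantom cohort shared by integration tests."""
    cfg = SimConfig(
        grid_shape=(8, 8, 8), region_radius_vox=2.5, n_controls=10,
        n_interest=4, seed=7,
    )
    return cfg, *simulate_cohort(cfg)


@pytest.fixture
def no_cov_spec():
    return TrajectorySpec(covariates=())
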