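"""Shared fixtures: small synthetic movies, trace cohorts and shell phantoms.

Everything is generated at test time from seeded generators; no binary test
data is stored.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from embryotrace import EmbryoSpec, PipelineConfig, generate_movie, generate_trace_table


@pytest.fixture()
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_movie():
    """3×3 nuclei, 20 frames, modest drift and noise; histone+mcp only."""
    spec = EmbryoSpec(
        nx=3, ny=3, shape_zyx=(32, 96, 96),
        duration_min=10.0, frame_interval_s=30.0, front_breakpoint_min=9.0,
        nucleus_drift_um=0.3, include_membrane=False,
        onset_mean_min=5.0, onset_sd_min=1.0, onset_floor_min=2.0,
        seed=7,
    )
    stack, gt = generate_movie(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free, bleach-free twin of the small movie (static nuclei)."""
    spec = EmbryoSpec(
        nx=3, ny=3, shape_zyx=(32, 96, 96),
        duration_min=5.0, frame_interval_s=60.0, front_breakpoint_min=4.0,
        movie_noise_sd=0.0, bleach_rate_per_min=0.0, include_membrane=False,
        onset_mean_min=2.0, onset_sd_min=0.5, onset_floor_min=1.0,
        seed=11,
    )
    stack, gt = generate_movie(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def front_movie():
    """Movie with a membrane channel sampled every 2 min over 50 min."""
    spec = EmbryoSpec(duration_min=50.0, frame_interval_s=120.0,
                      front_breakpoint_min=35.0, seed=3)
    stack, gt = generate_movie(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def trace_cohort():
    """200 telegraph traces: 100 active, 100 inactive, at study conditions."""
    spec = EmbryoSpec(
        nx=20, ny=10, duration_min=60.0, frame_interval_s=30.0,
        active_nuclei=list(range(100)), seed=5,
    )
    traces, truth, gt = generate_trace_table(spec)
    return spec, traces, truth, gt


def make_shell_phantom(
    interior_vols_um3,
    vitelline: bool = False,
    voxel_size_um=(0.5, 0.25, 0.25),
    shape_zyx=(48, 160, 160),
    noise_sd: float = 0.05,
    seed: int = 0,
    thickness_um: float = 1.2,
):
    """Hollow-sphere phantom for the envelope pipeline.

    Up to five shells: one centred, four on ±11 µm arms, all inside an
    optional vitelline-membrane-like ellipsoidal shell. Returns
    ``(volume, analytic_interior_volumes)``.
    """
    rng = np.random.default_rng(seed)
    vol = np.full(shape_zyx, 0.05)
    vz, vy, vx = voxel_size_um
    cz0 = shape_zyx[0] * vz / 2
    cy0 = shape_zyx[1] * vy / 2
    cx0 = shape_zyx[2] * vx / 2
    centers = [(cy0, cx0), (cy0 - 11, cx0), (cy0 + 11, cx0),
               (cy0, cx0 - 11), (cy0, cx0 + 11)]
    if len(interior_vols_um3) > len(centers):
        raise ValueError("phantom supports at most five shells")
    zz = (np.arange(shape_zyx[0]) + 0.5) * vz - cz0
    analytic = []
    for (cy, cx), v in zip(centers, interior_vols_um3):
        a = (v * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        yy = (np.arange(shape_zyx[1]) + 0.5) * vy - cy
        xx = (np.arange(shape_zyx[2]) + 0.5) * vx - cx
        r = np.sqrt(zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2)
        vol[(r >= a) & (r <= a + thickness_um)] = 1.0
        analytic.append(4.0 / 3.0 * np.pi * a ** 3)
    if vitelline:
        yy = (np.arange(shape_zyx[1]) + 0.5) * vy - cy0
        xx = (np.arange(shape_zyx[2]) + 0.5) * vx - cx0
        r = np.sqrt((zz[:, None, None] / 10.0) ** 2 + (yy[None, :, None] / 18.0) ** 2
                    + (xx[None, None, :] / 18.0) ** 2)
        vol[(r >= 1.0) & (r <= 1.06)] = 1.0
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, shape_zyx)
    return vol, analytic


def match_iou(gt_labels: np.ndarray, pred_labels: np.ndarray) -> list[float]:
    """Best-overlap IoU of every ground-truth object against a prediction."""
    ious = []
    for gid in np.unique(gt_labels):
        if gid == 0:
            continue
        g = gt_labels == gid
        vals, counts = np.unique(pred_labels[g], return_counts=True)
        fg = vals > 0
        if not fg.any():
            ious.append(0.0)
            continue
        best = vals[fg][np.argmax(counts[fg])]
        p = pred_labels == best
        ious.append(float((g & p).sum() / (g | p).sum()))
    return ious
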