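"""Cellularization-front quantification and onset-correlation analysis.

The membrane length at each time point is the vertical extent of the largest
Otsu-thresholded object in the central orthogonal section. Landmark times are
the first frames at which the (median-smoothed) length reaches configured
depths relative to the nuclei (apical margin, mid-nucleus, basal end);
arrested embryos that never reach a landmark are flagged. Across embryos,
the landmark time is correlated with the first quartile of transcription
onset times by pooled ordinary least squares; R² is the squared Pearson
correlation of the pooled points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu


@dataclass
class FrontTrace:
    """Membrane (cellularization-front) length vs time for one embryo."""

    table: pd.DataFrame          # frame, t_min, length_um, curated
    pixel_size_um: float

    def lengths(self) -> np.ndarray:
        return self.table["length_um"].to_numpy()


@dataclass
class CorrelationResult:
    points: pd.DataFrame         # embryo, landmark_min, q1_onset_min
    slope: float
    intercept: float
    r2: float


def front_length_timeseries(
    sections: np.ndarray,
    pixel_size_um: float,
    t_min: np.ndarray,
    invert: bool = False,
) -> FrontTrace:
    """Otsu-threshold each 2-D orthogonal section and measure membrane length.

    ``sections`` is (t, depth, width) with depth increasing basally. The
    length is the vertical extent of the largest foreground object,
    ``(last_row − first_row) × pixel size``. Transmitted-light sections are
    handled by inverting contrast first. Frames with no foreground (or no
    dynamic range) give a missing length with a warning.
    """
    sections = np.asarray(sections, dtype=np.float64)
    lengths = np.full(sections.shape[0], np.nan)
    for t in range(sections.shape[0]):
        # small median filter: single bright noise pixels attached to the
        # membrane object would otherwise stretch its vertical extent
        img = ndimage.median_filter(sections[t], size=3)
        if invert:
            img = img.max() - img
        if img.max() <= img.min():
            warnings.warn(f"frame {t}: constant section, length missing")
            continue
        thr = threshold_otsu(img)
        fg = img > thr
        if not fg.any():
            warnings.warn(f"frame {t}: empty foreground, length missing")
            continue
        # plausibility guard: when there is no real bimodality Otsu simply
        # splits the background noise. Require the foreground mean to stand
        # well clear of the background spread; failed frames are left missing
        # for manual curation.
        bg = img[~fg]
        separation = (img[fg].mean() - bg.mean()) / max(bg.std(), 1e-12)
        if separation < 4.0:
            warnings.warn(f"frame {t}: implausible Otsu split, length missing")
            continue
        lab, n = ndimage.label(fg)
        if n == 0:
            warnings.warn(f"frame {t}: empty foreground, length missing")
            continue
        sizes = ndimage.sum_labels(fg, lab, np.arange(1, n + 1))
        largest = int(np.argmax(sizes)) + 1
        # a row counts toward the vertical extent only with a few member
        # pixels; small noise clusters attached to the object otherwise
        # stretch the height by a row
        support = max(2, int(round(0.03 * fg.shape[1])))
        row_counts = (lab == largest).sum(axis=1)
        rows = np.nonzero(row_counts >= support)[0]
        if rows.size == 0:
            rows = np.nonzero(row_counts)[0]
        lengths[t] = (rows.max() - rows.min()) * pixel_size_um
    table = pd.DataFrame(
        {
            "frame": np.arange(sections.shape[0]),
            "t_min": np.asarray(t_min, dtype=float),
            "length_um": lengths,
            "curated": False,
        }
    )
    return FrontTrace(table=table, pixel_size_um=float(pixel_size_um))


def apply_manual_curation(front: FrontTrace, curation: dict[int, float]) -> FrontTrace:
    """Override lengths at curated frames (flagged); all other frames untouched."""
    table = front.table.copy()
    n = len(table)
    for frame, length in curation.items():
        if not (0 <= frame < n):
            raise ValueError(f"curated frame {frame} outside range [0, {n})")
        table.loc[table["frame"] == frame, ["length_um", "curated"]] = [float(length), True]
    return FrontTrace(table=table, pixel_size_um=front.pixel_size_um)


def landmark_times(
    front: FrontTrace,
    landmarks_um: dict[str, float],
    smooth_frames: int = 3,
) -> pd.DataFrame:
    """First time (min into nc14) at which the front reaches each landmark depth.

    The length series is smoothed with a short running median to suppress
    single-frame threshold flicker; a landmark never reached is missing and
    flagged ``arrested`` (cellularization-arrested embryos).
    """
    table = front.table
    smoothed = (
        table["length_um"].rolling(smooth_frames, center=True, min_periods=1).median()
    )
    rows = []
    for name, depth in sorted(landmarks_um.items(), key=lambda kv: kv[1]):
        reached = np.nonzero(smoothed.to_numpy() >= depth)[0]
        if reached.size == 0:
            rows.append({"landmark": name, "depth_um": depth,
                         "time_min": np.nan, "arrested": True})
        else:
            rows.append({"landmark": name, "depth_um": depth,
                         "time_min": float(table["t_min"].iloc[reached[0]]),
                         "arrested": False})
    return pd.DataFrame(rows)


def onset_q1(onsets) -> float:
    """First quartile of onset times, linear interpolation between order statistics."""
    arr = np.asarray(onsets, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite onsets")
    return float(np.percentile(arr, 25.0, method="linear"))


def onset_landmark_correlation(
    embryos: list[tuple[str, float, np.ndarray]],
) -> CorrelationResult:
    """Pooled OLS of per-embryo (landmark time, Q1 onset) points.

    ``embryos`` is a list of ``(embryo_id, landmark_time_min, onsets_min)``;
    embryos without any finite onset are excluded with a warning. R² is
    computed after pooling all points together.
    """
    pts = []
    for eid, lm, onsets in embryos:
        arr = np.asarray(onsets, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0 or not np.isfinite(lm):
            warnings.warn(f"embryo {eid}: no usable onsets/landmark, excluded")
            continue
        pts.append({"embryo": eid, "landmark_min": float(lm), "q1_onset_min": onset_q1(arr)})
    points = pd.DataFrame(pts, columns=["embryo", "landmark_min", "q1_onset_min"])
    if len(points) < 2:
        raise ValueError("need at least two embryos with landmark and onset data")
    res = stats.linregress(points["landmark_min"], points["q1_onset_min"])
    return CorrelationResult(
        points=points,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
    )
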