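"""FRAP quantification: circular-ROI traces, double normalization, zero-scaling.

Recovery at a bleached spot is measured as the mean intensity inside a 20 px
circle, divided by its own pre-bleach average and then by the same ratio for
the mean of six control circles (double normalization — this exactly cancels
any global per-frame multiplicative intensity factor such as acquisition
photobleaching). Each curve is then scaled so that the first post-bleach
value is 0: by default the affine map ``s = (r − r0)/(1 − r0)`` (full
recovery ↦ 1, so the plateau reads out the mobile fraction directly); a pure
offset ``s = r − r0`` is available as an alternative since either reading of
"scaled so the first value after bleaching was considered 0" is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class FrapExperiment:
    """Bleach/control ROI layout and timing for one FRAP acquisition."""

    bleach_centers: list            # (y, x) pixel coordinates
    control_centers: list
    roi_diameter_px: int = 20
    n_prebleach: int = 1
    frame_interval_s: float = 0.5

    def validate(self, shape_yx) -> None:
        h, w = shape_yx
        r = self.roi_diameter_px / 2.0
        for cy, cx in list(self.bleach_centers) + list(self.control_centers):
            if not (0 <= cy - r and cy + r <= h and 0 <= cx - r and cx + r <= w):
                raise ValueError(f"ROI at ({cy}, {cx}) extends outside the {shape_yx} field")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        for by, bx in self.bleach_centers:
            for cy, cx in self.control_centers:
                if (by - cy) ** 2 + (bx - cx) ** 2 < self.roi_diameter_px ** 2:
                    raise ValueError("bleach and control ROI sets must be disjoint")


def _roi_mask(shape_yx, center, diameter_px) -> np.ndarray:
    cy, cx = center
    r = diameter_px / 2.0
    yy, xx = np.mgrid[0:shape_yx[0], 0:shape_yx[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def measure_rois(series: np.ndarray, exp: FrapExperiment) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity per frame over each bleach and control circle.

    Circle membership is pixel-centre-in-circle with radius ``diameter/2``.
    Returns ``(bleach_traces, control_traces)`` with shape (n_rois, t).
    """
    series = np.asarray(series, dtype=np.float64)
    exp.validate(series.shape[1:])
    def traces(centers):
        out = np.empty((len(centers), series.shape[0]))
        for i, c in enumerate(centers):
            m = _roi_mask(series.shape[1:], c, exp.roi_diameter_px)
            out[i] = series[:, m].mean(axis=1)
        return out
    return traces(exp.bleach_centers), traces(exp.control_centers)


def normalize_recovery(
    bleach_traces: np.ndarray,
    control_traces: np.ndarray,
    n_prebleach: int,
) -> np.ndarray:
    """Double normalization against the pooled control-ROI trace.

    ``r(t) = [F_bleach(t)/F̄_bleach,pre] / [F_ctrl(t)/F̄_ctrl,pre]`` where
    ``F_ctrl`` is the mean over the control-ROI set.
    """
    bleach_traces = np.atleast_2d(np.asarray(bleach_traces, dtype=np.float64))
    control_traces = np.atleast_2d(np.asarray(control_traces, dtype=np.float64))
    ctrl = control_traces.mean(axis=0)
    ctrl_pre = ctrl[:n_prebleach].mean()
    pre = bleach_traces[:, :n_prebleach].mean(axis=1)
    if ctrl_pre <= 0 or np.any(pre <= 0):
        raise ValueError("zero or negative pre-bleach average")
    return (bleach_traces / pre[:, None]) / (ctrl / ctrl_pre)[None, :]


def scale_zero(recovery: np.ndarray, n_prebleach: int, mode: str = "rescale") -> np.ndarray:
    """Scale so the first post-bleach value is exactly 0.

    ``mode="rescale"`` (default): ``s = (r − r0)/(1 − r0)``, mapping the
    pre-bleach plateau 1 ↦ 1. ``mode="offset"``: ``s = r − r0``. Requires
    actual bleach depth (``r0 < 1``) in rescale mode.
    """
    r = np.atleast_2d(np.asarray(recovery, dtype=np.float64))
    if n_prebleach >= r.shape[1]:
        raise ValueError("no post-bleach frames")
    r0 = r[:, n_prebleach]
    if mode == "rescale":
        if np.any(r0 >= 1.0):
            raise ValueError("no bleach depth (first post-bleach value >= 1)")
        s = (r - r0[:, None]) / (1.0 - r0[:, None])
    elif mode == "offset":
        s = r - r0[:, None]
    else:
        raise ValueError(f"unknown scale mode {mode!r}")
    if np.asarray(recovery).ndim == 1:
        return s[0]
    return s


def fit_recovery(t_post_s: np.ndarray, scaled: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``s(t) = m·(1 − 2^(−t/τ))``.

    Returns ``(mobile_fraction m, half_time_s τ)``. This is the auxiliary
    single-exponential readout used to compare recovery speed across
    conditions, not a reaction–diffusion model.
    """
    t = np.asarray(t_post_s, dtype=float)
    s = np.asarray(scaled, dtype=float)

    def model(t, m, tau):
        return m * (1.0 - np.exp(-t * np.log(2.0) / tau))

    p0 = (max(float(np.nanmax(s)), 0.1), max(float(np.median(t)), 1e-3))
    popt, _ = curve_fit(model, t, s, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])


def frap_table(
    exp: FrapExperiment,
    bleach_traces: np.ndarray,
    recovery: np.ndarray,
    scaled: np.ndarray,
) -> pd.DataFrame:
    """Tidy per-curve table: t_s, raw, r, s for each bleach ROI."""
    rows = []
    for i in range(bleach_traces.shape[0]):
        for t in range(bleach_traces.shape[1]):
            rows.append(
                {
                    "roi": i,
                    "t_s": t * exp.frame_interval_s,
                    "raw": bleach_traces[i, t],
                    "r": recovery[i, t],
                    "s": scaled[i, t],
                }
            )
    return pd.DataFrame(rows)
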