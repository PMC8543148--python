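"""Transcription-trace processing: activity calling, bleach normalization,
onsets and total outputs.

The classifier is the two-pass procedure used for MS2/MCP max-pixel proxy
traces. Pass 1: the mean of *all* retained traces over time is fitted to a
straight line (the baseline); each trace is median-filtered (window 3) and a
frame is ON when the filtered value exceeds 1.2× the baseline at that time;
a nucleus is active when it has at least five ON frames. Pass 2: the baseline
is refitted to the mean of the *inactive* pool only and nuclei are segregated
again the same way. Normalization removes the fitted baseline from the raw
trace and divides by the relative baseline decay ``baseline(t)/baseline(0)``
to undo photobleaching. Onsets are the first ON frame at/after the search
start (15 min into nc14; 30 min under maternal Gal4); nuclei already active
before nc14 are discarded. Total output is the sum of normalized values over
the 30–50 min window, split into high/low at the cohort median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig


@dataclass
class TraceSet:
    """Per-track traces with classification state.

    ``traces`` is frames × track-id; all per-track series are indexed by the
    same column labels.
    """

    traces: pd.DataFrame
    t_min: np.ndarray
    retained: pd.Series = field(default=None)
    active: pd.Series = field(default=None)
    on_mask: pd.DataFrame = field(default=None)
    baseline: np.ndarray = field(default=None)          # fitted baseline(t), AU
    inactive_mean: np.ndarray = field(default=None)     # empirical inactive-pool mean
    baseline_coef: tuple[float, float] = (0.0, 0.0)     # slope (AU/frame), intercept
    normalized: pd.DataFrame = field(default=None)
    onsets: pd.Series = field(default=None)             # min into nc14, NaN if none
    excluded_pre_nc14: pd.Series = field(default=None)
    outputs: pd.Series = field(default=None)
    output_class: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        if len(self.t_min) != len(self.traces):
            raise ValueError("t_min length must match the number of frames")


def _median_filter_traces(traces: pd.DataFrame, size: int) -> pd.DataFrame:
    """Centered running median, NaN-tolerant (missing frames stay missing)."""
    filt = traces.rolling(size, center=True, min_periods=1).median()
    return filt.where(traces.notna())


def _fit_baseline(mean_trace: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    frames = np.arange(len(mean_trace), dtype=float)
    ok = np.isfinite(mean_trace)
    if ok.sum() < 2:
        raise ValueError("need at least two frames with data to fit a baseline")
    slope, intercept = np.polyfit(frames[ok], mean_trace[ok], 1)
    return slope * frames + intercept, (float(slope), float(intercept))


def _on_counts(on: pd.DataFrame, consecutive: bool) -> pd.Series:
    if not consecutive:
        return on.sum(axis=0)
    # longest run of consecutive ON frames per track
    def longest_run(col):
        best = run = 0
        for v in col:
            run = run + 1 if v else 0
            best = max(best, run)
        return best
    return on.apply(longest_run, axis=0)


def classify_active(traces: pd.DataFrame, t_min, config: PipelineConfig) -> TraceSet:
    """Two-pass active/inactive segregation with straight-line baseline.

    ``traces``: frames × track-id raw max-fluorescence values (NaN = track
    absent). Tracks present in fewer than ``min_track_length + 1`` frames are
    dropped from the analysis (retained = tracked for *more* than the
    configured number of frames).
    """
    ts = TraceSet(traces=traces, t_min=t_min)
    counts = traces.notna().sum(axis=0)
    ts.retained = counts > config.min_track_length
    kept = traces.loc[:, ts.retained[ts.retained].index]
    if kept.shape[1] < 2:
        raise ValueError("need at least two retained traces")

    filt = _median_filter_traces(kept, config.trace_median_filter)

    def segregate(baseline: np.ndarray):
        on = filt.gt(config.activity_factor * baseline, axis=0) & kept.notna()
        active = _on_counts(on, config.on_frames_consecutive) >= config.min_on_frames
        return on, active

    # pass 1: baseline from the mean of all retained nuclei
    baseline1, _ = _fit_baseline(kept.mean(axis=1, skipna=True).to_numpy())
    on1, active1 = segregate(baseline1)

    # pass 2: baseline from the inactive pool only
    inactive_cols = active1[~active1].index
    if len(inactive_cols) == 0:
        warnings.warn("no inactive nuclei after pass 1; keeping pass-1 baseline")
        inactive_mean = kept.mean(axis=1, skipna=True).to_numpy()
    else:
        inactive_mean = kept[inactive_cols].mean(axis=1, skipna=True).to_numpy()
    baseline2, coef2 = _fit_baseline(inactive_mean)
    on2, active2 = segregate(baseline2)

    # the final inactive pool defines the empirical bleach profile
    inactive_cols2 = active2[~active2].index
    if len(inactive_cols2):
        inactive_mean = kept[inactive_cols2].mean(axis=1, skipna=True).to_numpy()

    ts.on_mask = on2
    ts.active = active2
    ts.baseline = baseline2
    ts.baseline_coef = coef2
    ts.inactive_mean = inactive_mean
    return ts


def normalize_traces(ts: TraceSet, config: PipelineConfig) -> TraceSet:
    """Baseline-subtract and undo the photobleaching decay.

    The subtracted baseline and the decay ratio depend on
    ``config.bleach_norm_mode``:

    * ``"mixed"`` (default): subtract the fitted straight-line baseline,
      divide by the empirical inactive-pool decay ratio ``m(t)/m(0)``;
    * ``"fit"``: both from the fitted line
      (``(raw − b)/(b(t)/b(0))``);
    * ``"empirical"``: both from the inactive-pool mean, which cancels any
      global multiplicative decay exactly in the noiseless limit.

    Results are clipped at zero. Requires a strictly positive baseline.
    """
    if ts.baseline is None:
        raise ValueError("classify_active must run before normalize_traces")
    b = ts.baseline
    m = ts.inactive_mean
    if np.any(b <= 0) or (m is not None and np.any(m <= 0)):
        raise ValueError("baseline is non-positive within the analysis window")
    mode = config.bleach_norm_mode
    subtract = b if mode in ("mixed", "fit") else m
    ratio = (b / b[0]) if mode == "fit" else (m / m[0])
    kept = ts.traces.loc[:, ts.retained[ts.retained].index]
    norm = kept.sub(subtract, axis=0).div(ratio, axis=0).clip(lower=0.0)
    ts.normalized = norm
    return ts


def onset_times(ts: TraceSet, config: PipelineConfig) -> TraceSet:
    """First ON frame at/after the search start, in minutes into nc14.

    Nuclei whose first ON frame precedes nc14 (t < 0) were active in an
    earlier cycle and are excluded from the active set.
    """
    if ts.on_mask is None:
        raise ValueError("classify_active must run before onset_times")
    start = config.onset_start_min
    onsets = {}
    excluded = {}
    active = ts.active.copy()
    for col in ts.on_mask.columns:
        excluded[col] = False
        if not active.get(col, False):
            onsets[col] = np.nan
            continue
        on_frames = np.nonzero(ts.on_mask[col].to_numpy())[0]
        if on_frames.size and ts.t_min[on_frames[0]] < 0.0:
            excluded[col] = True
            active[col] = False
            onsets[col] = np.nan
            continue
        eligible = on_frames[ts.t_min[on_frames] >= start]
        if eligible.size == 0:
            warnings.warn(f"track {col}: active but no ON frame after {start} min")
            onsets[col] = np.nan
        else:
            onsets[col] = float(ts.t_min[eligible[0]])
    ts.onsets = pd.Series(onsets)
    ts.excluded_pre_nc14 = pd.Series(excluded)
    ts.active = active
    return ts


def total_output_and_class(ts: TraceSet, config: PipelineConfig) -> TraceSet:
    """Sum of normalized values over the output window; classes split at the median.

    Ties at the median go to "low" (classes are defined by values strictly
    above the median).
    """
    if ts.normalized is None:
        raise ValueError("normalize_traces must run before total_output_and_class")
    w0, w1 = config.output_window_min
    in_window = (ts.t_min >= w0) & (ts.t_min <= w1)
    outputs = ts.normalized.loc[in_window].sum(axis=0, skipna=True)
    ts.outputs = outputs
    cohort = outputs[ts.active.reindex(outputs.index, fill_value=False)]
    if len(cohort):
        med = float(np.median(cohort.to_numpy()))
        classes = cohort.gt(med).map({True: "high", False: "low"})
    else:
        classes = pd.Series(dtype=object)
    ts.output_class = classes
    return ts


def process_traces(traces: pd.DataFrame, t_min, config: PipelineConfig) -> TraceSet:
    """classify → normalize → onsets → outputs, in order."""
    ts = classify_active(traces, t_min, config)
    ts = normalize_traces(ts, config)
    ts = onset_times(ts, config)
    ts = total_output_and_class(ts, config)
    return ts


# ---------------------------------------------------------------------------
# cohort summaries (mean ± s.e.m. profile, onset-sorted heatmap matrix)
# ---------------------------------------------------------------------------

def cohort_profile(ts: TraceSet) -> pd.DataFrame:
    """Per-frame mean, s.e.m. and n of normalized traces over active nuclei."""
    if ts.normalized is None:
        raise ValueError("normalized traces required")
    act = ts.active[ts.active].index
    sub = ts.normalized.loc[:, ts.normalized.columns.intersection(act)]
    n = sub.notna().sum(axis=1)
    mean = sub.mean(axis=1, skipna=True)
    sem = sub.std(axis=1, skipna=True, ddof=1) / np.sqrt(n.clip(lower=1))
    return pd.DataFrame({"t_min": ts.t_min, "mean": mean, "sem": sem, "n": n})


def heatmap_matrix(ts: TraceSet) -> pd.DataFrame:
    """Normalized traces of active nuclei, rows sorted by onset time."""
    if ts.normalized is None or ts.onsets is None:
        raise ValueError("normalized traces and onsets required")
    act = [c for c in ts.normalized.columns
           if ts.active.get(c, False) and np.isfinite(ts.onsets.get(c, np.nan))]
    order = sorted(act, key=lambda c: ts.onsets[c])
    return ts.normalized[order].T
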