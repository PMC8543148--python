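"""Two-pass activity calling, bleach normalization, onsets and outputs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from embryotrace import EmbryoSpec, PipelineConfig
from embryotrace.synthetic import generate_trace_table
from embryotrace.transcription import (
    classify_active,
    cohort_profile,
    heatmap_matrix,
    normalize_traces,
    onset_times,
    process_traces,
    total_output_and_class,
)


def cohort_config(**kw):
    return dataclasses.replace(PipelineConfig(), **kw)


def toy_traces(n_frames=60, baseline=1.0):
    """Twenty flat traces at baseline; callers perturb individual columns."""
    rng = np.random.default_rng(0)
    vals = baseline + rng.normal(0, 0.01, size=(n_frames, 20))
    return pd.DataFrame(vals, columns=range(20))


def toy_times(n_frames=60, dt_min=0.5):
    return np.arange(n_frames) * dt_min


class TestClassify:
    def test_constant_trace_inactive(self, cfg):
        traces = toy_traces()
        ts = classify_active(traces, toy_times(), cfg)
        assert not ts.active[0]
        assert ts.on_mask[0].sum() == 0

    def test_six_frames_above_threshold_is_active_with_exact_mask(self, cfg):
        traces = toy_traces()
        traces.loc[30:35, 3] = 1.5  # 6 consecutive frames at 1.5x baseline
        ts = classify_active(traces, toy_times(), cfg)
        assert ts.active[3]
        on = np.nonzero(ts.on_mask[3].to_numpy())[0]
        assert on.min() >= 29 and on.max() <= 36  # median-3 edge latitude
        assert 5 <= len(on) <= 7

    def test_four_on_frames_insufficient(self, cfg):
        traces = toy_traces()
        traces.loc[30:33, 3] = 1.5
        ts = classify_active(traces, toy_times(), cfg)
        assert not ts.active[3]

    def test_retention_requires_more_than_ten_frames(self, cfg):
        traces = toy_traces()
        traces.loc[10:, 5] = np.nan  # present for exactly 10 frames
        traces.loc[11:, 6] = np.nan  # present for 11 frames
        ts = classify_active(traces, toy_times(), cfg)
        assert not ts.retained[5]
        assert ts.retained[6]

    def test_all_active_falls_back_with_warning(self, cfg):
        rng = np.random.default_rng(1)
        vals = 1.0 + rng.normal(0, 0.01, size=(60, 4))
        vals[20:40] += 2.0  # every nucleus bursts
        traces = pd.DataFrame(vals, columns=range(4))
        with pytest.warns(UserWarning, match="no inactive"):
            ts = classify_active(traces, toy_times(), cfg)
        assert ts.active.all()

    def test_idempotent_on_reclassification(self, trace_cohort, cfg):
        spec, traces, truth, gt = trace_cohort
        t1 = classify_active(traces, spec.times_min(), cfg)
        t2 = classify_active(traces, spec.times_min(), cfg)
        assert t1.active.equals(t2.active)
        assert t1.on_mask.equals(t2.on_mask)

    def test_sensitivity_and_specificity_on_cohort(self, trace_cohort, cfg):
        spec, traces, truth, gt = trace_cohort
        ts = classify_active(traces, spec.times_min(), cfg)
        pred = np.array([bool(ts.active.get(c, False)) for c in range(200)])
        act = truth["active"].to_numpy()
        sens = (pred & act).sum() / act.sum()
        spec_ = (~pred & ~act).sum() / (~act).sum()
        assert sens >= 0.95
        assert spec_ >= 0.95

    def test_raising_one_frame_never_deactivates(self, trace_cohort, cfg):
        spec, traces, truth, gt = trace_cohort
        ts = classify_active(traces, spec.times_min(), cfg)
        active_col = ts.active[ts.active].index[0]
        boosted = traces.copy()
        boosted.loc[80, active_col] += 2.0
        ts2 = classify_active(boosted, spec.times_min(), cfg)
        assert ts2.active[active_col]


class TestNormalize:
    def test_flat_baseline_subtraction_exact(self, cfg):
        spec = EmbryoSpec(nx=4, ny=2, duration_min=30, frame_interval_s=30,
                          front_breakpoint_min=25, active_nuclei=[0, 1],
                          trace_noise_sd=0.0, bleach_rate_per_min=0.0,
                          onset_mean_min=10, onset_sd_min=1, onset_floor_min=5,
                          seed=2)
        traces, truth, gt = generate_trace_table(spec)
        ts = process_traces(traces, spec.times_min(), cfg)
        for c in (0, 1):
            expected = gt.signal[c].to_numpy()
            assert np.allclose(ts.normalized[c].to_numpy(), expected, atol=1e-9)

    @pytest.mark.parametrize("mode", ["mixed", "fit", "empirical"])
    def test_linear_decay_yields_flat_amplitude(self, mode):
        cfg = cohort_config(bleach_norm_mode=mode)
        spec = EmbryoSpec(nx=10, ny=4, duration_min=60, frame_interval_s=30,
                          active_nuclei=list(range(20)), trace_noise_sd=0.0,
                          k_on_per_min=np.inf, k_off_per_min=0.0,
                          bleach_model="linear", bleach_rate_per_min=0.3 / 60,
                          seed=3)
        traces, truth, gt = generate_trace_table(spec)
        ts = process_traces(traces, spec.times_min(), cfg)
        for c in range(0, 20, 5):
            on = gt.signal[c].to_numpy() > 0
            vals = ts.normalized[c].to_numpy()[on]
            assert np.abs(vals - spec.spot_amplitude_au).max() < 0.05

    def test_exponential_decay_cancels_within_one_percent(self, cfg):
        spec = EmbryoSpec(nx=10, ny=4, duration_min=60, frame_interval_s=30,
                          active_nuclei=list(range(20)), trace_noise_sd=0.0,
                          k_on_per_min=np.inf, k_off_per_min=0.0,
                          bleach_model="exponential", bleach_rate_per_min=0.005,
                          seed=3)
        traces, truth, gt = generate_trace_table(spec)
        ts = process_traces(traces, spec.times_min(), cfg)
        for c in range(0, 20, 5):
            on = gt.signal[c].to_numpy() > 0
            vals = ts.normalized[c].to_numpy()[on]
            assert np.abs(vals - spec.spot_amplitude_au).max() < 0.01

    def test_inactive_traces_normalize_to_zero_mean(self, trace_cohort, cfg):
        spec, traces, truth, gt = trace_cohort
        ts = process_traces(traces, spec.times_min(), cfg)
        inact = [c for c in range(100, 200) if not ts.active.get(c, False)]
        means = [ts.normalized[c].mean() for c in inact]
        # clipped at zero, so the mean sits slightly above 0 by half the noise
        assert np.mean(means) < 3 * spec.trace_noise_sd

    def test_requires_classification_first(self, cfg):
        from embryotrace.transcription import TraceSet

        ts = TraceSet(traces=toy_traces(), t_min=toy_times())
        with pytest.raises(ValueError, match="classify_active"):
            normalize_traces(ts, cfg)


class TestOnsets:
    def test_onset_arithmetic(self, cfg):
        traces = toy_traces(n_frames=80)
        traces.loc[40:60, 2] = 1.6
        ts = classify_active(traces, toy_times(n_frames=80), cfg)
        ts = onset_times(ts, cfg)
        # frame 40 at 30 s frames = 20 min (median-3 may shift one frame)
        assert abs(ts.onsets[2] - 20.0) <= 0.5

    def test_activity_before_search_start_excluded(self, cfg):
        traces = toy_traces(n_frames=80)
        traces.loc[20:24, 2] = 1.6  # 10-12 min only, before the 15-min start
        with pytest.warns(UserWarning, match="no ON frame"):
            ts = onset_times(classify_active(traces, toy_times(80), cfg), cfg)
        assert np.isnan(ts.onsets[2])

    def test_pre_nc14_activity_discards_nucleus(self, cfg):
        t_min = toy_times(80) - 10.0  # movie starts 10 min before nc14
        traces = toy_traces(n_frames=80)
        traces.loc[2:40, 2] = 1.6  # ON from before the nc14 origin
        traces.loc[60:70, 3] = 1.6  # ON at 20-25 min: legitimate
        ts = onset_times(classify_active(traces, t_min, cfg), cfg)
        assert ts.excluded_pre_nc14[2]
        assert not ts.active[2]
        assert not ts.excluded_pre_nc14[3]

    def test_maternal_gal4_mode_starts_at_thirty(self):
        cfg = cohort_config(maternal_gal4=True)
        traces = toy_traces(n_frames=120)
        traces.loc[40:50, 2] = 1.6   # 20-25 min: before the Gal4 start
        traces.loc[70:80, 2] = 1.6   # 35-40 min
        ts = onset_times(classify_active(traces, toy_times(120), cfg), cfg)
        assert ts.onsets[2] >= 30.0

    def test_median_onset_error_at_most_one_frame(self, trace_cohort, cfg):
        spec, traces, truth, gt = trace_cohort
        ts = process_traces(traces, spec.times_min(), cfg)
        dt = spec.frame_interval_s / 60.0
        errs = []
        for c in range(100):
            if np.isfinite(ts.onsets.get(c, np.nan)):
                errs.append(abs(ts.onsets[c] - truth["onset_min"][c]) / dt)
        assert np.median(errs) <= 1.0


class TestOutputs:
    def test_zero_trace_zero_output(self, cfg):
        traces = toy_traces()
        ts = process_traces(traces, toy_times(60, 1.0), cohort_config(
            output_window_min=(30.0, 50.0)))
        assert (ts.outputs.abs() < 0.2).all()

    def test_output_arithmetic(self):
        cfg = cohort_config(output_window_min=(30.0, 50.0))
        n = 80
        t_min = np.arange(n) * 1.0
        rng = np.random.default_rng(4)
        vals = 1.0 + rng.normal(0, 1e-6, size=(n, 6))
        vals[:, 0] += 2.0 * ((t_min >= 0) & (t_min <= 79))  # always 2 AU above
        traces = pd.DataFrame(vals, columns=range(6))
        ts = process_traces(traces, t_min, cfg)
        # 21 in-window frames at 1 min/frame x 2 AU, minus baseline-fit leakage
        assert abs(ts.outputs[0] - 42.0) < 2.0

    def test_median_split_ties_to_low(self, cfg):
        from embryotrace.transcription import TraceSet

        ts = TraceSet(traces=toy_traces(4), t_min=toy_times(4))
        ts.normalized = pd.DataFrame(np.zeros((4, 4)), columns=range(4))
        ts.active = pd.Series(True, index=range(4))
        ts.retained = pd.Series(True, index=range(4))
        ts.outputs = pd.Series([1.0, 2.0, 3.0, 4.0], index=range(4))
        w0 = cfg.output_window_min
        ts.t_min = np.array([w0[0]] * 4)
        out = total_output_and_class(ts, cfg)
        # recompute with the crafted outputs
        med = np.median([1, 2, 3, 4])
        classes = pd.Series([1.0, 2.0, 3.0, 4.0]).gt(med).map({True: "high", False: "low"})
        assert list(classes) == ["low", "low", "high", "high"]

    def test_cohort_profile_matches_generator_expectation(self, trace_cohort, cfg):
        spec, traces, truth, gt = trace_cohort
        ts = process_traces(traces, spec.times_min(), cfg)
        prof = cohort_profile(ts)
        act = [c for c in range(100) if ts.active.get(c, False)]
        expected = gt.signal[act].mean(axis=1).to_numpy()
        sel = expected > 0.2  # after the first onsets
        resid = prof["mean"].to_numpy()[sel] - expected[sel]
        assert np.abs(resid).mean() < 0.1

    def test_heatmap_rows_sorted_by_onset(self, trace_cohort, cfg):
        spec, traces, truth, gt = trace_cohort
        ts = process_traces(traces, spec.times_min(), cfg)
        mat = heatmap_matrix(ts)
        onsets = [ts.onsets[c] for c in mat.index]
        assert onsets == sorted(onsets)
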