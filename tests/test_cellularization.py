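"""Front-length measurement, landmark times and onset correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_otsu

from embryotrace.cellularization import (
    FrontTrace,
    apply_manual_curation,
    front_length_timeseries,
    landmark_times,
    onset_landmark_correlation,
    onset_q1,
)


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximisation over all 8-bit cuts."""
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def between_class_variance(values, thr):
    lo, hi = values[values <= thr], values[values > thr]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    return lo.size * hi.size * (lo.mean() - hi.mean()) ** 2


class TestOtsu:
    def test_binary_band_length(self):
        sec = np.zeros((1, 64, 32))
        sec[0, 10:41, :] = 1.0
        ft = front_length_timeseries(sec, 1.0, np.array([0.0]))
        assert ft.table["length_um"].item() == 30.0

    def test_bimodal_threshold_between_peaks(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < 0.3, 200.0, 20.0)
        thr = threshold_otsu(img)
        assert 20.0 < thr < 200.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_otsu_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random bimodal-ish 8-bit sample
        n0, n1 = rng.integers(50, 400, size=2)
        values = np.concatenate([
            rng.normal(rng.integers(30, 100), 15, n0),
            rng.normal(rng.integers(120, 220), 20, n1),
        ]).clip(0, 255).astype(np.uint8)
        img = values.reshape(1, -1).astype(float)
        thr = threshold_otsu(values, nbins=256)
        v_lib = between_class_variance(values.astype(float), thr)
        v_oracle = between_class_variance(
            values.astype(float), brute_force_otsu(values.astype(float))
        )
        assert v_lib >= v_oracle * (1 - 1e-12)


class TestCuration:
    def make_front(self):
        table = pd.DataFrame({
            "frame": np.arange(10), "t_min": np.arange(10, dtype=float),
            "length_um": np.linspace(0, 9, 10), "curated": False,
        })
        return FrontTrace(table=table, pixel_size_um=1.0)

    def test_empty_table_is_identity(self):
        f = self.make_front()
        out = apply_manual_curation(f, {})
        assert out.table.equals(f.table)

    def test_single_override_flagged(self):
        out = apply_manual_curation(self.make_front(), {7: 99.0})
        assert out.table.loc[7, "length_um"] == 99.0
        assert out.table.loc[7, "curated"]
        assert not out.table.drop(index=7)["curated"].any()

    def test_out_of_range_frame_rejected(self):
        with pytest.raises(ValueError, match="range"):
            apply_manual_curation(self.make_front(), {10: 5.0})


class TestLandmarks:
    def test_linear_front_arithmetic(self):
        t = np.arange(0, 100, 2.0)  # 2-min frames
        table = pd.DataFrame({"frame": np.arange(50), "t_min": t,
                              "length_um": 0.5 * t, "curated": False})
        lm = landmark_times(FrontTrace(table, 1.0), {"basal": 20.0})
        assert lm["time_min"].item() == 40.0

    def test_arrested_front_flagged(self):
        t = np.arange(0, 60, 2.0)
        length = np.minimum(0.5 * t, 8.0)  # plateaus below the landmark
        table = pd.DataFrame({"frame": np.arange(30), "t_min": t,
                              "length_um": length, "curated": False})
        lm = landmark_times(FrontTrace(table, 1.0), {"basal": 20.0})
        assert lm["arrested"].item()
        assert np.isnan(lm["time_min"].item())

    def test_landmark_times_non_decreasing_in_depth(self, front_movie):
        spec, stack, gt = front_movie
        chan = stack.channel("membrane")
        sections = chan[:, :, :, chan.shape[3] // 2]
        ft = front_length_timeseries(sections, stack.voxel_size_um[0], stack.times_min())
        lm = landmark_times(ft, {"a": 5.0, "b": 10.0, "c": 15.0, "d": 22.0})
        times = lm.sort_values("depth_um")["time_min"].to_numpy()
        assert (np.diff(times) >= 0).all()

    def test_generator_biphasic_front_recovered(self, front_movie):
        spec, stack, gt = front_movie
        chan = stack.channel("membrane")
        sections = chan[:, :, :, chan.shape[3] // 2]
        ft = front_length_timeseries(sections, stack.voxel_size_um[0], stack.times_min())
        err_vox = (ft.table["length_um"].to_numpy() - gt.front_um) / stack.voxel_size_um[0]
        assert np.nanmax(np.abs(err_vox)) <= 1.0
        # landmark within one frame of the analytic crossing of f(t)
        lm = landmark_times(ft, {"mid": 10.0, "basal": 15.0})
        dt = spec.frame_interval_s / 60.0
        for depth, t_meas in zip(lm["depth_um"], lm["time_min"]):
            t_true = depth / spec.front_slow_um_per_min
            assert abs(t_meas - t_true) <= dt


class TestCorrelation:
    def test_q1_linear_interpolation(self):
        assert onset_q1([10, 20, 30, 40]) == 17.5

    def test_collinear_points_r2_one(self):
        embryos = [(f"e{i}", 30.0 + i, np.array([35.0 + i])) for i in range(5)]
        res = onset_landmark_correlation(embryos)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(1.0)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError, match="two embryos"):
            onset_landmark_correlation([("a", 30.0, np.array([32.0]))])

    def test_embryo_without_onsets_excluded(self):
        embryos = [("a", 30.0, np.array([32.0])),
                   ("b", 31.0, np.array([33.0])),
                   ("c", 32.0, np.array([np.nan]))]
        with pytest.warns(UserWarning, match="excluded"):
            res = onset_landmark_correlation(embryos)
        assert len(res.points) == 2

    def test_r2_affine_invariance(self):
        rng = np.random.default_rng(5)
        lms = np.linspace(25, 37, 20)
        embryos = [(str(i), lm, lm + rng.normal(0, 2, 8)) for i, lm in enumerate(lms)]
        r2 = onset_landmark_correlation(embryos).r2
        scaled = [(e, 3 * lm + 7, o) for e, lm, o in embryos]
        r2_scaled = onset_landmark_correlation(scaled).r2
        assert r2_scaled == pytest.approx(r2, rel=1e-9)

    def test_noise_attenuates_r2_toward_analytic_expectation(self):
        # onset Q1 = landmark + N(0, sigma) over embryos with fixed spread s:
        # E[R^2] ~= s^2 / (s^2 + sigma^2)
        sigma = 2.0
        lms = np.linspace(25, 37, 40)
        s2 = lms.var()
        r2s = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            embryos = [(str(i), lm, np.full(4, lm + rng.normal(0, sigma)))
                       for i, lm in enumerate(lms)]
            r2s.append(onset_landmark_correlation(embryos).r2)
        expected = s2 / (s2 + sigma ** 2)
        sem = np.std(r2s, ddof=1) / np.sqrt(len(r2s))
        assert abs(np.mean(r2s) - expected) < 3 * sem + 0.01
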