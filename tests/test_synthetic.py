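"""Generator self-consistency: determinism, rendering fidelity, telegraph
statistics and the FRAP ground-truth curve."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from embryotrace import EmbryoSpec, FrapSpec, generate_movie, generate_frap_series
from embryotrace.synthetic import (
    bleach_curve,
    front_length,
    generate_trace_table,
    sample_onsets,
    telegraph_states,
    frap_recovery_curve,
)


def tiny_spec(**kw):
    base = dict(nx=2, ny=2, shape_zyx=(24, 64, 64), duration_min=4.0,
                frame_interval_s=60.0, front_breakpoint_min=3.0,
                include_membrane=False, seed=1)
    base.update(kw)
    return EmbryoSpec(**base)


@pytest.mark.parametrize(
    "field, kw",
    [
        ("semi_axes_start_um", {"semi_axes_start_um": (0.0, 2.0, 2.0)}),
        ("voxel_size_um", {"voxel_size_um": (0.0, 0.25, 0.25)}),
        ("front_breakpoint_min", {"front_breakpoint_min": 99.0}),
        ("bleach_model", {"bleach_model": "quadratic"}),
        ("frame_interval_s", {"frame_interval_s": 0.0}),
    ],
)
def test_invalid_spec_names_field(field, kw):
    with pytest.raises(ValueError, match=field):
        tiny_spec(**kw)


def test_seed_determinism_byte_identical():
    s1, g1 = generate_movie(tiny_spec(seed=42))
    s2, g2 = generate_movie(tiny_spec(seed=42))
    assert np.array_equal(s1.data, s2.data)
    assert np.array_equal(g1.labels, g2.labels)
    s3, _ = generate_movie(tiny_spec(seed=43))
    assert not np.array_equal(s1.data, s3.data)


def test_no_active_nuclei_no_puncta():
    spec = tiny_spec(active_nuclei=[], movie_noise_sd=0.0, bleach_rate_per_min=0.0)
    stack, gt = generate_movie(spec)
    mcp = stack.channel("mcp")
    assert mcp.max() <= spec.nuclear_background_au + 1e-9
    assert (gt.signal.to_numpy() == 0).all()


def test_no_bleach_no_noise_constant_histone_mean():
    spec = tiny_spec(movie_noise_sd=0.0, bleach_rate_per_min=0.0,
                     semi_axes_end_um=(3.0, 2.2, 2.2))  # no growth either
    stack, _ = generate_movie(spec)
    means = stack.channel("histone").mean(axis=(1, 2, 3))
    assert np.allclose(means, means[0], rtol=0, atol=1e-12)


def test_rendered_volume_matches_analytic_ellipsoid():
    spec = tiny_spec(movie_noise_sd=0.0, wrinkle_amplitude=0.0)
    stack, gt = generate_movie(spec)
    voxvol = np.prod(spec.voxel_size_um)
    az, ay, ax_ = gt.semi_axes_um[0]
    analytic = 4.0 / 3.0 * np.pi * az * ay * ax_
    for nid in range(spec.n_nuclei):
        rendered = (gt.labels[0] == nid + 1).sum() * voxvol
        assert abs(rendered / analytic - 1) < 0.10


def test_traces_zero_before_onset(small_movie):
    spec, stack, gt = small_movie
    times = spec.times_min()
    sig = gt.signal.to_numpy()
    for nid, onset in zip(gt.nuclei["nucleus_id"], gt.nuclei["onset_min"]):
        if np.isfinite(onset):
            assert (sig[times < onset, nid] == 0).all()
            assert sig[times >= onset, nid].max() > 0
        else:
            assert (sig[:, nid] == 0).all()


def test_onsets_respect_floor():
    rng = np.random.default_rng(0)
    spec = tiny_spec(onset_mean_min=10.0, onset_sd_min=30.0, onset_floor_min=8.0)
    onsets = sample_onsets(rng, 500, spec)
    assert (onsets >= 8.0).all()


class TestTelegraph:
    def test_limit_always_on(self):
        rng = np.random.default_rng(0)
        states = telegraph_states(rng, 50, np.inf, 0.0, 0.5)
        assert states.all()

    def test_stationary_on_fraction_matches_closed_form(self):
        # stationary P(ON) of the two-state chain is k_on / (k_on + k_off)
        k_on, k_off, dt = 2.0, 1.0, 0.5
        rng = np.random.default_rng(1)
        frac = np.mean([telegraph_states(rng, 400, k_on, k_off, dt).mean()
                        for _ in range(60)])
        expected = k_on / (k_on + k_off)
        assert abs(frac - expected) < 0.02

    def test_trace_table_deterministic(self):
        spec = tiny_spec()
        t1 = generate_trace_table(spec)[0]
        t2 = generate_trace_table(spec)[0]
        assert t1.equals(t2)

    def test_trace_table_step_limit(self):
        spec = tiny_spec(k_on_per_min=np.inf, k_off_per_min=0.0,
                         trace_noise_sd=0.0, bleach_rate_per_min=0.0,
                         active_nuclei=[0], onset_mean_min=2.0, onset_sd_min=0.0,
                         onset_floor_min=2.0)
        traces, truth, gt = generate_trace_table(spec)
        sig = gt.signal[0].to_numpy()
        onset_frame = int(np.searchsorted(spec.times_min(), truth["onset_min"][0]))
        assert (sig[:onset_frame] == 0).all()
        assert (sig[onset_frame:] == spec.spot_amplitude_au).all()


def test_front_profile_biphasic():
    spec = tiny_spec(front_slow_um_per_min=0.5, front_fast_um_per_min=1.5,
                     front_breakpoint_min=3.0, duration_min=4.0)
    t = np.array([0.0, 2.0, 3.0, 4.0])
    f = front_length(t, spec)
    assert np.allclose(f, [0.0, 1.0, 1.5, 3.0])


def test_bleach_models():
    spec_exp = tiny_spec(bleach_rate_per_min=0.01)
    t = np.array([0.0, 10.0])
    assert np.allclose(bleach_curve(t, spec_exp), [1.0, np.exp(-0.1)])
    spec_lin = tiny_spec(bleach_rate_per_min=0.01, bleach_model="linear")
    assert np.allclose(bleach_curve(t, spec_lin), [1.0, 0.9])


class TestFrapGenerator:
    def test_fully_immobile_no_recovery(self):
        spec = FrapSpec(immobile_fraction=1.0, acquisition_bleach_per_s=0.01,
                        noise_sd=0.0)
        series, gt = generate_frap_series(spec)
        post = series[spec.n_prebleach:]
        roi = post[:, 50:70, 50:70]  # inside the first bleach disc
        ratio = roi.mean(axis=(1, 2)) / gt.bleach[spec.n_prebleach:]
        assert np.allclose(ratio, ratio[0], rtol=1e-5)

    def test_roi_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            FrapSpec(bleach_centers=[(5, 5)]).validate()

    def test_curve_fit_oracle_recovers_parameters(self):
        # independent least-squares fit of the noiseless ground-truth curve
        spec = FrapSpec(half_time_s=30.0, immobile_fraction=0.2, noise_sd=0.0,
                        n_frames=400, frame_interval_s=0.5)
        _, gt = generate_frap_series(spec)
        t = np.arange(len(gt.recovery)) * spec.frame_interval_s

        def model(t, r0, phi, tau):
            return frap_recovery_curve(t, r0, phi, tau)

        popt, _ = curve_fit(model, t, gt.recovery, p0=(0.5, 0.5, 10.0))
        assert abs(popt[0] - spec.bleach_depth_r0) < 1e-6
        assert abs(popt[1] - spec.immobile_fraction) < 1e-6
        assert abs(popt[2] - spec.half_time_s) < 1e-4
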