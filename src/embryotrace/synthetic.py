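"""Synthetic nc14 blastoderm movies, trace tables and FRAP series with ground truth.

The generator emulates the features of a cellularizing *Drosophila* embryo
movie that the analysis pipeline measures:

* a monolayer grid of ellipsoidal nuclei whose apico-basal semi-axis grows
  during the slow phase of cellularization and whose medial outline wrinkles
  from ~25 min onwards (low-order sinusoidal radial perturbation);
* a membrane front ingressing basally with a slow then a fast phase
  (piecewise-linear ``f(t)`` with a configurable breakpoint, default 35 min);
* bright intranuclear MS2/MCP puncta that switch on at per-nucleus onset
  times and then burst according to a two-state (telegraph) process;
* global photobleaching applied multiplicatively to every channel
  (exponential by default, linear as an option);
* Gaussian read noise and optional Poisson shot noise, added last.

Every stochastic choice flows through one seeded generator, so a fixed seed
yields byte-identical output. The returned :class:`GroundTruth` carries the
true label volumes, tracks, traces, onsets, front curve and bleach curve that
the test-suite and acceptance checks compare against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .stack import ImageStack


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class EmbryoSpec:
    """Parameters of a synthetic nc14 embryo movie.

    Lengths in µm, times in minutes unless stated; intensities in AU.
    """

    # geometry
    nx: int = 5
    ny: int = 5
    shape_zyx: tuple[int, int, int] = (32, 128, 128)
    voxel_size_um: tuple[float, float, float] = (1.25, 0.25, 0.25)  # 5:1:1 anisotropy
    nucleus_spacing_um: float = 6.0     # blastoderm packing
    apical_z_um: float = 3.0            # depth of the apical nuclear surface
    semi_axes_start_um: tuple[float, float, float] = (3.0, 2.2, 2.2)  # (z, y, x)
    semi_axes_end_um: tuple[float, float, float] = (6.0, 2.2, 2.2)
    elongation_end_min: float = 35.0
    nucleus_drift_um: float = 0.0       # per-frame random-walk step (xy)
    drift_max_offset_um: float = 0.7    # cage: crowded nuclei stay near lattice sites

    # wrinkling: radial perturbation of the in-plane outline
    wrinkle_amplitude: float = 0.10
    wrinkle_frequency: int = 5
    wrinkle_start_min: float = 25.0
    wrinkle_ramp_min: float = 5.0

    # timing
    frame_interval_s: float = 30.0
    duration_min: float = 60.0
    nc14_origin_frame: int = 0

    # cellularization front f(t), piecewise linear
    front_slow_um_per_min: float = 0.5
    front_fast_um_per_min: float = 1.5
    front_breakpoint_min: float = 35.0

    # transcription
    active_nuclei: Sequence[int] | None = None  # default: central grid column
    onset_mean_min: float = 30.0
    onset_sd_min: float = 3.0
    onset_floor_min: float = 15.0
    k_on_per_min: float = 2.0
    k_off_per_min: float = 1.0
    spot_amplitude_au: float = 1.0
    spot_sigma_um: float = 0.4

    # intensities
    histone_intensity_au: float = 1.0
    nuclear_background_au: float = 0.3
    cyto_background_au: float = 0.05
    envelope_intensity_au: float = 1.0
    membrane_intensity_au: float = 1.0
    envelope_thickness_um: float = 0.8
    trace_baseline_au: float = 1.0

    # bleaching and noise
    bleach_rate_per_min: float = 0.005  # fraction of signal lost per minute
    bleach_model: str = "exponential"   # or "linear"
    movie_noise_sd: float = 0.15        # Gaussian read noise on voxels
    trace_noise_sd: float = 0.10        # Gaussian noise on trace-table values
    poisson_scale: float = 0.0          # photons per AU; 0 disables shot noise

    # channels
    include_envelope: bool = False
    include_membrane: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _fail(name, msg):
            raise ValueError(f"invalid EmbryoSpec field {name!r}: {msg}")

        for name in ("semi_axes_start_um", "semi_axes_end_um"):
            if any(a <= 0 for a in getattr(self, name)):
                _fail(name, "all semi-axes must be > 0")
        if any(v <= 0 for v in self.voxel_size_um):
            _fail("voxel_size_um", "voxel sizes must be > 0")
        if not (0 < self.front_breakpoint_min <= self.duration_min):
            _fail("front_breakpoint_min", "breakpoint must lie within the movie duration")
        if self.onset_mean_min < 0 or self.onset_floor_min < 0:
            _fail("onset_mean_min", "onset means must be >= 0")
        if self.frame_interval_s <= 0:
            _fail("frame_interval_s", "must be > 0")
        if self.duration_min <= 0:
            _fail("duration_min", "must be > 0")
        if self.bleach_model not in ("exponential", "linear"):
            _fail("bleach_model", "must be 'exponential' or 'linear'")
        if self.bleach_rate_per_min < 0:
            _fail("bleach_rate_per_min", "must be >= 0")
        if self.k_on_per_min < 0 or self.k_off_per_min < 0:
            _fail("k_on_per_min", "telegraph rates must be >= 0")
        if self.nx < 1 or self.ny < 1:
            _fail("nx", "grid must contain at least one nucleus")

    # -- derived ----------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min * 60.0 / self.frame_interval_s))

    @property
    def n_nuclei(self) -> int:
        return self.nx * self.ny

    def times_min(self) -> np.ndarray:
        frames = np.arange(self.n_frames)
        return (frames - self.nc14_origin_frame) * self.frame_interval_s / 60.0

    def default_active(self) -> np.ndarray:
        """Central grid column: the mesectoderm-like single-cell-wide stripe."""
        col = self.nx // 2
        return np.array([j * self.nx + col for j in range(self.ny)], dtype=int)


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    labels: np.ndarray | None            # (t, z, y, x) uint16, 0 = background
    tracks: pd.DataFrame                 # nucleus_id, frame, z_um, y_um, x_um
    nuclei: pd.DataFrame                 # nucleus_id, active, onset_min
    traces_rendered: pd.DataFrame | None  # frames × nucleus_id, incl. bleach
    signal: pd.DataFrame | None          # frames × nucleus_id, bleach-free spot signal
    front_um: np.ndarray | None          # f(t) per frame
    bleach: np.ndarray                   # b(t) per frame
    semi_axes_um: np.ndarray | None      # (t, 3) true (z, y, x) semi-axes
    spec: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def front_length(t_min: np.ndarray, spec: EmbryoSpec) -> np.ndarray:
    """Biphasic membrane length f(t): slow in-growth, then fast after the breakpoint."""
    t = np.asarray(t_min, dtype=float)
    tb = spec.front_breakpoint_min
    f = np.where(
        t < tb,
        spec.front_slow_um_per_min * t,
        spec.front_slow_um_per_min * tb + spec.front_fast_um_per_min * (t - tb),
    )
    return np.clip(f, 0.0, None)


def bleach_curve(t_min: np.ndarray, spec: EmbryoSpec) -> np.ndarray:
    """Global multiplicative bleach factor b(t), b(0)=1."""
    t = np.clip(np.asarray(t_min, dtype=float), 0.0, None)
    if spec.bleach_model == "exponential":
        return np.exp(-spec.bleach_rate_per_min * t)
    return np.clip(1.0 - spec.bleach_rate_per_min * t, 0.0, None)


def semi_axes(t_min: float, spec: EmbryoSpec) -> np.ndarray:
    """Nucleus semi-axes at time t: linear elongation until ``elongation_end_min``."""
    frac = np.clip(t_min / spec.elongation_end_min, 0.0, 1.0) if spec.elongation_end_min > 0 else 1.0
    a0 = np.asarray(spec.semi_axes_start_um, float)
    a1 = np.asarray(spec.semi_axes_end_um, float)
    return a0 + frac * (a1 - a0)


def wrinkle_amplitude_at(t_min: float, spec: EmbryoSpec) -> float:
    """Wrinkle amplitude ramps linearly from 0 over ``wrinkle_ramp_min`` after onset."""
    if spec.wrinkle_amplitude == 0 or t_min <= spec.wrinkle_start_min:
        return 0.0
    ramp = np.clip((t_min - spec.wrinkle_start_min) / max(spec.wrinkle_ramp_min, 1e-9), 0.0, 1.0)
    return float(spec.wrinkle_amplitude * ramp)


def telegraph_states(
    rng: np.random.Generator,
    n_frames: int,
    k_on_per_min: float,
    k_off_per_min: float,
    dt_min: float,
    start_on: bool = True,
) -> np.ndarray:
    """Sample the two-state (telegraph) promoter chain at the frame times.

    The transition probabilities over one frame are the *exact* ones of the
    continuous-time chain, ``P(off→on) = π_on (1 − e^{−(k_on+k_off)·dt})``
    with ``π_on = k_on/(k_on+k_off)`` (and symmetrically for on→off), so the
    sampled chain has exactly the stationary ON fraction ``π_on``. Bursting
    begins in the ON state (an onset is, by definition, the start of an ON
    period).
    """
    if n_frames <= 0:
        return np.zeros(0, dtype=bool)
    if not np.isfinite(k_on_per_min):
        p_on, p_off = 1.0, 0.0
    else:
        total = k_on_per_min + k_off_per_min
        if total <= 0:
            p_on = p_off = 0.0
        else:
            relax = 1.0 - np.exp(-total * dt_min)
            p_on = (k_on_per_min / total) * relax
            p_off = (k_off_per_min / total) * relax
    states = np.empty(n_frames, dtype=bool)
    u = rng.random(n_frames)
    s = bool(start_on)
    for i in range(n_frames):
        states[i] = s
        if s:
            s = not (u[i] < p_off)
        else:
            s = u[i] < p_on
    return states


def sample_onsets(rng: np.random.Generator, n: int, spec: EmbryoSpec) -> np.ndarray:
    """Truncated-normal onset times (min into nc14), floored at ``onset_floor_min``."""
    t = rng.normal(spec.onset_mean_min, spec.onset_sd_min, size=n)
    return np.maximum(t, spec.onset_floor_min)


def _apply_noise(vol: np.ndarray, rng: np.random.Generator, spec: EmbryoSpec) -> np.ndarray:
    if spec.poisson_scale > 0:
        vol = rng.poisson(np.clip(vol, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.movie_noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.movie_noise_sd, size=vol.shape)
    return vol


# ---------------------------------------------------------------------------
# movie generator
# ---------------------------------------------------------------------------

def _grid_centers(spec: EmbryoSpec, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) array of (y, x) nucleus centres in µm, with small fixed jitter."""
    _, ny_px, nx_px = spec.shape_zyx
    _, vy, vx = spec.voxel_size_um
    width_x = nx_px * vx
    width_y = ny_px * vy
    sp = spec.nucleus_spacing_um
    x0 = (width_x - (spec.nx - 1) * sp) / 2.0
    y0 = (width_y - (spec.ny - 1) * sp) / 2.0
    centers = np.array(
        [(y0 + j * sp, x0 + i * sp) for j in range(spec.ny) for i in range(spec.nx)],
        dtype=float,
    )
    jitter = rng.uniform(-0.05 * sp, 0.05 * sp, size=centers.shape)
    return centers + jitter


def _render_nucleus_mask(
    shape_zyx, voxel, center_zyx, axes_zyx, wrinkle_amp, wrinkle_freq, wrinkle_phase,
    shell_thickness_um: float | None = None,
):
    """Boolean mask of one (possibly wrinkled) ellipsoid, within a bounding box.

    Returns ``(slices, mask)``. The wrinkle perturbs the in-plane radius:
    ``r_eff(theta) = 1 + A sin(m theta + phase)``. With
    ``shell_thickness_um`` set, only the outer shell of that physical
    thickness (measured along the normalized radius) is kept.
    """
    vz, vy, vx = voxel
    cz, cy, cx = center_zyx
    az, ay, ax_ = axes_zyx
    pad = 1.0 + abs(wrinkle_amp)
    zlo = max(int(np.floor((cz - az * pad) / vz)) - 1, 0)
    zhi = min(int(np.ceil((cz + az * pad) / vz)) + 2, shape_zyx[0])
    ylo = max(int(np.floor((cy - ay * pad) / vy)) - 1, 0)
    yhi = min(int(np.ceil((cy + ay * pad) / vy)) + 2, shape_zyx[1])
    xlo = max(int(np.floor((cx - ax_ * pad) / vx)) - 1, 0)
    xhi = min(int(np.ceil((cx + ax_ * pad) / vx)) + 2, shape_zyx[2])
    if zlo >= zhi or ylo >= yhi or xlo >= xhi:
        return None, None
    zz = (np.arange(zlo, zhi) + 0.5) * vz - cz
    yy = (np.arange(ylo, yhi) + 0.5) * vy - cy
    xx = (np.arange(xlo, xhi) + 0.5) * vx - cx
    Z = zz[:, None, None]
    Y = yy[None, :, None]
    X = xx[None, None, :]
    if wrinkle_amp != 0.0:
        theta = np.arctan2(Y / ay, X / ax_)
        # irregular wrinkling: a mode-2 (elongating) component plus the
        # configured higher corrugation mode, so wrinkled outlines are both
        # crinkled and more eccentric, as in late-interphase nuclei
        p2, pm = wrinkle_phase
        r_eff = 1.0 + wrinkle_amp * (
            0.5 * np.sin(2 * theta + p2) + np.sin(wrinkle_freq * theta + pm)
        ) / 1.5
    else:
        r_eff = 1.0
    rho2 = (Z / az) ** 2 + (Y / (ay * r_eff)) ** 2 + (X / (ax_ * r_eff)) ** 2
    if shell_thickness_um is None:
        mask = rho2 <= 1.0
    else:
        inner = 1.0 - shell_thickness_um / float(np.mean([az, ay, ax_]))
        mask = (rho2 <= 1.0) & (rho2 >= max(inner, 0.0) ** 2)
    sl = (slice(zlo, zhi), slice(ylo, yhi), slice(xlo, xhi))
    return sl, mask


def generate_movie(spec: EmbryoSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic nc14 movie with full ground truth.

    Channel order: histone, mcp[, envelope][, membrane]. All intensities are
    multiplied by the bleach curve; noise is added last.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nt = spec.n_frames
    nz, ny_px, nx_px = spec.shape_zyx
    vz, vy, vx = spec.voxel_size_um
    times = spec.times_min()
    t_pos = np.clip(times, 0.0, None)

    roles = ["histone", "mcp"]
    if spec.include_envelope:
        roles.append("envelope")
    if spec.include_membrane:
        roles.append("membrane")
    data = np.zeros((nt, len(roles), nz, ny_px, nx_px), dtype=np.float32)

    centers0 = _grid_centers(spec, rng)
    n = spec.n_nuclei
    wrinkle_phases = rng.uniform(0, 2 * np.pi, size=(n, 2))
    if spec.nucleus_drift_um > 0:
        steps = rng.normal(0.0, spec.nucleus_drift_um, size=(nt, n, 2))
        # bounded random walk: cumulative offsets are clipped so crowded
        # nuclei jiggle around their lattice sites without interpenetrating
        offsets = np.clip(
            np.cumsum(steps, axis=0),
            -spec.drift_max_offset_um,
            spec.drift_max_offset_um,
        )
    else:
        offsets = np.zeros((nt, n, 2))

    active_ids = (
        np.asarray(spec.active_nuclei, dtype=int)
        if spec.active_nuclei is not None
        else spec.default_active()
    )
    if np.any((active_ids < 0) | (active_ids >= n)):
        raise ValueError("invalid EmbryoSpec field 'active_nuclei': ids out of range")
    onsets = np.full(n, np.nan)
    onsets[active_ids] = sample_onsets(rng, len(active_ids), spec)

    dt_min = spec.frame_interval_s / 60.0
    states = np.zeros((n, nt), dtype=bool)
    for i in active_ids:
        onset_frame = int(np.searchsorted(times, onsets[i]))
        if onset_frame < nt:
            states[i, onset_frame:] = telegraph_states(
                rng, nt - onset_frame, spec.k_on_per_min, spec.k_off_per_min, dt_min
            )
            # true onset is realised at the first rendered ON frame
            onsets[i] = times[onset_frame]

    bleach = bleach_curve(t_pos, spec)
    front = front_length(t_pos, spec)

    labels = np.zeros((nt, nz, ny_px, nx_px), dtype=np.uint16)
    track_rows = []
    trace_rendered = np.full((nt, n), np.nan)
    signal = np.zeros((nt, n))

    # membrane wall positions: grid lines midway between nucleus columns/rows
    centers_sorted_x = np.unique(np.round(centers0[:, 1], 3))
    centers_sorted_y = np.unique(np.round(centers0[:, 0], 3))

    for t in range(nt):
        ax_t = semi_axes(t_pos[t], spec)
        w_amp = wrinkle_amplitude_at(t_pos[t], spec)
        cz = spec.apical_z_um + ax_t[0]  # apical surface pinned, growth is basal
        centers_t = centers0 + offsets[t]

        hist = np.full((nz, ny_px, nx_px), spec.cyto_background_au, dtype=np.float64)
        mcp = np.full_like(hist, spec.cyto_background_au)
        env = np.zeros_like(hist) if spec.include_envelope else None
        mem = np.zeros_like(hist) if spec.include_membrane else None

        for i in range(n):
            cy, cx = centers_t[i]
            sl, mask = _render_nucleus_mask(
                (nz, ny_px, nx_px), (vz, vy, vx), (cz, cy, cx), ax_t,
                w_amp, spec.wrinkle_frequency, wrinkle_phases[i],
            )
            if mask is None or not mask.any():
                continue
            region = labels[t][sl]
            paint = mask & (region == 0)
            region[paint] = i + 1
            hist[sl][paint] = spec.histone_intensity_au
            mcp[sl][paint] = spec.nuclear_background_au
            if env is not None:
                _, shell = _render_nucleus_mask(
                    (nz, ny_px, nx_px), (vz, vy, vx), (cz, cy, cx), ax_t,
                    w_amp, spec.wrinkle_frequency, wrinkle_phases[i],
                    shell_thickness_um=spec.envelope_thickness_um,
                )
                env[sl][shell] = spec.envelope_intensity_au

            # centroid of the painted voxels, in µm (voxel-centre convention)
            idx = np.argwhere(paint)
            c_vox = idx.mean(axis=0) + np.array([sl[0].start, sl[1].start, sl[2].start])
            track_rows.append(
                (i, t, (c_vox[0] + 0.5) * vz, (c_vox[1] + 0.5) * vy, (c_vox[2] + 0.5) * vx)
            )

            # MS2 punctum: Gaussian blob centred on the nearest voxel centre
            if states[i, t]:
                pz = int(np.clip(round(cz / vz - 0.5), 0, nz - 1))
                py = int(np.clip(round(cy / vy - 0.5), 0, ny_px - 1))
                px = int(np.clip(round(cx / vx - 0.5), 0, nx_px - 1))
                s_sl, s_mask = _render_nucleus_mask(
                    (nz, ny_px, nx_px), (vz, vy, vx),
                    ((pz + 0.5) * vz, (py + 0.5) * vy, (px + 0.5) * vx),
                    (max(3 * spec.spot_sigma_um, vz), 3 * spec.spot_sigma_um, 3 * spec.spot_sigma_um),
                    0.0, 0, 0.0,
                )
                if s_mask is not None:
                    zz = (np.arange(s_sl[0].start, s_sl[0].stop) + 0.5) * vz - (pz + 0.5) * vz
                    yy = (np.arange(s_sl[1].start, s_sl[1].stop) + 0.5) * vy - (py + 0.5) * vy
                    xx = (np.arange(s_sl[2].start, s_sl[2].stop) + 0.5) * vx - (px + 0.5) * vx
                    d2 = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
                          + xx[None, None, :] ** 2)
                    blob = spec.spot_amplitude_au * np.exp(-d2 / (2 * spec.spot_sigma_um ** 2))
                    mcp[s_sl] += blob
                signal[t, i] = spec.spot_amplitude_au

            in_nuc = labels[t] == i + 1
            trace_rendered[t, i] = mcp[in_nuc].max() * bleach[t]

        if mem is not None:
            z0 = int(round(spec.apical_z_um / vz))
            z1 = int(np.clip(np.floor((spec.apical_z_um + front[t]) / vz), z0, nz - 1))
            xcols = [int(np.clip(round((cxm + spec.nucleus_spacing_um / 2) / vx - 0.5), 0, nx_px - 1))
                     for cxm in centers_sorted_x[:-1]]
            yrows = [int(np.clip(round((cym + spec.nucleus_spacing_um / 2) / vy - 0.5), 0, ny_px - 1))
                     for cym in centers_sorted_y[:-1]]
            if front[t] > 0:
                # walls two pixels wide: a one-pixel sheet at this sampling
                # would be thinner than any real imaged membrane
                for xc in xcols:
                    mem[z0:z1 + 1, :, xc:xc + 2] = spec.membrane_intensity_au
                for yr in yrows:
                    mem[z0:z1 + 1, yr:yr + 2, :] = spec.membrane_intensity_au
            # apical surface (present throughout), two z-rows like the walls
            mem[z0:z0 + 2, :, :] = spec.membrane_intensity_au

        vols = [hist, mcp] + [v for v in (env, mem) if v is not None]
        for c, vol in enumerate(vols):
            data[t, c] = _apply_noise(vol * bleach[t], rng, spec).astype(np.float32)

    stack = ImageStack(
        data=data,
        voxel_size_um=spec.voxel_size_um,
        frame_interval_s=spec.frame_interval_s,
        nc14_origin_frame=spec.nc14_origin_frame,
        channels={role: i for i, role in enumerate(roles)},
    )
    tracks = pd.DataFrame(track_rows, columns=["nucleus_id", "frame", "z_um", "y_um", "x_um"])
    nuclei = pd.DataFrame(
        {
            "nucleus_id": np.arange(n),
            "active": np.isin(np.arange(n), active_ids),
            "onset_min": onsets,
        }
    )
    gt = GroundTruth(
        labels=labels,
        tracks=tracks,
        nuclei=nuclei,
        traces_rendered=pd.DataFrame(trace_rendered, columns=np.arange(n)),
        signal=pd.DataFrame(signal, columns=np.arange(n)),
        front_um=front,
        bleach=bleach,
        semi_axes_um=np.stack([semi_axes(tp, spec) for tp in t_pos]),
        spec=asdict(spec),
    )
    return stack, gt


# ---------------------------------------------------------------------------
# trace-table generator (transcription module tested in isolation)
# ---------------------------------------------------------------------------

def generate_trace_table(spec: EmbryoSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-nucleus max-fluorescence proxy traces without rendering a movie.

    Returns ``(traces, truth, gt)``: ``traces`` is a frames × nucleus DataFrame
    of trace values; ``truth`` has columns nucleus_id / active / onset_min.
    Inactive nuclei fluctuate about the bleached baseline; active nuclei gain
    telegraph bursts of ``spot_amplitude_au`` after their onset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nt = spec.n_frames
    n = spec.n_nuclei
    times = spec.times_min()
    t_pos = np.clip(times, 0.0, None)
    bleach = bleach_curve(t_pos, spec)

    active_ids = (
        np.asarray(spec.active_nuclei, dtype=int)
        if spec.active_nuclei is not None
        else spec.default_active()
    )
    onsets = np.full(n, np.nan)
    onsets[active_ids] = sample_onsets(rng, len(active_ids), spec)

    dt_min = spec.frame_interval_s / 60.0
    values = np.empty((nt, n))
    signal = np.zeros((nt, n))
    for i in range(n):
        base = spec.trace_baseline_au * bleach
        if i in active_ids:
            onset_frame = int(np.searchsorted(times, onsets[i]))
            if onset_frame < nt:
                st = telegraph_states(
                    rng, nt - onset_frame, spec.k_on_per_min, spec.k_off_per_min, dt_min
                )
                signal[onset_frame:, i] = spec.spot_amplitude_au * st
                onsets[i] = times[onset_frame]
        values[:, i] = (spec.trace_baseline_au + signal[:, i]) * bleach
    if spec.trace_noise_sd > 0:
        values = values + rng.normal(0.0, spec.trace_noise_sd, size=values.shape)

    traces = pd.DataFrame(values, columns=np.arange(n))
    truth = pd.DataFrame(
        {
            "nucleus_id": np.arange(n),
            "active": np.isin(np.arange(n), active_ids),
            "onset_min": onsets,
        }
    )
    gt = GroundTruth(
        labels=None,
        tracks=pd.DataFrame(),
        nuclei=truth,
        traces_rendered=traces,
        signal=pd.DataFrame(signal, columns=np.arange(n)),
        front_um=None,
        bleach=bleach,
        semi_axes_um=None,
        spec=asdict(spec),
    )
    return traces, truth, gt


# ---------------------------------------------------------------------------
# FRAP generator
# ---------------------------------------------------------------------------

@dataclass
class FrapSpec:
    """Parameters of a synthetic FRAP acquisition (2-D field over time)."""

    shape_yx: tuple[int, int] = (200, 200)
    n_frames: int = 140
    n_prebleach: int = 10
    frame_interval_s: float = 0.5
    bleach_centers: Sequence[tuple[int, int]] = ((60, 60), (60, 140), (140, 100))
    roi_diameter_px: int = 20
    n_controls: int = 6
    plateau_au: float = 1.0
    bleach_depth_r0: float = 0.4          # first post-bleach relative intensity
    immobile_fraction: float = 0.2
    half_time_s: float = 10.0
    acquisition_bleach_per_s: float = 0.0  # global exponential decay rate
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape_yx
        r = self.roi_diameter_px / 2.0
        for cy, cx in self.bleach_centers:
            if not (r <= cy <= h - r and r <= cx <= w - r):
                raise ValueError(f"bleach ROI centre ({cy}, {cx}) outside field {self.shape_yx}")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if not (0.0 < self.bleach_depth_r0 < 1.0):
            raise ValueError("bleach_depth_r0 must lie in (0, 1)")
        if not (0.0 <= self.immobile_fraction <= 1.0):
            raise ValueError("immobile_fraction must lie in [0, 1]")
        if self.half_time_s <= 0:
            raise ValueError("half_time_s must be > 0")


@dataclass
class FrapGroundTruth:
    r0: float
    immobile_fraction: float
    mobile_fraction: float
    half_time_s: float
    recovery: np.ndarray       # true r(t) for post-bleach frames
    bleach: np.ndarray         # global acquisition decay per frame
    control_centers: list


def frap_recovery_curve(t_s: np.ndarray, r0: float, immobile: float, tau_s: float) -> np.ndarray:
    """True normalized recovery: r(t) = 1 − (1−r0)·(φ + (1−φ)·2^(−t/τ)).

    ``r(0) = r0`` and ``r(∞) = 1 − (1−r0)·φ``; after zero-scaling the plateau
    equals the mobile fraction ``1 − φ``.
    """
    t = np.asarray(t_s, dtype=float)
    return 1.0 - (1.0 - r0) * (immobile + (1.0 - immobile) * np.exp(-t * np.log(2.0) / tau_s))


def generate_frap_series(spec: FrapSpec) -> tuple[np.ndarray, "FrapGroundTruth"]:
    """Render a synthetic FRAP movie ``(t, y, x)`` and its ground truth.

    Pre-bleach frames sit at the plateau; at the bleach frame every bleach ROI
    drops to ``r0`` of the plateau and recovers along
    :func:`frap_recovery_curve`; a global acquisition-bleaching exponential is
    applied to the whole field; Gaussian noise is added last.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_yx
    t_frames = np.arange(spec.n_frames)
    t_s = t_frames * spec.frame_interval_s
    decay = np.exp(-spec.acquisition_bleach_per_s * t_s)

    post = t_frames >= spec.n_prebleach
    t_post = (t_frames[post] - spec.n_prebleach) * spec.frame_interval_s
    recovery = frap_recovery_curve(t_post, spec.bleach_depth_r0,
                                   spec.immobile_fraction, spec.half_time_s)

    yy, xx = np.mgrid[0:h, 0:w]
    field = np.full((spec.n_frames, h, w), spec.plateau_au, dtype=np.float64)
    r = spec.roi_diameter_px / 2.0
    for cy, cx in spec.bleach_centers:
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        for k, t in enumerate(np.nonzero(post)[0]):
            field[t][mask] = spec.plateau_au * recovery[k]

    # control ROI centres on a deterministic ring away from bleach spots
    controls = []
    cy0, cx0 = h / 2.0, w / 2.0
    ring = min(h, w) / 2.0 - 1.5 * r
    k = 0
    while len(controls) < spec.n_controls and k < 10 * spec.n_controls:
        ang = 2 * np.pi * k / max(spec.n_controls, 1) + 0.3
        cand = (cy0 + ring * np.sin(ang), cx0 + ring * np.cos(ang))
        k += 1
        if all((cand[0] - by) ** 2 + (cand[1] - bx) ** 2 > (2.5 * r) ** 2
               for by, bx in spec.bleach_centers):
            controls.append((float(cand[0]), float(cand[1])))
    if len(controls) < spec.n_controls:
        raise ValueError("could not place control ROIs away from bleach ROIs")

    series = field * decay[:, None, None]
    if spec.noise_sd > 0:
        series = series + rng.normal(0.0, spec.noise_sd, size=series.shape)

    gt = FrapGroundTruth(
        r0=spec.bleach_depth_r0,
        immobile_fraction=spec.immobile_fraction,
        mobile_fraction=1.0 - spec.immobile_fraction,
        half_time_s=spec.half_time_s,
        recovery=recovery,
        bleach=decay,
        control_centers=controls,
    )
    return series.astype(np.float32), gt
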