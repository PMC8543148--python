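"""Pipeline configuration.

Every numeric knob of the analysis lives here with its default. Defaults follow
the quantification protocol this package implements: 3-voxel median filter,
6 µm tracking gate with 2-frame lookback, >10-frame track retention, ON calling
at 1.2× baseline with ≥5 ON frames, onset search from 15 min into nc14 (30 min
under maternal Gal4), output window 30–50 min, envelope segmentation at a 10%
intensity threshold with a 10–200 µm³ size range and a 4 µm / 5-frame tracker,
nuclear slices at 25/50/75% of the apico-basal extent, and FRAP ROIs of 20 px
diameter with six controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class PipelineConfig:
    # --- histone-channel nucleus segmentation ---
    median_filter_size: int = 3
    contrast_percentiles: tuple[float, float] = (1.0, 99.0)
    object_scale_um: float = 5.0          # expected in-plane nucleus diameter
    segmentation_threshold: float = 0.40  # fraction of enhanced dynamic range
    size_bounds_um3: tuple[float, float] = (20.0, 800.0)
    thickening_radius_vox: int = 0        # optional; the band-pass keeps edges

    # --- nucleus tracking ---
    tracking_gate_um: float = 6.0
    lookback_frames: int = 2

    # --- transcription trace processing ---
    min_track_length: int = 10            # retained if tracked for MORE than this
    activity_factor: float = 1.2
    min_on_frames: int = 5
    on_frames_consecutive: bool = False   # five total ON frames by default
    trace_median_filter: int = 3
    # photobleaching normalization: divide by the inactive-pool decay ratio.
    # "mixed" subtracts the fitted straight-line baseline and divides by the
    # empirical inactive-mean ratio; "fit" uses the fitted line for both;
    # "empirical" uses the inactive-pool mean for both (exact cancellation of
    # any global multiplicative decay in the noiseless limit).
    bleach_norm_mode: str = "mixed"
    onset_search_start_min: float = 15.0
    maternal_gal4: bool = False           # shifts onset search start to 30 min
    onset_search_start_gal4_min: float = 30.0
    output_window_min: tuple[float, float] = (30.0, 50.0)

    # --- nuclear-envelope segmentation ---
    envelope_sigma_vox: float = 1.0
    envelope_threshold: float = 0.10      # fraction of intensity range above min
    envelope_size_bounds_um3: tuple[float, float] = (10.0, 200.0)
    envelope_gate_um: float = 4.0
    envelope_lookback: int = 5
    active_contour_iters: int = 50
    vitelline_footprint_fraction: float = 0.25

    # --- morphology ---
    slice_fractions: tuple[float, ...] = (0.25, 0.50, 0.75)
    extent_percentiles: tuple[float, float] = (10.0, 90.0)

    # --- cellularization front ---
    front_invert: bool = False            # transmitted-light sections
    front_smooth_frames: int = 3

    # --- FRAP ---
    frap_roi_diameter_px: int = 20
    frap_control_count: int = 6
    frap_scale_mode: str = "rescale"      # or "offset"

    # --- misc ---
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _fail(name, msg):
            raise ValueError(f"invalid config field {name!r}: {msg}")

        if self.median_filter_size < 1:
            _fail("median_filter_size", "must be >= 1")
        lo, hi = self.contrast_percentiles
        if not (0 <= lo < hi <= 100):
            _fail("contrast_percentiles", "need 0 <= low < high <= 100")
        if self.object_scale_um <= 0:
            _fail("object_scale_um", "must be > 0")
        for name in ("segmentation_threshold", "envelope_threshold",
                     "vitelline_footprint_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                _fail(name, "must lie in (0, 1)")
        for name in ("tracking_gate_um", "envelope_gate_um"):
            if getattr(self, name) <= 0:
                _fail(name, "gate must be > 0")
        for name in ("size_bounds_um3", "envelope_size_bounds_um3"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                _fail(name, "need 0 <= low < high")
        w0, w1 = self.output_window_min
        if not w0 < w1:
            _fail("output_window_min", "window start must precede end")
        if self.frap_scale_mode not in ("rescale", "offset"):
            _fail("frap_scale_mode", "must be 'rescale' or 'offset'")
        if self.bleach_norm_mode not in ("mixed", "fit", "empirical"):
            _fail("bleach_norm_mode", "must be 'mixed', 'fit' or 'empirical'")
        if self.min_on_frames < 1:
            _fail("min_on_frames", "must be >= 1")

    @property
    def onset_start_min(self) -> float:
        """Effective onset search start, honouring maternal-Gal4 mode."""
        return (self.onset_search_start_gal4_min if self.maternal_gal4
                else self.onset_search_start_min)

    # --- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for name, f in cls.__dataclass_fields__.items():
            if name in d and isinstance(getattr(cls, name, None), tuple):
                d[name] = tuple(d[name])
            elif name in d and isinstance(d[name], list):
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
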