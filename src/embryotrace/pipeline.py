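"""End-to-end pipeline runner and run manifest.

Stages: segment+track nuclei → extract and process MS2 traces → morphology →
cellularization front and landmarks. Every output directory receives exactly
one ``manifest.json`` recording the config echo, input hash, seed, package
version, per-stage timings and warnings — enough to re-run the stage.
All tables are CSV with a one-line header; times are minutes into nc14,
coordinates µm from the volume corner, frame indices 0-based.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .stack import ImageStack
from .segmentation import segment_movie
from .tracking import track_nuclei, extract_traces
from .transcription import process_traces, cohort_profile, heatmap_matrix
from .morphology import measure_movie
from .cellularization import front_length_timeseries, landmark_times


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_sha256: str | None = None
    stages: dict = field(default_factory=dict)      # stage -> {"seconds": float, "skipped": bool}
    warnings: list = field(default_factory=list)

    def write(self, out_dir: Path) -> None:
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(
    stack: ImageStack,
    config: PipelineConfig,
    out_dir,
    stages: tuple[str, ...] = ("track", "traces", "morphology", "front"),
    input_path=None,
    landmarks_um: dict[str, float] | None = None,
) -> RunManifest:
    """Run the enabled stages on a loaded stack and write CSV/JSON outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    if input_path is not None:
        manifest.input_sha256 = hash_file(input_path)
    times = stack.times_min()

    label_volumes = None
    trackset = None

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        for stage in ("track", "traces", "morphology", "front"):
            if stage not in stages:
                manifest.stages[stage] = {"skipped": True}
                continue
            t0 = time.perf_counter()

            if stage == "track":
                label_volumes = segment_movie(
                    stack.channel("histone"), config, stack.voxel_size_um
                )
                trackset = track_nuclei(
                    label_volumes, stack.voxel_size_um,
                    gate_um=config.tracking_gate_um, lookback=config.lookback_frames,
                )
                table = trackset.table.copy()
                table["t_min"] = times[table["frame"].to_numpy()]
                _write_csv(
                    table[["track_id", "frame", "t_min", "x_um", "y_um", "z_um",
                           "label", "new_track", "conflict"]],
                    out_dir / "tracks.csv",
                )

            elif stage == "traces":
                if trackset is None:
                    raise ValueError("traces stage requires the track stage")
                raw = extract_traces(trackset, label_volumes, stack.channel("mcp"))
                raw_out = raw.copy()
                raw_out.insert(0, "t_min", times)
                raw_out.insert(0, "frame", np.arange(stack.n_frames))
                _write_csv(raw_out, out_dir / "traces.csv")
                ts = process_traces(raw, times, config)
                nuclei = pd.DataFrame(
                    {
                        "track_id": ts.onsets.index,
                        "active": [bool(ts.active.get(c, False)) for c in ts.onsets.index],
                        "onset_min": ts.onsets.to_numpy(),
                        "output_au": [float(ts.outputs.get(c, np.nan)) for c in ts.onsets.index],
                        "class": [ts.output_class.get(c, "") for c in ts.onsets.index],
                    }
                )
                _write_csv(nuclei, out_dir / "nuclei.csv")
                _write_csv(cohort_profile(ts), out_dir / "cohort.csv")
                heat = heatmap_matrix(ts)
                heat.insert(0, "track_id", heat.index)
                _write_csv(heat, out_dir / "heatmap.csv")

            elif stage == "morphology":
                if trackset is None:
                    raise ValueError("morphology stage requires the track stage")
                morph = measure_movie(
                    label_volumes, trackset.table, stack.voxel_size_um, times,
                    fractions=config.slice_fractions,
                )
                _write_csv(morph, out_dir / "morphology.csv")

            elif stage == "front":
                if "membrane" not in stack.channels and "transmitted" not in stack.channels:
                    manifest.stages[stage] = {"skipped": True,
                                              "reason": "no membrane/transmitted channel"}
                    continue
                role = "membrane" if "membrane" in stack.channels else "transmitted"
                chan = stack.channel(role)
                x_mid = chan.shape[3] // 2
                sections = chan[:, :, :, x_mid]  # (t, z, y) central orthogonal section
                invert = config.front_invert or role == "transmitted"
                front = front_length_timeseries(
                    sections, stack.voxel_size_um[0], times, invert=invert
                )
                _write_csv(front.table, out_dir / "front.csv")
                if landmarks_um:
                    lm = landmark_times(front, landmarks_um, config.front_smooth_frames)
                    with open(out_dir / "landmarks.json", "w") as fh:
                        json.dump(lm.to_dict(orient="records"), fh, indent=2)
                        fh.write("\n")

            manifest.stages[stage] = {
                "skipped": False,
                "seconds": round(time.perf_counter() - t0, 3),
            }

        manifest.warnings = sorted({str(w.message) for w in caught})
    manifest.write(out_dir)
    return manifest
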