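"""Nearest-centroid nucleus tracking and spot-proxy trace extraction.

The linking rule: each object at frame *t* links to the nearest centroid
(physical µm distance) strictly within the gate, searching frame *t−1* first
and then deeper frames up to the configured lookback; if no candidate exists
the object starts a new track, and if two objects claim the same predecessor
*both* start new tracks. Only track tails (objects without a successor) are
linkable, so a track holds at most one object per frame. Ties between
equidistant candidates break toward the shallower frame, then the lower label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class TrackSet:
    """Identity-linked tracks over a labelled movie.

    ``table`` columns: track_id, frame, label, z_um, y_um, x_um, new_track
    (no predecessor found), conflict (predecessor contested).
    """

    table: pd.DataFrame

    @property
    def track_ids(self) -> np.ndarray:
        return np.unique(self.table["track_id"].to_numpy())

    def track_lengths(self) -> pd.Series:
        return self.table.groupby("track_id").size()

    def filter_min_length(self, min_frames: int) -> "TrackSet":
        """Keep tracks present for strictly more than ``min_frames`` frames."""
        lengths = self.track_lengths()
        keep = lengths[lengths > min_frames].index
        return TrackSet(self.table[self.table["track_id"].isin(keep)].reset_index(drop=True))


def frame_centroids(labels: np.ndarray, voxel_size_um) -> tuple[np.ndarray, np.ndarray]:
    """Labels present in a frame and their centroids in µm (voxel-centre convention)."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return ids, np.zeros((0, 3))
    cents = np.array(ndimage.center_of_mass(labels > 0, labels, ids), dtype=float)
    cents = (cents + 0.5) * np.asarray(voxel_size_um, dtype=float)
    return ids, cents


def link_centroids(
    frames: list[tuple[np.ndarray, np.ndarray]],
    gate_um: float,
    lookback: int,
) -> pd.DataFrame:
    """Link per-frame (ids, centroids-µm) lists into tracks.

    Returns the TrackSet table (without voxel labels resolved — the ``label``
    column holds the per-frame object id passed in).
    """
    rows = []  # (track_id, frame, label, z, y, x, new_track, conflict)
    next_track = 0
    # per recent frame: list of (object_key, centroid, track_id, is_tail)
    tails: dict[tuple[int, int], int] = {}   # (frame, label) -> track_id
    history: list[tuple[int, np.ndarray, np.ndarray]] = []  # (frame, ids, cents)

    for t, (ids, cents) in enumerate(frames):
        proposals: dict[int, tuple[int, int] | None] = {}
        for k, oid in enumerate(ids):
            chosen = None
            for db in range(1, lookback + 1):
                prev = next(((f, pi, pc) for f, pi, pc in reversed(history) if f == t - db), None)
                if prev is None:
                    continue
                pf, pids, pcents = prev
                cand = [
                    (float(np.linalg.norm(cents[k] - pcents[j])), int(pids[j]))
                    for j in range(len(pids))
                    if (pf, int(pids[j])) in tails
                ]
                cand = [(d, lab) for d, lab in cand if d < gate_um]
                if cand:
                    cand.sort(key=lambda c: (c[0], c[1]))
                    chosen = (pf, cand[0][1])
                    break
            proposals[k] = chosen

        # resolve conflicts: predecessors claimed more than once
        claims: dict[tuple[int, int], list[int]] = {}
        for k, pred in proposals.items():
            if pred is not None:
                claims.setdefault(pred, []).append(k)
        contested = {pred for pred, ks in claims.items() if len(ks) > 1}

        for k, oid in enumerate(ids):
            pred = proposals[k]
            conflict = pred in contested
            if pred is None or conflict:
                tid = next_track
                next_track += 1
                new = True
            else:
                tid = tails.pop(pred)
                new = False
            tails[(t, int(oid))] = tid
            rows.append(
                (tid, t, int(oid), cents[k][0], cents[k][1], cents[k][2], new, conflict)
            )
        for pred in contested:
            tails.pop(pred, None)  # contested predecessor's track ends here

        history.append((t, ids, cents))
        history = [h for h in history if h[0] >= t - lookback + 1]
        tails = {key: tid for key, tid in tails.items() if key[0] >= t - lookback + 1}

    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "label", "z_um", "y_um", "x_um", "new_track", "conflict"],
    )


def track_nuclei(
    label_volumes: list[np.ndarray],
    voxel_size_um,
    gate_um: float = 6.0,
    lookback: int = 2,
) -> TrackSet:
    """Track labelled 3-D volumes across frames (histone pipeline defaults)."""
    if len(label_volumes) < 1:
        raise ValueError("need at least one frame")
    shapes = {v.shape for v in label_volumes}
    if len(shapes) > 1:
        raise ValueError(f"mismatched frame shapes: {shapes}")
    frames = [frame_centroids(lab, voxel_size_um) for lab in label_volumes]
    return TrackSet(link_centroids(frames, gate_um, lookback))


def extract_traces(
    trackset: TrackSet,
    label_volumes: list[np.ndarray],
    mcp: np.ndarray,
) -> pd.DataFrame:
    """Max-MCP-intensity proxy trace per track.

    For every frame where a track is present, the trace value is the maximum
    MCP intensity over the nucleus's voxels; absent frames are NaN. The
    maximum over the nuclear mask serves as the spot-fluorescence proxy (no
    sub-voxel spot fitting).
    """
    tids = trackset.track_ids
    n_frames = len(label_volumes)
    out = pd.DataFrame(np.nan, index=np.arange(n_frames), columns=tids)
    for frame, sub in trackset.table.groupby("frame"):
        lab = label_volumes[frame]
        vol = mcp[frame]
        maxima = ndimage.labeled_comprehension(
            vol, lab, sub["label"].to_numpy(), np.max, float, np.nan
        )
        for (tid, label), mval in zip(sub[["track_id", "label"]].to_numpy(), np.atleast_1d(maxima)):
            if np.isnan(mval):
                warnings.warn(f"track {tid}: empty mask at frame {frame}")
            out.at[frame, tid] = mval
    return out
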