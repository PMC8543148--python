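"""Calibrated multichannel image stacks and OME-TIFF I/O.

The in-memory container for every movie in the pipeline is :class:`ImageStack`:
a ``(t, c, z, y, x)`` voxel array plus physical calibration (anisotropic voxel
sizes in µm, frame interval in s), the frame index taken as the start of
nuclear cycle 14, and a mapping from channel *roles* (``histone``, ``mcp``,
``envelope``, ``membrane``, ``transmitted``) to channel indices.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile

CHANNEL_ROLES = ("histone", "mcp", "envelope", "membrane", "transmitted")


@dataclass
class ImageStack:
    """A calibrated 5-D fluorescence movie.

    Parameters
    ----------
    data
        Voxel intensities indexed ``(t, c, z, y, x)`` (arbitrary units).
    voxel_size_um
        Physical voxel edge lengths ``(z, y, x)`` in µm; z is typically the
        coarse axis on a confocal stack.
    frame_interval_s
        Time between consecutive frames, seconds.
    nc14_origin_frame
        Frame index corresponding to the end of the 13th syncytial division;
        all reported times are minutes relative to this frame.
    channels
        Mapping from channel role to channel index along axis 1.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    frame_interval_s: float
    nc14_origin_frame: int = 0
    channels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"data must be 5-D (t, c, z, y, x); got shape {self.data.shape}"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be three positive values; got {self.voxel_size_um}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if not (0 <= self.nc14_origin_frame < self.data.shape[0]):
            raise ValueError(
                f"nc14_origin_frame {self.nc14_origin_frame} outside frame range "
                f"[0, {self.data.shape[0]})"
            )
        seen: dict[int, str] = {}
        for role, idx in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if not (0 <= idx < self.data.shape[1]):
                raise ValueError(f"channel index {idx} for role {role!r} out of range")
            if idx in seen:
                raise ValueError(f"channel index {idx} assigned to both {seen[idx]!r} and {role!r}")
            seen[idx] = role

    # -- convenience -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def times_min(self) -> np.ndarray:
        """Time of each frame in minutes into nc14."""
        frames = np.arange(self.n_frames)
        return (frames - self.nc14_origin_frame) * self.frame_interval_s / 60.0

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(t, z, y, x)`` sub-array for a channel role."""
        if role not in self.channels:
            raise KeyError(f"stack has no channel with role {role!r}; roles: {sorted(self.channels)}")
        return self.data[:, self.channels[role]]


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF (axes TCZYX) with calibration.

    Channel roles are stored as OME channel names so that :func:`read_stack`
    round-trips them.
    """
    vz, vy, vx = stack.voxel_size_um
    names = [""] * stack.n_channels
    for role, idx in stack.channels.items():
        names[idx] = role
    metadata = {
        "axes": "TCZYX",
        "PhysicalSizeZ": vz,
        "PhysicalSizeY": vy,
        "PhysicalSizeX": vx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
        "TimeIncrement": stack.frame_interval_s,
        "TimeIncrementUnit": "s",
        "Channel": {"Name": names},
    }
    tifffile.imwrite(str(path), stack.data, ome=True, metadata=metadata)


def _parse_ome_calibration(ome_xml: str) -> dict:
    """Pull voxel sizes, frame interval and channel names out of OME XML."""
    out: dict = {}
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return out
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag.split("}")[0] + "}"
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return out
    for key, attr in [
        ("voxel_z", "PhysicalSizeZ"),
        ("voxel_y", "PhysicalSizeY"),
        ("voxel_x", "PhysicalSizeX"),
        ("frame_interval", "TimeIncrement"),
    ]:
        if attr in pixels.attrib:
            out[key] = float(pixels.attrib[attr])
    names = [ch.attrib.get("Name", "") for ch in pixels.findall(f"{ns}Channel")]
    if names:
        out["channel_names"] = names
    return out


def read_stack(
    path,
    channel_map: dict[str, int] | None = None,
    voxel_size_um: tuple[float, float, float] | None = None,
    frame_interval_s: float | None = None,
    nc14_origin_frame: int = 0,
) -> ImageStack:
    """Read a TIFF/OME-TIFF movie into a normalized ``(t, c, z, y, x)`` stack.

    Calibration is taken from OME metadata where present; explicit arguments
    override metadata. Missing calibration that cannot be resolved raises a
    ``ValueError`` naming the absent fields. A file without a z axis is
    rejected (this pipeline is 3-D throughout).
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        meta = _parse_ome_calibration(tif.ome_metadata) if tif.ome_metadata else {}

    # Treat sample/other singleton axes as removable; normalize to TCZYX.
    axes = axes.replace("S", "C") if "C" not in axes else axes
    # plain TIFFs come back with unknown ('Q'/'I') axes: assume the leading
    # unknown dimensions are T then Z (the TZYX convention), which a channel
    # map in the config can re-interpret
    unknown = [i for i, ax in enumerate(axes) if ax in "QI"]
    if unknown:
        missing = [ax for ax in ("T", "Z", "C") if ax not in axes]
        axes = list(axes)
        for i, ax in zip(unknown, missing):
            axes[i] = ax
        axes = "".join(axes)
    keep = []
    for ax, size in zip(axes, data.shape):
        if ax not in "TCZYX":
            if size != 1:
                raise ValueError(f"unsupported axis {ax!r} of length {size} in {path}")
            continue
        keep.append(ax)
    data = data.reshape([s for ax, s in zip(axes, data.shape) if ax in "TCZYX"])
    axes = "".join(keep)

    if "Z" not in axes:
        raise ValueError(f"{path}: no z axis (axes {axes!r}); 3-D stacks are required")
    for missing_ax in "TC":
        if missing_ax not in axes:
            data = data[np.newaxis]
            axes = missing_ax + axes
    order = [axes.index(ax) for ax in "TCZYX"]
    data = np.transpose(data, order)

    vz = vy = vx = None
    if voxel_size_um is not None:
        vz, vy, vx = voxel_size_um
    else:
        vz, vy, vx = meta.get("voxel_z"), meta.get("voxel_y"), meta.get("voxel_x")
    if frame_interval_s is None:
        frame_interval_s = meta.get("frame_interval")

    absent = [
        name
        for name, val in [
            ("voxel_size_z", vz),
            ("voxel_size_y", vy),
            ("voxel_size_x", vx),
            ("frame_interval_s", frame_interval_s),
        ]
        if val is None
    ]
    if absent:
        raise ValueError(f"{path}: missing calibration fields {absent}; supply overrides")

    if channel_map is None:
        channel_map = {}
        for idx, name in enumerate(meta.get("channel_names", [])):
            if name in CHANNEL_ROLES:
                channel_map[name] = idx
        if not channel_map:
            warnings.warn(f"{path}: no channel roles found in metadata or config")

    return ImageStack(
        data=data,
        voxel_size_um=(vz, vy, vx),
        frame_interval_s=float(frame_interval_s),
        nc14_origin_frame=nc14_origin_frame,
        channels=channel_map,
    )
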