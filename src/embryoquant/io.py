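"""Hyperstack container and (OME-)TIFF round-trip.

A movie is held in memory as a 5D array with fixed axis order
``(T, Z, C, Y, X)`` regardless of on-disk layout. Physical metadata
(pixel size, frame interval) and channel roles travel with the array so
downstream stages never guess which channel is fluorescence and which is
DIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import ParameterError

AXES = "TZCYX"


@dataclass
class Hyperstack:
    """5D time-lapse movie, axes (T, Z, C, Y, X).

    Parameters
    ----------
    data
        Pixel array, shape ``(T, Z, C, Y, X)``. Stored as given; the
        generator keeps float internally and converts to uint16 on write.
    pixel_size_um
        Lateral pixel size in micrometres.
    frame_interval_s
        Time between frames in seconds.
    channels
        Role of each channel along the C axis, e.g. ``("fluorescence", "dic")``.
    """

    data: np.ndarray
    pixel_size_um: float = 0.1
    frame_interval_s: float = 8.0
    channels: tuple[str, ...] = ("fluorescence", "dic")

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ParameterError(
                f"hyperstack must be 5D (T,Z,C,Y,X); got {self.data.ndim}D"
            )
        if self.data.shape[2] != len(self.channels):
            raise ParameterError(
                f"{self.data.shape[2]} channels in array but "
                f"{len(self.channels)} channel roles given"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def channel_index(self, role: str) -> int:
        """Index along C of the channel with the given role."""
        try:
            return self.channels.index(role)
        except ValueError as exc:
            raise ParameterError(
                f"no channel with role {role!r}; available: {self.channels}"
            ) from exc

    def channel(self, role: str) -> np.ndarray:
        """(T, Z, Y, X) view of one channel."""
        return self.data[:, :, self.channel_index(role)]


def write_hyperstack(path, stack: Hyperstack) -> None:
    """Write as OME-TIFF (TZCYX) with physical metadata.

    Float data is clipped to [0, 65535] and stored as 16-bit unsigned.
    """
    arr = stack.data
    if arr.dtype.kind == "f":
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        arr,
        ome=True,
        photometric="minisblack",  # 2-channel axes otherwise mistaken for RGB samples
        metadata={
            "axes": AXES,
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": stack.frame_interval_s,
            "TimeIncrementUnit": "s",
            "Channel": {"Name": list(stack.channels)},
        },
    )


def read_hyperstack(
    path,
    axes: str | None = None,
    channels: tuple[str, ...] | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> Hyperstack:
    """Read a TIFF / OME-TIFF into TZCYX order.

    Axis order is taken from the file's series metadata; missing axes are
    inserted with length 1. A file without axis metadata must be read with
    an explicit ``axes`` string (fail-fast rather than guessing).
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        file_axes = axes or series.axes
        arr = series.asarray()
        meta = _ome_physical(tif)
    file_axes = file_axes.upper().replace("S", "C").replace("Q", "Z")
    if sorted(set(file_axes)) != sorted(file_axes):
        raise ParameterError(f"duplicate axes in {file_axes!r}")
    unknown = set(file_axes) - set(AXES)
    if unknown:
        raise ParameterError(
            f"cannot interpret axes {file_axes!r}; pass axes= explicitly"
        )
    # insert missing axes, then transpose to TZCYX
    for ax in AXES:
        if ax not in file_axes:
            arr = arr[np.newaxis]
            file_axes = ax + file_axes
    arr = np.transpose(arr, [file_axes.index(ax) for ax in AXES])
    n_c = arr.shape[2]
    if channels is None:
        channels = meta.get("channels") or tuple(f"channel{i}" for i in range(n_c))
    return Hyperstack(
        data=arr,
        pixel_size_um=pixel_size_um or meta.get("pixel_size_um") or 0.1,
        frame_interval_s=frame_interval_s or meta.get("frame_interval_s") or 8.0,
        channels=tuple(channels),
    )


def _ome_physical(tif: tifffile.TiffFile) -> dict:
    """Pull physical sizes and channel names out of OME-XML, if present."""
    out: dict = {}
    if not tif.is_ome:
        return out
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        if pixels is not None:
            if pixels.get("PhysicalSizeX"):
                out["pixel_size_um"] = float(pixels.get("PhysicalSizeX"))
            if pixels.get("TimeIncrement"):
                out["frame_interval_s"] = float(pixels.get("TimeIncrement"))
            names = [c.get("Name") for c in pixels.findall("ome:Channel", ns)]
            if names and all(names):
                out["channels"] = tuple(names)
    except Exception:  # metadata is advisory; fall back to defaults
        pass
    return out
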