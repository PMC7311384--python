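"""Multi-channel intensity-image container and TIFF I/O.

Conventions used across the package: 0-based ``(row, col)`` indexing,
pixel-center sampling, origin at the top-left. Arrays are indexed
``[channel][z?][row][col]``; the optional ``z`` axis is a confocal stack that
:func:`segmix.aggseg.max_project` flattens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["MultiChannelImage", "dtype_range_for"]


def dtype_range_for(dtype: np.dtype) -> tuple[float, float]:
    """Intensity range implied by an integer dtype (floats map to [0, 1])."""
    dtype = np.dtype(dtype)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.min), float(info.max)
    return 0.0, 1.0


@dataclass
class MultiChannelImage:
    """Intensity grids for one field of view.

    Parameters
    ----------
    data:
        ``(C, H, W)`` or ``(C, Z, H, W)`` array; the matrix value is
        intensity and the row/column index is the pixel position.
    channel_names:
        One name per channel, e.g. ``["red", "green"]``.
    pixel_size_um:
        Physical pixel size, if known. Optional: none of the statistics
        require calibration, all lengths are reported in pixels.
    dtype_range:
        ``(min, max)`` representable intensity; used by contrast
        normalization to map output back onto the acquisition range.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float | None = None
    dtype_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (C, H, W) or (C, Z, H, W)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if self.dtype_range is None:
            self.dtype_range = dtype_range_for(self.data.dtype)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's grid by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.data[idx]

    def with_data(self, data: np.ndarray) -> "MultiChannelImage":
        return replace(self, data=data)

    # -- I/O ---------------------------------------------------------------
    def to_tiff(self, path) -> None:
        """Write as a TIFF with the channel axis first."""
        axes = "CZYX" if self.has_z else "CYX"
        meta = {"axes": axes, "channel_names": list(self.channel_names)}
        if self.pixel_size_um is not None:
            meta["pixel_size_um"] = self.pixel_size_um
        tifffile.imwrite(
            str(path), self.data, metadata=meta, photometric="minisblack"
        )

    @classmethod
    def from_tiff(
        cls,
        path,
        channel_names: list[str] | None = None,
        pixel_size_um: float | None = None,
    ) -> "MultiChannelImage":
        """Read a TIFF written by :meth:`to_tiff` (or any C-first stack).

        2D files are promoted to a single channel; metadata written by
        :meth:`to_tiff` (channel names, pixel size) is recovered when present.
        """
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        if data.ndim == 2:
            data = data[None]
        if channel_names is None:
            channel_names = list(
                meta.get("channel_names", [f"ch{i}" for i in range(data.shape[0])])
            )
        if pixel_size_um is None:
            pixel_size_um = meta.get("pixel_size_um")
        return cls(data=data, channel_names=channel_names, pixel_size_um=pixel_size_um)
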