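"""Lightweight containers for confocal image data and binary masks.

The study's raw data are multi-channel confocal z-stacks and time-lapse
series exported as TIFF, with physical calibration (pixel size, z-step,
frame interval) supplied out-of-band.  :class:`ImageStack` keeps channels
as named arrays together with that calibration; :class:`BinaryMask`
carries a 2-D segmentation plus a provenance record of the preprocessing
parameters that produced it.

Axis conventions: a morphology stack per channel is ``(Z, H, W)`` or
``(H, W)``; a time-lapse is ``(T, H, W)``.  Which convention applies is
decided by the operation consuming the stack, not the container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "BinaryMask"]


@dataclass
class ImageStack:
    """Named intensity channels with physical calibration.

    Parameters
    ----------
    channels
        Mapping from channel label (``"EC"``, ``"dextran"``, ``"PMN"`` ...)
        to an intensity array.  Intensities must be non-negative.
    pixel_size_um
        In-plane pixel edge length, micrometres per pixel.
    z_step_um
        Axial step between slices, micrometres (``None`` for 2-D data).
    frame_interval_s
        Time between frames, seconds (``None`` for single time points).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    z_step_um: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for label, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.size and float(np.min(arr)) < 0:
                raise ValueError(f"channel {label!r} contains negative intensities")
            self.channels[label] = arr

    def channel(self, label: str) -> np.ndarray:
        if label not in self.channels:
            known = ", ".join(sorted(self.channels))
            raise KeyError(f"unknown channel {label!r}; available: {known}")
        return self.channels[label]

    def write_tiff(self, path: str | Path, channel: str) -> None:
        """Write one channel as a (multi-page) TIFF with resolution tags."""
        data = self.channel(channel)
        tifffile.imwrite(
            Path(path),
            np.asarray(data),
            resolution=(1.0 / self.pixel_size_um, 1.0 / self.pixel_size_um),
            metadata={"axes": "QYX"[3 - data.ndim :], "channel": channel},
        )

    @classmethod
    def read_tiff(
        cls,
        path: str | Path,
        channel: str = "image",
        pixel_size_um: float = 1.0,
        z_step_um: float | None = None,
        frame_interval_s: float | None = None,
    ) -> "ImageStack":
        data = tifffile.imread(Path(path))
        return cls(
            channels={channel: np.asarray(data)},
            pixel_size_um=pixel_size_um,
            z_step_um=z_step_um,
            frame_interval_s=frame_interval_s,
        )


@dataclass
class BinaryMask:
    """A 2-D boolean segmentation with its preprocessing provenance."""

    data: np.ndarray
    pixel_size_um: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("BinaryMask data must be 2-D")
        self.data = arr.astype(bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def write_tiff(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the mask as 0/255 uint8 TIFF plus a JSON provenance sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.uint8) * 255)
        if sidecar:
            meta = {"pixel_size_um": self.pixel_size_um, "provenance": self.provenance}
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read_tiff(cls, path: str | Path, pixel_size_um: float | None = None) -> "BinaryMask":
        path = Path(path)
        data = tifffile.imread(path) > 0
        provenance: dict = {}
        px = pixel_size_um
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            provenance = meta.get("provenance", {})
            if px is None:
                px = meta.get("pixel_size_um")
        return cls(data=data, pixel_size_um=1.0 if px is None else px, provenance=provenance)
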