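"""Multi-channel time-lapse image stacks with physical calibration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class TimeLapseStack:
    """A time-ordered multi-channel pixel array with calibration metadata.

    Parameters
    ----------
    data : ndarray, shape (T, C, Y, X)
        Pixel intensities in arbitrary units.
    channel_names : list of str
        One name per channel, e.g. ``["tracer", "blood_pool"]``.
    pixel_size_um : float
        Lateral pixel size in micrometres.
    frame_interval_s : float
        Time between consecutive frames in seconds.
    t0_s : float
        Acquisition time of the first frame, seconds post-injection.
    valid : ndarray of bool, shape (T, Y, X), optional
        Per-frame validity mask.  Pixels shifted in from outside the
        field during drift correction are marked invalid and excluded
        from downstream masks and curve extraction.  ``None`` means all
        pixels are valid.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    frame_interval_s: float
    t0_s: float = 0.0
    valid: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must have shape (T, C, Y, X)")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names must match the channel axis")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be distinct")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            expected = (self.n_frames,) + self.frame_shape
            if self.valid.shape != expected:
                raise ValueError(f"valid mask must have shape {expected}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame acquisition times in seconds post-injection."""
        return self.t0_s + self.frame_interval_s * np.arange(self.n_frames)

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel index {channel} out of range")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the (T, Y, X) array of one channel."""
        return self.data[:, self.channel_index(channel)]

    def valid_mask(self) -> np.ndarray:
        """(T, Y, X) boolean validity, materialised even when all-valid."""
        if self.valid is None:
            return np.ones((self.n_frames,) + self.frame_shape, dtype=bool)
        return self.valid

    def always_valid(self) -> np.ndarray:
        """(Y, X) pixels valid in every frame."""
        return self.valid_mask().all(axis=0)

    def copy(self) -> "TimeLapseStack":
        return TimeLapseStack(
            self.data.copy(),
            list(self.channel_names),
            self.pixel_size_um,
            self.frame_interval_s,
            self.t0_s,
            None if self.valid is None else self.valid.copy(),
        )

    # -- I/O -------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the stack as a multi-page TIFF with JSON metadata.

        Data are stored as float32 pages in (T, C, Y, X) order; pixel
        size, frame interval, injection-relative start time, channel
        names and the optional validity mask travel in the image
        description.
        """
        path = Path(path)
        meta = {
            "axes": "TCYX",
            "channel_names": list(self.channel_names),
            "pixel_size_um": float(self.pixel_size_um),
            "frame_interval_s": float(self.frame_interval_s),
            "t0_s": float(self.t0_s),
            "has_valid_mask": self.valid is not None,
        }
        data = self.data.astype(np.float32)
        if self.valid is not None:
            # validity rides along as an extra channel of 0/1 pages
            data = np.concatenate(
                [data, self.valid[:, None].astype(np.float32)], axis=1
            )
        # three-plane stacks would otherwise be guessed as RGB
        tifffile.imwrite(path, data, photometric="minisblack", metadata=meta)

    @classmethod
    def load(cls, path: str | Path) -> "TimeLapseStack":
        path = Path(path)
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
            else:  # pragma: no cover - foreign TIFFs
                raise ValueError(
                    f"{path} lacks qmpm metadata; supply calibration explicitly"
                )
        data = np.asarray(data, dtype=float)
        if data.ndim == 3:  # single channel stored without channel axis
            data = data[:, None]
        valid = None
        if meta.get("has_valid_mask"):
            valid = data[:, -1] > 0.5
            data = data[:, :-1]
        return cls(
            data,
            list(meta["channel_names"]),
            float(meta["pixel_size_um"]),
            float(meta["frame_interval_s"]),
            float(meta.get("t0_s", 0.0)),
            valid,
        )


def save_sidecar(path: str | Path, record: dict) -> None:
    """Write a JSON sidecar next to a stack file."""
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))


def load_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
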