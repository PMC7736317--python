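"""Compartment time-intensity curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TimeCurve:
    """Mean fluorescent intensity of one compartment over time.

    Parameters
    ----------
    times : array of float
        Acquisition times in seconds post-injection, strictly increasing.
    values : array of float
        Mean intensity (arbitrary units), one per time point, all finite.
    n_pixels : array of int, optional
        Number of pixels contributing to the mean at each frame.  Defaults
        to 1 everywhere (e.g. for purely simulated curves).
    """

    times: np.ndarray
    values: np.ndarray
    n_pixels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a time curve needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.n_pixels is None:
            self.n_pixels = np.ones(self.times.size, dtype=int)
        else:
            self.n_pixels = np.asarray(self.n_pixels, dtype=int)
            if self.n_pixels.shape != self.times.shape:
                raise ValueError("n_pixels must match times in length")
            if np.any(self.n_pixels <= 0):
                raise ValueError("n_pixels must be positive for every frame")

    def __len__(self) -> int:
        return self.times.size

    def scaled(self, gain: float) -> "TimeCurve":
        """Return a copy with intensities multiplied by ``gain``."""
        return TimeCurve(self.times.copy(), self.values * gain, self.n_pixels.copy())

    def resample(self, times: np.ndarray) -> "TimeCurve":
        """Linearly interpolate the curve onto a new time grid."""
        times = np.asarray(times, dtype=float)
        vals = np.interp(times, self.times, self.values)
        return TimeCurve(times, vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "value": self.values, "n_pixels": self.n_pixels}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeCurve":
        df = pd.read_csv(path)
        npix = df["n_pixels"].to_numpy() if "n_pixels" in df else None
        return cls(df["time_s"].to_numpy(), df["value"].to_numpy(), npix)
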