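"""Timestamped bivariate affect observations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AffectTimeSeries"]

MINUTES_PER_DAY = 1440.0


@dataclass
class AffectTimeSeries:
    """An irregularly sampled (PA, NA) series for one subject.

    Attributes
    ----------
    times
        Strictly increasing observation times in minutes from study start.
    y
        Array of shape (n, 2) with PA in column 0 and NA in column 1,
        all values in [0, 1].  Missing beeps are simply absent rows
        (they lengthen the time gap).
    subject_id
        Free-form label.
    day
        Optional integer day index per observation.  If omitted it is
        derived as ``floor(times / 1440)``, which is exact for series
        whose clock starts at midnight of day 0 (as the synthetic
        generator produces).
    """

    times: np.ndarray
    y: np.ndarray
    subject_id: str = "subject"
    day: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.y.shape != (self.times.size, 2):
            raise ValueError("y must have shape (len(times), 2)")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.y < 0) or np.any(self.y > 1):
            raise ValueError("affect values must lie in [0, 1]")
        if self.day is None:
            self.day = np.floor(self.times / MINUTES_PER_DAY).astype(int)
        else:
            self.day = np.asarray(self.day, dtype=int)
            if self.day.shape != self.times.shape:
                raise ValueError("day must align with times")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_obs(self) -> int:
        return self.times.size

    @property
    def pa(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def na(self) -> np.ndarray:
        return self.y[:, 1]

    def gaps(self) -> np.ndarray:
        """Time differences between successive observations (minutes)."""
        return np.diff(self.times)

    def same_day_pairs(self) -> np.ndarray:
        """Indices t such that observations t and t+1 fall on the same day."""
        return np.nonzero(self.day[1:] == self.day[:-1])[0]

    def drop(self, index: int) -> "AffectTimeSeries":
        """Series with observation ``index`` removed (neighbours join up)."""
        keep = np.ones(len(self), dtype=bool)
        keep[index] = False
        return AffectTimeSeries(
            self.times[keep], self.y[keep], self.subject_id, self.day[keep]
        )

    def subset(self, idx) -> "AffectTimeSeries":
        idx = np.asarray(idx, dtype=int)
        return AffectTimeSeries(
            self.times[idx], self.y[idx], self.subject_id, self.day[idx]
        )
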