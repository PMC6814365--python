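"""Core containers shared across the package.

Time-resolved data live on a :class:`TimeAxis`: the laser repetition period
(ns) divided into ``n_bins`` ADC time bins.  A :class:`TCSPCImage` is the
photon-count cube recorded by a time-correlated single-photon-counting
system — one decay histogram per pixel — and an :class:`IRF` is the
instrument response histogram on the same axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeAxis", "IRF", "TCSPCImage"]


@dataclass(frozen=True)
class TimeAxis:
    """Discretization of one laser repetition period into ADC time bins.

    Parameters
    ----------
    n_bins
        Number of ADC time bins (>= 8).
    period
        Repetition period in ns (e.g. 12.5 ns for 80 MHz excitation).
    """

    n_bins: int = 256
    period: float = 12.5

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError(f"n_bins must be >= 8, got {self.n_bins}")
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")

    @property
    def bin_width(self) -> float:
        """Width of one ADC bin in ns."""
        return self.period / self.n_bins

    def times(self) -> np.ndarray:
        """Left edge of each bin in ns, shape (n_bins,)."""
        return np.arange(self.n_bins) * self.bin_width

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeAxis):
            return NotImplemented
        return self.n_bins == other.n_bins and abs(self.period - other.period) < 1e-9

    def __hash__(self) -> int:
        return hash((self.n_bins, round(self.period, 9)))


@dataclass(frozen=True)
class IRF:
    """Normalized instrument-response histogram on a :class:`TimeAxis`."""

    axis: TimeAxis
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.axis.n_bins,):
            raise ValueError(
                f"IRF has {values.shape} values for a {self.axis.n_bins}-bin axis"
            )
        if np.any(values < 0):
            raise ValueError("IRF values must be nonnegative")
        total = values.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("IRF must have positive total weight")
        object.__setattr__(self, "values", values / total)

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.values))


@dataclass
class TCSPCImage:
    """Photon-count cube, shape (height, width, n_bins).

    ``truth`` optionally carries the ground-truth record written by the
    synthetic generator (lifetime map, per-group membrane potential,
    label map) so downstream stages can be scored.
    """

    counts: np.ndarray
    axis: TimeAxis
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError(f"counts must be 3-D (y, x, time), got {counts.ndim}-D")
        if counts.shape[2] != self.axis.n_bins:
            raise ValueError(
                f"time dimension {counts.shape[2]} != axis n_bins {self.axis.n_bins}"
            )
        if np.any(counts < 0):
            raise ValueError("photon counts must be nonnegative")
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (height, width)."""
        return self.counts.shape[:2]

    def count_image(self) -> np.ndarray:
        """Total photons per pixel (sum over time bins)."""
        return self.counts.sum(axis=2)

    def peak_image(self) -> np.ndarray:
        """Counts in the maximum time bin per pixel."""
        return self.counts.max(axis=2)
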