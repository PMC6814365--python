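"""Dual-excitation ratiometric voltage imaging.

The comparison pipeline for electrochromic dyes read out as an excitation
ratio: per-channel background subtraction, pixelwise blue/green ratio with
a minimum-signal mask, ROI averaging (optionally across repeat frames), and
a linear ratio-voltage calibration R(V) = R0 + slope * V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RatioImagePair",
    "estimate_background",
    "compute_ratio_map",
    "roi_ratio",
    "ratio_to_vmem",
]


@dataclass
class RatioImagePair:
    """Blue- and green-excited images with per-channel backgrounds.

    Backgrounds may be scalars or estimated from an empty region via
    :func:`estimate_background`.
    """

    blue: np.ndarray
    green: np.ndarray
    bg_blue: float = 0.0
    bg_green: float = 0.0

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.blue.shape != self.green.shape:
            raise ValueError("blue and green images must share a shape")
        if self.bg_blue < 0 or self.bg_green < 0:
            raise ValueError("backgrounds must be nonnegative")


def estimate_background(image: np.ndarray, empty_roi: np.ndarray) -> float:
    """Median intensity of a cell-free region (robust to stray debris)."""
    roi = np.asarray(empty_roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty-region mask has no pixels")
    return float(np.median(np.asarray(image, dtype=float)[roi]))


def compute_ratio_map(
    pair: RatioImagePair, min_signal: float = 100.0
) -> np.ma.MaskedArray:
    """Pixelwise background-subtracted blue/green ratio.

    Pixels where either background-subtracted channel falls below
    ``min_signal`` counts are masked.
    """
    b = pair.blue - pair.bg_blue
    g = pair.green - pair.bg_green
    valid = (b >= min_signal) & (g >= min_signal)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, b / np.where(valid, g, 1.0), np.nan)
    return np.ma.MaskedArray(ratio, mask=~valid)


def roi_ratio(
    ratio_maps: np.ma.MaskedArray | list[np.ma.MaskedArray],
    label_map: np.ndarray,
) -> pd.DataFrame:
    """Mean ratio over unmasked pixels per ROI, then across repeat frames.

    Accepts one ratio map or a list (sequential exposures at the same
    potential); fully masked ROIs report NaN.
    """
    maps = ratio_maps if isinstance(ratio_maps, list) else [ratio_maps]
    label_map = np.asarray(label_map)
    rows = []
    for g in np.unique(label_map):
        if g == 0:
            continue
        mask = label_map == g
        frame_means = []
        for m in maps:
            if m.shape != label_map.shape:
                raise ValueError("ratio map and label map shapes differ")
            vals = m[mask].compressed()
            frame_means.append(vals.mean() if len(vals) else np.nan)
        frame_means = np.array(frame_means, dtype=float)
        good = np.isfinite(frame_means)
        mean_r = float(frame_means[good].mean()) if good.any() else np.nan
        rows.append((int(g), mean_r, int(good.sum())))
    return pd.DataFrame(rows, columns=["label", "ratio", "n_frames"]).set_index("label")


def ratio_to_vmem(
    r, slope_r_per_mv: float = 0.0039, r0: float = 1.8, normalized: bool = False
):
    """Membrane potential (mV) from a blue/green ratio.

    V = (R - R0) / slope.  With ``normalized=True`` the input is a ratio
    already divided by that cell's own 0 mV ratio (requires per-cell
    electrode calibration), so R0 is 1 and the slope must be on the
    normalized scale.
    """
    if slope_r_per_mv == 0:
        raise ValueError("ratio calibration slope is zero")
    r = np.asarray(r, dtype=float)
    intercept = 1.0 if normalized else r0
    return (r - intercept) / slope_r_per_mv
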