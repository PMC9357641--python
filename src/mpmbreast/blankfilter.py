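"""Blank-tile exclusion: SNR against a median-filtered pseudo-noiseless
image combined with an average-brightness cutoff.

A tile is blank iff its signal-to-noise ratio is below the threshold AND
its mean brightness (on the raw [0, 1] 12-bit scale) is below the
brightness cutoff.  The SNR compares the median-filtered estimate of the
noise-free tile against the residual it leaves:

    SNR_db = 20 log10( RMS(median(tile)) / RMS(tile - median(tile)) )

The decibel interpretation of the threshold (default 20) and the 3 x 3
median window are package choices; a plain ratio mode is available.
Blank decisions read raw gray levels, never standardized values — a
zero-mean image would make a 0.10 mean-brightness cutoff meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidConfigError

__all__ = ["BlankRule", "pseudo_noiseless", "tile_snr", "mean_brightness", "is_blank"]

FULL_SCALE = 4095.0  # 12-bit detector


@dataclass(frozen=True)
class BlankRule:
    snr_threshold: float = 20.0
    brightness_threshold: float = 0.10
    median_window: int = 3
    snr_mode: str = "db"  # "db" | "ratio"

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0 or self.brightness_threshold <= 0:
            raise InvalidConfigError("blank-rule thresholds must be positive")
        if self.median_window % 2 == 0 or self.median_window < 1:
            raise InvalidConfigError("median window must be odd")
        if self.snr_mode not in ("db", "ratio"):
            raise InvalidConfigError("snr_mode must be 'db' or 'ratio'")


def pseudo_noiseless(pixels: np.ndarray, rule: BlankRule | None = None) -> np.ndarray:
    """Per-channel 2-D median filter (reflected edges), same shape out."""
    rule = rule or BlankRule()
    arr = np.asarray(pixels, dtype=float)
    w = rule.median_window
    if arr.ndim == 2:
        return ndimage.median_filter(arr, size=w, mode="reflect")
    return np.stack([ndimage.median_filter(ch, size=w, mode="reflect") for ch in arr])


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x, dtype=float))))


def tile_snr(pixels: np.ndarray, rule: BlankRule | None = None) -> float:
    """Signal-to-noise ratio of a raw-intensity tile.

    Degenerate cases: zero residual with nonzero signal -> +inf; all-zero
    tile -> 0.
    """
    rule = rule or BlankRule()
    arr = np.asarray(pixels, dtype=float)
    denoised = pseudo_noiseless(arr, rule)
    signal_rms = _rms(denoised)
    resid_rms = _rms(arr - denoised)
    if resid_rms == 0.0:
        if signal_rms == 0.0:
            return 0.0
        return float("inf")
    ratio = signal_rms / resid_rms
    if rule.snr_mode == "ratio":
        return ratio
    if ratio == 0.0:
        return float("-inf")
    return 20.0 * float(np.log10(ratio))


def mean_brightness(pixels: np.ndarray, full_scale: float = FULL_SCALE) -> float:
    """Mean intensity over all channels and pixels, normalized to [0, 1]."""
    return float(np.mean(np.asarray(pixels, dtype=float))) / full_scale


def is_blank(pixels: np.ndarray, rule: BlankRule | None = None) -> bool:
    """True iff SNR < threshold AND mean brightness < threshold."""
    rule = rule or BlankRule()
    if mean_brightness(pixels) >= rule.brightness_threshold:
        return False
    return tile_snr(pixels, rule) < rule.snr_threshold
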