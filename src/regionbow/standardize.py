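"""Landmark-based intensity standardization.

MRI-like intensities have no absolute scale: the same tissue can land on
very different gray values in different acquisitions.  The two-step
remedy implemented here learns three histogram landmarks — a low
percentile, the median, and a high percentile of the image foreground —
and piecewise-linearly remaps every image so its landmarks land on a
common standard triple ``(s_low, s_mid, s_high)``.

Training: each training image's (low, high) landmarks are linearly mapped
to the standard-scale ends and its median is carried through that map;
``s_mid`` is the mean of those mapped medians.  Transformation: a
continuous, monotone, two-segment linear map sends (low, median, high) to
(s_low, s_mid, s_high); values beyond the landmarks follow the adjacent
segment's slope.

The foreground is the set of pixels strictly above the image median,
computed as an order statistic.  Because an order statistic commutes with
any strictly increasing map, a standardized image selects the same
foreground pixels again and its landmarks sit exactly on the standard
triple — which makes the transform exactly idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .phantoms import LabeledImage

__all__ = [
    "StandardizationModel",
    "foreground_landmarks",
    "fit_standardization",
    "apply_standardization",
]


@dataclass(frozen=True)
class StandardizationModel:
    """Learned standard-scale landmarks and the settings that produced them."""

    s_low: float
    s_mid: float
    s_high: float
    pc_low: float = 0.01
    pc_high: float = 0.99
    foreground_rule: str = "above-median"  # or "above-mean"

    def __post_init__(self) -> None:
        if not (self.s_low < self.s_mid < self.s_high):
            raise ValueError("standard landmarks must satisfy s_low < s_mid < s_high")
        if not (0.0 <= self.pc_low < 0.5 < self.pc_high <= 1.0):
            raise ValueError("percentiles must satisfy 0 <= pc_low < 0.5 < pc_high <= 1")


def _foreground(pixels: np.ndarray, rule: str) -> np.ndarray:
    flat = pixels.ravel()
    if rule == "above-median":
        thr = np.quantile(flat, 0.5, method="lower")
    elif rule == "above-mean":
        thr = flat.mean()
    else:
        raise ValueError(f"unknown foreground rule {rule!r}")
    return flat[flat > thr]


def foreground_landmarks(
    pixels: np.ndarray,
    pc_low: float = 0.01,
    pc_high: float = 0.99,
    foreground_rule: str = "above-median",
) -> tuple[float, float, float] | None:
    """(low, median, high) foreground landmarks, or ``None`` if degenerate.

    Landmarks are order statistics (``method='lower'``) so they are actual
    pixel values and commute with monotone maps.  Degenerate means the
    three landmarks are not strictly increasing (e.g. a constant image).
    """
    fg = _foreground(pixels, foreground_rule)
    if fg.size == 0:
        return None
    lo, md, hi = np.quantile(fg, [pc_low, 0.5, pc_high], method="lower")
    if not (lo < md < hi):
        return None
    return float(lo), float(md), float(hi)


def fit_standardization(
    images: Iterable[LabeledImage],
    s_low: float = 0.0,
    s_high: float = 4095.0,
    pc_low: float = 0.01,
    pc_high: float = 0.99,
    foreground_rule: str = "above-median",
) -> StandardizationModel:
    """Learn ``s_mid`` from training images; ``s_low``/``s_high`` are fixed.

    Images with a degenerate foreground are excluded with a warning; if
    every image is degenerate the fit fails.
    """
    mapped_medians: list[float] = []
    for i, img in enumerate(images):
        lm = foreground_landmarks(img.pixels, pc_low, pc_high, foreground_rule)
        if lm is None:
            warnings.warn(
                f"image {img.image_id or i}: degenerate foreground, "
                "excluded from standardization training"
            )
            continue
        lo, md, hi = lm
        mapped_medians.append(s_low + (md - lo) / (hi - lo) * (s_high - s_low))
    if not mapped_medians:
        raise ValueError("all training images have degenerate foregrounds")
    s_mid = float(np.mean(mapped_medians))
    return StandardizationModel(
        s_low=s_low,
        s_mid=s_mid,
        s_high=s_high,
        pc_low=pc_low,
        pc_high=pc_high,
        foreground_rule=foreground_rule,
    )


def standardize_pixels(pixels: np.ndarray, model: StandardizationModel) -> np.ndarray:
    """Apply the piecewise-linear landmark map to a raw pixel array."""
    lm = foreground_landmarks(
        pixels, model.pc_low, model.pc_high, model.foreground_rule
    )
    if lm is None:
        warnings.warn("degenerate foreground: image returned unstandardized")
        return pixels.copy()
    lo, md, hi = lm
    xp = np.array([lo, md, hi])
    fp = np.array([model.s_low, model.s_mid, model.s_high])
    out = np.interp(pixels, xp, fp)
    # extend the end segments linearly beyond the landmarks (np.interp
    # clamps); slopes are positive, so the full map stays strictly monotone
    slope_lo = (model.s_mid - model.s_low) / (md - lo)
    slope_hi = (model.s_high - model.s_mid) / (hi - md)
    below = pixels < lo
    above = pixels > hi
    out[below] = model.s_low + (pixels[below] - lo) * slope_lo
    out[above] = model.s_high + (pixels[above] - hi) * slope_hi
    return out


def apply_standardization(image: LabeledImage, model: StandardizationModel) -> LabeledImage:
    """Standardized copy of ``image``; the mask is untouched."""
    return image.with_pixels(standardize_pixels(image.pixels, model))
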