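"""Immunofluorescence intensity quantification.

Background is estimated per nucleus from three line profiles drawn
perpendicular to chromosome fragments: each profile looks like a bump with
flat flanks, and the background pixel intensity is the level at which the
profile flattens. Operationally, the profile is lightly smoothed and the
flattening level is the mean over the maximal outer runs where the absolute
discrete slope stays below a fraction of the profile's dynamic range.

The integrated intensity of a nucleus counts the masked pixels strictly
above background; their sum is the raw total, and

    corrected_total = raw_total - background_per_pixel * n_pixels_above
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import profile_line

__all__ = [
    "LineProfile",
    "IntensityResult",
    "BackgroundEstimationError",
    "sample_line_profile",
    "profile_background",
    "nucleus_background",
    "integrated_intensity",
    "quantify_nucleus",
]


class BackgroundEstimationError(RuntimeError):
    """Raised when a line profile has no flat flanks to read background from."""


@dataclass(frozen=True)
class LineProfile:
    """Pixel offsets and intensities sampled along a line (>= 7 samples)."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.size != inten.size:
            raise ValueError("positions and intensities must have equal length")
        if pos.size < 7:
            raise ValueError(f"need >= 7 samples along the line, got {pos.size}")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class IntensityResult:
    background_per_pixel: float
    n_pixels_above: int
    raw_total: float
    corrected_total: float


def sample_line_profile(
    image: np.ndarray, endpoints, interpolation: str = "nearest"
) -> LineProfile:
    """Sample an image along ``(x1, y1, x2, y2)``; nearest-pixel by default,
    ``"linear"`` for sub-pixel interpolation."""
    x1, y1, x2, y2 = endpoints
    order = {"nearest": 0, "linear": 1}[interpolation]
    inten = profile_line(
        np.asarray(image, dtype=float), (y1, x1), (y2, x2), order=order, mode="reflect"
    )
    return LineProfile(positions=np.arange(inten.size, dtype=float), intensities=inten)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    return np.convolve(x, np.ones(window), mode="valid") / window


def profile_background(
    profile: LineProfile,
    slope_frac: float = 0.02,
    smooth_window: int = 3,
    min_tail: int = 3,
) -> float:
    """Flattening level of a perpendicular line profile.

    After a moving-average smoothing (window ``smooth_window``), the outer
    tails are the maximal runs from each end over which the absolute
    discrete slope stays below ``slope_frac`` times the peak-minus-minimum
    range. Both tails must contribute at least ``min_tail`` pixels; the
    background is the mean smoothed intensity over the two tails.
    """
    y = _moving_average(profile.intensities, smooth_window)
    rng = float(y.max() - y.min())
    if rng == 0.0:
        return float(y[0])
    thr = slope_frac * rng
    slopes = np.abs(np.diff(y))
    flat = slopes <= thr
    left = 0
    while left < flat.size and flat[left]:
        left += 1
    right = 0
    while right < flat.size and flat[flat.size - 1 - right]:
        right += 1
    left_px, right_px = left + 1, right + 1
    if left_px + right_px >= y.size:  # profile flat end to end
        return float(y.mean())
    if left_px < min_tail or right_px < min_tail:
        raise BackgroundEstimationError(
            f"no flat tail of >= {min_tail} px at {'both ends' if min(left_px, right_px) == 1 else 'one end'}; "
            "draw a longer line with more flanking background"
        )
    tails = np.concatenate([y[:left_px], y[-right_px:]])
    return float(tails.mean())


def nucleus_background(profiles, **kwargs) -> float:
    """Mean of the three per-profile background levels of one nucleus."""
    profiles = list(profiles)
    if len(profiles) != 3:
        raise ValueError(f"expected exactly 3 line profiles, got {len(profiles)}")
    values = []
    for i, prof in enumerate(profiles):
        try:
            values.append(profile_background(prof, **kwargs))
        except BackgroundEstimationError as err:
            raise BackgroundEstimationError(f"profile {i}: {err}") from err
    return float(np.mean(values))


def integrated_intensity(
    image: np.ndarray, mask: np.ndarray, background_per_pixel: float
) -> IntensityResult:
    """Background-corrected integrated intensity over the masked nucleus.

    Only pixels strictly above background are counted (ties at exactly the
    background level are excluded).
    """
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if img.shape != msk.shape:
        raise ValueError("image and mask shapes differ")
    if background_per_pixel < 0:
        raise ValueError("background must be >= 0")
    vals = img[msk]
    if vals.size == 0:
        raise ValueError("empty nucleus mask")
    above = vals[vals > background_per_pixel]
    raw = float(above.sum())
    return IntensityResult(
        background_per_pixel=float(background_per_pixel),
        n_pixels_above=int(above.size),
        raw_total=raw,
        corrected_total=raw - background_per_pixel * above.size,
    )


def quantify_nucleus(
    image: np.ndarray,
    mask: np.ndarray,
    lines,
    interpolation: str = "nearest",
    **background_kwargs,
) -> IntensityResult:
    """Full per-nucleus quantification: three perpendicular lines ->
    background -> corrected integrated intensity."""
    profiles = [sample_line_profile(image, ln, interpolation) for ln in lines]
    bg = nucleus_background(profiles, **background_kwargs)
    return integrated_intensity(image, mask, bg)
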