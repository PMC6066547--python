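"""Image parameters used to predict perceptual dominance.

Six retained parameters (the core ``FeatureVector``):

========================  ====================================================
gradient                  sum over pixels of squared intensity differences
low_frequencies           sum of 2-D DFT magnitudes at radial frequency
                          <= 0.25 of Nyquist (DC included)
luminance                 mean of 0.299 R + 0.587 G + 0.114 B
global_contrast           population std of the same weighted intensity
colorfulness              sum over pixels of sqrt(I^2 + Q^2) in YIQ
saturation                mean of 255 (max(R,G,B) - min(R,G,B)) / max(R,G,B)
========================  ====================================================

plus the extended twelve-feature set (per-channel means, local contrast,
directional gradients, high frequencies). All intensity-domain features
(gradients, spectral bands, contrasts) are computed on the floating-point
weighted-intensity (luminance) image; gradients use first-order forward
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .images import validate_image

__all__ = [
    "FeatureVector",
    "ExtendedFeatureVector",
    "CORE_FEATURES",
    "EXTENDED_FEATURES",
    "weighted_intensity",
    "weighted_intensity_stats",
    "gradient_energy",
    "spectral_band_energy",
    "color_stats",
    "local_contrast",
    "extract_features",
    "extract_extended",
    "select_least_correlated",
]

#: Rec. 601 luma weights (R, G, B).
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: NTSC YIQ chrominance rows.
YIQ_I = np.array([0.596, -0.274, -0.322])
YIQ_Q = np.array([0.211, -0.523, 0.312])

CORE_FEATURES = (
    "gradient",
    "low_frequencies",
    "luminance",
    "global_contrast",
    "colorfulness",
    "saturation",
)


@dataclass(frozen=True)
class FeatureVector:
    gradient: float
    low_frequencies: float
    luminance: float
    global_contrast: float
    colorfulness: float
    saturation: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class ExtendedFeatureVector(FeatureVector):
    avg_red: float
    avg_green: float
    avg_blue: float
    local_contrast: float
    horizontal_gradient: float
    vertical_gradient: float
    high_frequencies: float


EXTENDED_FEATURES = tuple(f.name for f in fields(ExtendedFeatureVector))


def weighted_intensity(image: np.ndarray) -> np.ndarray:
    """Per-pixel luma 0.299 R + 0.587 G + 0.114 B as float64."""
    arr = validate_image(image).astype(np.float64)
    return arr @ LUMA_WEIGHTS


def weighted_intensity_stats(image: np.ndarray) -> tuple[float, float]:
    """(luminance, global_contrast): mean and population std of the luma image."""
    y = weighted_intensity(image)
    return float(y.mean()), float(y.std())


def gradient_energy(
    image: np.ndarray, axis: Literal["horizontal", "vertical", "both"] = "both"
) -> float:
    """Sum of squared forward differences of the luma image.

    ``horizontal`` differentiates along the width axis, ``vertical`` along the
    height axis; ``both`` is their sum.
    """
    y = weighted_intensity(image)
    h = float(np.sum(np.diff(y, axis=1) ** 2))
    v = float(np.sum(np.diff(y, axis=0) ** 2))
    if axis == "horizontal":
        return h
    if axis == "vertical":
        return v
    if axis == "both":
        return h + v
    raise ValueError(f"unknown axis {axis!r}")


def _radial_frequency_grid(h: int, w: int) -> np.ndarray:
    # Signed per-axis frequencies normalized so Nyquist = 1.
    fy = np.fft.fftfreq(h) * 2.0
    fx = np.fft.fftfreq(w) * 2.0
    return np.hypot(fy[:, None], fx[None, :])


def spectral_band_energy(image: np.ndarray, band: Literal["low", "high"]) -> float:
    """Sum of 2-D DFT magnitudes of the luma image over a radial band.

    ``low`` keeps radial frequency <= 0.25 of Nyquist (DC included); ``high``
    keeps >= 0.75. Unnormalized forward transform.
    """
    y = weighted_intensity(image)
    mag = np.abs(np.fft.fft2(y))
    r = _radial_frequency_grid(*y.shape)
    if band == "low":
        mask = r <= 0.25
    elif band == "high":
        mask = r >= 0.75
    else:
        raise ValueError(f"unknown band {band!r}")
    return float(mag[mask].sum())


def color_stats(image: np.ndarray) -> tuple[float, float, float, float, float]:
    """(colorfulness, saturation, avg_red, avg_green, avg_blue).

    Colorfulness sums the IQ-plane chroma magnitude over pixels; saturation is
    the pixel mean of 255 (max - min) / max over RGB, defined as 0 at black
    pixels (the formula's removable singularity).
    """
    arr = validate_image(image).astype(np.float64)
    i = arr @ YIQ_I
    q = arr @ YIQ_Q
    colorfulness = float(np.hypot(i, q).sum())
    mx = arr.max(axis=2)
    mn = arr.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, 255.0 * (mx - mn) / mx, 0.0)
    saturation = float(sat.mean())
    means = arr.mean(axis=(0, 1))
    return colorfulness, saturation, float(means[0]), float(means[1]), float(means[2])


def local_contrast(image: np.ndarray, tile: int = 8) -> float:
    """Mean over non-overlapping tile x tile blocks of within-block luma std.

    Edge remainders that do not fill a block are dropped.
    """
    y = weighted_intensity(image)
    h, w = y.shape
    if tile < 2 or tile > min(h, w):
        raise ValueError(f"tile must be in [2, {min(h, w)}], got {tile}")
    nh, nw = h // tile, w // tile
    blocks = y[: nh * tile, : nw * tile].reshape(nh, tile, nw, tile)
    stds = blocks.std(axis=(1, 3))
    return float(stds.mean())


def extract_features(image: np.ndarray) -> FeatureVector:
    """Assemble the six retained parameters for one image."""
    lum, contrast = weighted_intensity_stats(image)
    colorfulness, saturation, *_ = color_stats(image)
    return FeatureVector(
        gradient=gradient_energy(image, "both"),
        low_frequencies=spectral_band_energy(image, "low"),
        luminance=lum,
        global_contrast=contrast,
        colorfulness=colorfulness,
        saturation=saturation,
    )


def extract_extended(image: np.ndarray, tile: int = 8) -> ExtendedFeatureVector:
    """Assemble the full twelve-feature set for one image."""
    lum, contrast = weighted_intensity_stats(image)
    colorfulness, saturation, r, g, b = color_stats(image)
    return ExtendedFeatureVector(
        gradient=gradient_energy(image, "both"),
        low_frequencies=spectral_band_energy(image, "low"),
        luminance=lum,
        global_contrast=contrast,
        colorfulness=colorfulness,
        saturation=saturation,
        avg_red=r,
        avg_green=g,
        avg_blue=b,
        local_contrast=local_contrast(image, tile),
        horizontal_gradient=gradient_energy(image, "horizontal"),
        vertical_gradient=gradient_energy(image, "vertical"),
        high_frequencies=spectral_band_energy(image, "high"),
    )


def select_least_correlated(
    feature_table: pd.DataFrame | Mapping[str, Sequence[float]],
    k: int,
) -> tuple[list[str], list[str]]:
    """Greedy forward selection of the k mutually least-correlated features.

    Start from the pair with the lowest absolute Pearson correlation across
    images, then repeatedly add the feature minimizing the maximum absolute
    correlation with the chosen set. Ties break lexicographically. Constant
    columns (undefined correlation) are treated as perfectly correlated with
    everything and returned in the second element as flagged names.

    Returns ``(selected_names, flagged_constant_names)``.
    """
    table = pd.DataFrame(feature_table)
    if len(table) < 3:
        raise ValueError("need at least 3 images to estimate correlations")
    names = sorted(table.columns)
    if not 1 <= k <= len(names):
        raise ValueError(f"k must be in [1, {len(names)}]")

    flagged = [n for n in names if np.isclose(table[n].std(), 0.0)]
    corr = table[names].corr().abs()
    # Constant columns: correlation 1 with everything (worst candidates).
    for n in flagged:
        corr.loc[n, :] = 1.0
        corr.loc[:, n] = 1.0
    np.fill_diagonal(corr.values, 0.0)

    if k == 1:
        # Lowest maximum correlation with anything; lexicographic tie-break.
        best = min(names, key=lambda n: (corr.loc[n].max(), n))
        return [best], flagged

    # Seed with the least-correlated pair.
    best_pair = min(
        ((a, b) for ia, a in enumerate(names) for b in names[ia + 1 :]),
        key=lambda ab: (corr.loc[ab[0], ab[1]], ab),
    )
    selected = list(best_pair)
    while len(selected) < k:
        remaining = [n for n in names if n not in selected]
        nxt = min(
            remaining, key=lambda n: (corr.loc[n, selected].max(), n)
        )
        selected.append(nxt)
    return selected, flagged
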