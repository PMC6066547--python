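"""Construction of two-image mixtures.

Two morphing methods produce the competing stimuli:

* ``average_5050`` — pixel-wise arithmetic mean of the two sources' RGB values.
* ``phase_magnitude`` — per RGB channel, the 2-D Fourier magnitude spectrum of
  one source is combined with the phase spectrum of the other and inverse
  transformed; the result carries one image's spectral energy distribution and
  the other's spatial structure.

Images are plain ``(H, W, 3)`` integer arrays with channel values in [0, 255].
Mixing requires equal dimensions, so sources are first standardized by a
center-crop to the largest centered square followed by resampling to a common
side length (default 224, the canonical input size of the classification
networks this pipeline feeds).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "MixtureRecord",
    "validate_image",
    "standardize",
    "mix_average",
    "mix_phase_magnitude",
    "build_mixture_set",
]

MixMode = Literal["average_5050", "phase_magnitude"]
Pairing = Literal["all_pairwise", "unique_pairing"]


@dataclass(frozen=True)
class MixtureRecord:
    """One mixture and its provenance.

    For ``phase_magnitude`` mode, ``source1_id`` supplied the phase spectrum
    and ``source2_id`` the magnitude spectrum (recorded in ``role_note``).
    """

    id: str
    mode: MixMode
    source1_id: str
    source2_id: str
    mixed: np.ndarray
    role_note: str = ""

    def __post_init__(self) -> None:
        if self.source1_id == self.source2_id:
            raise ValueError("mixture sources must be distinct")
        if self.mode not in ("average_5050", "phase_magnitude"):
            raise ValueError(f"unknown mixture mode {self.mode!r}")


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check an RGB raster and return it as an array.

    Raises ``ValueError`` for wrong rank/channel count, values outside
    [0, 255], non-finite values, or any spatial dimension below 2 px.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) array, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("degenerate image: both dimensions must be >= 2")
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return arr


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; the pipeline's convention is round-half-up.
    return np.floor(x + 0.5)


def standardize(
    image: np.ndarray, side: int = 224, resample: str = "bicubic"
) -> np.ndarray:
    """Center-crop to the largest centered square, then resample to side x side.

    Idempotent on an input that is already ``side x side``. ``resample`` names
    a Pillow filter (``nearest``, ``bilinear``, ``bicubic``, ``lanczos``).
    """
    arr = validate_image(image)
    if side < 2:
        raise ValueError("side must be >= 2")
    h, w = arr.shape[:2]
    if (h, w) == (side, side):
        return arr.copy()
    s = min(h, w)
    top = (h - s) // 2
    left = (w - s) // 2
    square = arr[top : top + s, left : left + s]
    filt = getattr(Image.Resampling, resample.upper())
    pil = Image.fromarray(square.astype(np.uint8), mode="RGB")
    out = np.asarray(pil.resize((side, side), resample=filt))
    return out.astype(arr.dtype if np.issubdtype(arr.dtype, np.integer) else np.uint8)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")


def mix_average(image1: np.ndarray, image2: np.ndarray) -> np.ndarray:
    """Pixel-wise 50/50 average of two equal-size images (round-half-up)."""
    a = validate_image(image1).astype(np.float64)
    b = validate_image(image2).astype(np.float64)
    _check_same_shape(a, b)
    return _round_half_up((a + b) / 2.0).astype(np.uint8)


def mix_phase_magnitude(
    phase_source: np.ndarray,
    magnitude_source: np.ndarray,
    quantize: bool = True,
) -> np.ndarray:
    """Hybrid image from one source's Fourier phase and the other's magnitude.

    Per channel: ``out = Re(IFFT(|FFT(mag)| * exp(i * angle(FFT(phase)))))``,
    using the unnormalized forward / 1/(HW) inverse DFT convention. By default
    the result is clamped to [0, 255] and quantized; ``quantize=False``
    returns the raw floating-point inverse transform, whose magnitude
    spectrum equals the magnitude source's up to floating-point error.
    """
    p = validate_image(phase_source).astype(np.float64)
    m = validate_image(magnitude_source).astype(np.float64)
    _check_same_shape(p, m)
    out = np.empty_like(p)
    for c in range(3):
        fp = np.fft.fft2(p[:, :, c])
        fm = np.fft.fft2(m[:, :, c])
        hybrid = np.abs(fm) * np.exp(1j * np.angle(fp))
        out[:, :, c] = np.fft.ifft2(hybrid).real
    if not quantize:
        return out
    return _round_half_up(np.clip(out, 0.0, 255.0)).astype(np.uint8)


def build_mixture_set(
    images: Sequence[tuple[str, np.ndarray]],
    mode: MixMode = "average_5050",
    pairing: Pairing = "all_pairwise",
    seed: int | None = 0,
) -> list[MixtureRecord]:
    """Build the pairwise mixture set of an image bank.

    ``all_pairwise`` enumerates every unordered pair for the symmetric average
    mode (n(n-1)/2 records) and every ordered pair for the asymmetric
    phase/magnitude mode (n(n-1) records, the first source giving the phase).
    ``unique_pairing`` draws one seeded random perfect matching, n/2 records,
    each image used exactly once (requires an even count).
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    ids = [i for i, _ in images]
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique")
    bank = dict(images)

    if pairing == "all_pairwise":
        if mode == "average_5050":
            pairs = list(itertools.combinations(ids, 2))
        else:
            pairs = list(itertools.permutations(ids, 2))
    elif pairing == "unique_pairing":
        if len(ids) % 2 != 0:
            raise ValueError("unique_pairing requires an even number of images")
        rng = np.random.default_rng(seed)
        order = list(rng.permutation(len(ids)))
        pairs = [(ids[order[k]], ids[order[k + 1]]) for k in range(0, len(ids), 2)]
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    records = []
    for a, b in pairs:
        if mode == "average_5050":
            mixed = mix_average(bank[a], bank[b])
            note = ""
        else:
            mixed = mix_phase_magnitude(bank[a], bank[b])
            note = f"phase={a};magnitude={b}"
        records.append(
            MixtureRecord(
                id=f"{mode}:{a}+{b}",
                mode=mode,
                source1_id=a,
                source2_id=b,
                mixed=mixed,
                role_note=note,
            )
        )
    return records
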