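"""Synthetic inputs with known ground truth for every pipeline stage.

Everything the analysis consumes can be generated here with controlled
parameters, so the full pipeline runs — and its estimates can be checked
against the generating truth — without any external download:

* 1/f^alpha noise textures with steerable luminance, global contrast,
  saturation, hue and spectral slope (natural-image photographs do not allow
  independent control of these parameters; these textures do);
* image banks sampling those parameters over wide ranges, giving broad
  feature-ratio coverage for dominance curves;
* choice trials drawn from the dominance logistic model with known
  coefficients (the generative inverse of the fitting module);
* activation-stack fixtures with an analytically known mixture-winner
  correlation (mix = alpha * winner + sqrt(1 - alpha^2) * noise);
* coded report tables emulating pre-coded human trial outcomes.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .choice import ChoiceScenario
from .dominance import TrialRecord
from .layers import ActivationStack

__all__ = [
    "TextureSpec",
    "SyntheticChoiceSpec",
    "make_texture_image",
    "make_image_bank",
    "make_choice_trials",
    "make_activation_fixture",
    "make_report_table",
    "aggregate_report_table",
    "SCENARIO_CODES",
]

SCENARIO_CODES = ("none", "first", "second", "both")


@dataclass(frozen=True)
class TextureSpec:
    """Targets for one synthetic texture.

    ``luminance`` and ``saturation`` on the [0, 255] display scale,
    ``contrast`` as the population std of weighted intensity, ``alpha`` the
    1/f^alpha spectral slope (0 = white noise, 2 = strongly low-pass),
    ``hue`` in degrees on the HSV circle.
    """

    luminance: float
    contrast: float
    saturation: float = 0.0
    alpha: float = 1.0
    hue: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.luminance <= 255:
            raise ValueError("luminance target must be in [0, 255]")
        if self.contrast < 0 or self.alpha < 0:
            raise ValueError("contrast and alpha must be >= 0")
        if not 0 <= self.saturation <= 255:
            raise ValueError("saturation target must be in [0, 255]")


@dataclass(frozen=True)
class SyntheticChoiceSpec:
    """Generating model for choice trials: known logistic coefficients."""

    betas: Mapping[str, float]
    n_pairs: int = 500
    spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be > 0")
        if not all(np.isfinite(list(self.betas.values()))):
            raise ValueError("coefficients must be finite")
        if self.n_pairs < 1:
            raise ValueError("need at least one pair")


def _pink_noise_field(h: int, w: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-std 1/f^alpha Gaussian noise field."""
    white = rng.standard_normal((h, w))
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    r = np.hypot(fy, fx)
    r[0, 0] = 1.0  # avoid division by zero; DC is zeroed below
    shaping = r ** (-alpha / 2.0)
    shaping[0, 0] = 0.0  # zero mean by construction
    shaped = np.fft.ifft2(spectrum * shaping).real
    std = shaped.std()
    if std == 0:
        return shaped
    return shaped / std


def _hue_sat_direction(hue: float, sat01: float) -> np.ndarray:
    """HSV -> RGB at value 1: the fixed per-pixel color direction.

    For this vector c, max(c) = 1 and (max(c) - min(c)) / max(c) = sat01, so
    scaling pixels along c leaves the measured saturation at 255 * sat01.
    """
    h = (hue % 360.0) / 60.0
    c = sat01
    x = c * (1.0 - abs(h % 2 - 1.0))
    m = 1.0 - c
    sector = int(h) % 6
    rgb = [
        (c, x, 0.0), (x, c, 0.0), (0.0, c, x),
        (0.0, x, c), (x, 0.0, c), (c, 0.0, x),
    ][sector]
    return np.array(rgb) + m


def make_texture_image(spec: TextureSpec, side: int = 224) -> np.ndarray:
    """Seeded 1/f^alpha texture hitting the spec's luminance/contrast/saturation.

    The grayscale field is affinely mapped to the target mean and std, then
    colorized along a fixed hue/saturation direction whose luma projection is
    normalized out, so the weighted-intensity statistics are preserved.
    Raises when the targets would clip more than 1% of pixels.
    """
    rng = np.random.default_rng(spec.seed)
    field_ = _pink_noise_field(side, side, spec.alpha, rng)
    g = spec.luminance + spec.contrast * field_

    direction = _hue_sat_direction(spec.hue, spec.saturation / 255.0)
    luma_w = np.array([0.299, 0.587, 0.114])
    direction = direction / (luma_w @ direction)  # unit luma projection
    pixels = g[:, :, None] * direction[None, None, :]

    clipped = np.mean((pixels < 0.0) | (pixels > 255.0))
    if clipped >= 0.01:
        raise ValueError(
            f"unachievable targets: {clipped:.1%} of pixels would clip at [0, 255]"
        )
    return np.clip(np.floor(pixels + 0.5), 0, 255).astype(np.uint8)


DEFAULT_BANK_RANGES: dict[str, tuple[float, float]] = {
    "luminance": (60.0, 180.0),
    "contrast": (5.0, 35.0),
    "saturation": (4.0, 160.0),
    "alpha": (0.3, 2.2),
}


def make_image_bank(
    n: int = 180,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    side: int = 224,
) -> list[tuple[str, np.ndarray]]:
    """n seeded textures with parameters sampled log-uniformly over ranges.

    Log-uniform sampling spreads feature *ratios* widely and symmetrically,
    which is what populates dominance curves on their log axis.
    """
    if n < 2:
        raise ValueError("need at least 2 images")
    ranges = dict(DEFAULT_BANK_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    bank = []
    for i in range(n):
        # Rejection-sample jointly infeasible draws (e.g. saturated blue at
        # high luminance, which would clip); the accepted marginals stay wide.
        for _ in range(100):
            params = {
                key: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                for key, (lo, hi) in ranges.items()
            }
            spec = TextureSpec(
                luminance=params["luminance"],
                contrast=params["contrast"],
                saturation=params["saturation"],
                alpha=params["alpha"],
                hue=float(rng.uniform(0.0, 360.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                bank.append((f"tex{i:04d}", make_texture_image(spec, side)))
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not realize texture targets within the ranges")
    return bank


def make_choice_trials(spec: SyntheticChoiceSpec) -> list[TrialRecord]:
    """Choice trials drawn from the dominance logistic model.

    Per pair, feature log-ratios x_i ~ N(0, spread^2); the winner indicator is
    Bernoulli with P(y=1) = 1/(1 + exp(-sum beta_i x_i)). The per-image
    features are reconstructed as exp(+x/2) and exp(-x/2) around 1, so the
    log ratio of the stored features reproduces x exactly.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.betas)
    beta = np.array([spec.betas[n] for n in names])
    trials = []
    for i in range(spec.n_pairs):
        x = rng.normal(0.0, spec.spread, size=len(names))
        p = 1.0 / (1.0 + np.exp(-(beta @ x)))
        y = int(rng.random() < p)
        f1 = {n: float(np.exp(+x[j] / 2.0)) for j, n in enumerate(names)}
        f2 = {n: float(np.exp(-x[j] / 2.0)) for j, n in enumerate(names)}
        outcome = (
            ChoiceScenario("first", winner="I1")
            if y == 1
            else ChoiceScenario("second", winner="I2")
        )
        trials.append(
            TrialRecord(pair_id=f"pair{i:05d}", features1=f1, features2=f2,
                        outcome=outcome, y=y)
        )
    return trials


def make_activation_fixture(
    alpha: float,
    widths: Sequence[int] = (10_000, 10_000, 10_000),
    n_trials: int = 50,
    seed: int = 0,
) -> list[tuple[ActivationStack, ActivationStack, ActivationStack]]:
    """(mix, winner, loser) stacks with known mixture-winner correlation.

    Winner and loser activations are independent standard normal vectors; the
    mixture is alpha * winner + sqrt(1 - alpha^2) * fresh noise per layer, so
    the expected mix-winner correlation is alpha and mix-loser is ~0.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = tuple(f"layer{i + 1}" for i in range(len(widths)))
    out = []
    for _ in range(n_trials):
        winner_arrays, loser_arrays, mix_arrays = [], [], []
        for w in widths:
            win = rng.standard_normal(w)
            lose = rng.standard_normal(w)
            noise = rng.standard_normal(w)
            mix = alpha * win + np.sqrt(1.0 - alpha**2) * noise
            winner_arrays.append(win)
            loser_arrays.append(lose)
            mix_arrays.append(mix)
        out.append(
            (
                ActivationStack(tuple(zip(names, mix_arrays))),
                ActivationStack(tuple(zip(names, winner_arrays))),
                ActivationStack(tuple(zip(names, loser_arrays))),
            )
        )
    return out


def make_report_table(
    probabilities: Sequence[float],
    n_participants: int = 100,
    trials_per_participant: int = 30,
    condition: str = "5050_a",
    seed: int = 0,
) -> pd.DataFrame:
    """Coded human-trial table: multinomial scenario draws per participant.

    ``probabilities`` are the four scenario probabilities over
    (none, first, second, both) and must sum to 1. Columns:
    participant_id, pair_id, condition, scenario_code.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("probabilities must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for part in range(n_participants):
        draws = rng.choice(4, size=trials_per_participant, p=p)
        for t, d in enumerate(draws):
            rows.append(
                {
                    "participant_id": f"p{part:04d}",
                    "pair_id": f"pair{t:04d}",
                    "condition": condition,
                    "scenario_code": SCENARIO_CODES[d],
                }
            )
    return pd.DataFrame(rows)


def aggregate_report_table(table: pd.DataFrame) -> dict[str, float]:
    """Aggregate a coded report table into (none, one, both) proportions.

    "first" and "second" collapse into the one-image share. Standard errors
    are binomial over the pooled trial count.
    """
    codes = table["scenario_code"]
    n = len(codes)
    if n == 0:
        raise ValueError("empty report table")
    p_none = float((codes == "none").mean())
    p_one = float(codes.isin(["first", "second"]).mean())
    p_both = float((codes == "both").mean())
    out = {"p_none": p_none, "p_one": p_one, "p_both": p_both, "n_trials": n}
    for key in ("none", "one", "both"):
        p = out[f"p_{key}"]
        out[f"se_{key}"] = float(np.sqrt(p * (1 - p) / n))
    return out
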