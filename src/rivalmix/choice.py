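"""Classifying which source image a perceiver "chooses" from a mixture.

A mixture trial yields three output distributions over K categories: one for
the mixture and one for each original source. A source is "chosen" when the
top-N category set of the mixture intersects the source's top-N set; the trial
outcome is one of four scenarios — neither source recognized, the first, the
second, or both.

To emulate stochastic decision-making, zero-mean Gaussian noise with standard
deviation sigma can be injected into the logits before the softmax:

    P(class_i) = exp(x_i + eps_i) / sum_j exp(x_j + eps_j),  eps ~ N(0, sigma^2)

Scenario probabilities are estimated by repeatedly drawing a fixed-size sample
of mixtures without replacement (default 90 mixtures, 100 iterations) and
averaging the three proportions; a sigma sweep picks the noise level whose
scenario proportions best match a reference (e.g., human report proportions)
in total-variation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import softmax as _softmax

__all__ = [
    "CategoryDistribution",
    "ChoiceScenario",
    "ScenarioProbabilities",
    "noisy_softmax",
    "top_n",
    "classify_scenario",
    "scenario_probabilities",
    "sigma_sweep",
]

ScenarioValue = Literal["none", "first", "second", "both"]


@dataclass(frozen=True)
class CategoryDistribution:
    """Pre-softmax logits and the normalized probabilities over K categories."""

    logits: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "logits", np.asarray(self.logits, dtype=float))
        object.__setattr__(
            self, "probabilities", np.asarray(self.probabilities, dtype=float)
        )
        if self.logits.shape != self.probabilities.shape or self.logits.ndim != 1:
            raise ValueError("logits and probabilities must be 1-D of equal length")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def k(self) -> int:
        return self.logits.size


@dataclass(frozen=True)
class ChoiceScenario:
    """Four-way outcome of a mixture trial."""

    value: ScenarioValue
    winner: str | None = None

    def __post_init__(self) -> None:
        if self.value in ("none", "both"):
            if self.winner is not None:
                raise ValueError(f"winner must be None for scenario {self.value!r}")
        elif self.winner is None:
            raise ValueError(f"winner required for scenario {self.value!r}")


@dataclass(frozen=True)
class ScenarioProbabilities:
    """Mean scenario proportions with across-iteration standard errors."""

    p_none: float
    p_one: float
    p_both: float
    se_none: float
    se_one: float
    se_both: float
    n_iterations: int
    sample_size: int

    def as_vector(self) -> np.ndarray:
        return np.array([self.p_none, self.p_one, self.p_both])


def noisy_softmax(
    logits: np.ndarray, sigma: float = 0.0, rng: np.random.Generator | None = None
) -> CategoryDistribution:
    """Softmax of logits perturbed by i.i.d. N(0, sigma^2) noise.

    sigma = 0 reduces to the deterministic softmax. Numerically stabilized by
    max-subtraction, so any finite logits are handled.
    """
    x = np.asarray(logits, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("logits must be 1-D with K >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("logits must be finite")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        x = x + rng.normal(0.0, sigma, size=x.shape)
    return CategoryDistribution(logits=x, probabilities=_softmax(x))


def top_n(dist: CategoryDistribution, n: int) -> list[int]:
    """The n highest-probability categories, descending; ties break by index."""
    if not 1 <= n <= dist.k:
        raise ValueError(f"n must be in [1, {dist.k}]")
    order = np.argsort(-dist.probabilities, kind="stable")
    return list(map(int, order[:n]))


def classify_scenario(
    mix_dist: CategoryDistribution,
    orig1_dist: CategoryDistribution,
    orig2_dist: CategoryDistribution,
    n: int = 5,
    source_ids: tuple[str, str] = ("source1", "source2"),
) -> ChoiceScenario:
    """Top-N overlap rule: a source is chosen iff its top-N meets the mixture's."""
    if not (mix_dist.k == orig1_dist.k == orig2_dist.k):
        raise ValueError("all distributions must share the same K")
    mix_top = set(top_n(mix_dist, n))
    chose1 = bool(mix_top & set(top_n(orig1_dist, n)))
    chose2 = bool(mix_top & set(top_n(orig2_dist, n)))
    if chose1 and chose2:
        return ChoiceScenario("both")
    if chose1:
        return ChoiceScenario("first", winner=source_ids[0])
    if chose2:
        return ChoiceScenario("second", winner=source_ids[1])
    return ChoiceScenario("none")


def _proportions(scenarios: Sequence[ChoiceScenario]) -> np.ndarray:
    values = np.array([s.value for s in scenarios])
    n = len(values)
    return np.array(
        [
            np.sum(values == "none") / n,
            np.sum((values == "first") | (values == "second")) / n,
            np.sum(values == "both") / n,
        ]
    )


def scenario_probabilities(
    scenarios: Sequence[ChoiceScenario],
    sample_size: int = 90,
    iterations: int = 100,
    rng: np.random.Generator | None = None,
) -> ScenarioProbabilities:
    """Subsampled scenario proportions: mean and SE over repeated draws.

    Each iteration samples ``sample_size`` scenarios without replacement and
    computes the (none, one, both) proportions; the across-iteration mean and
    standard error of the mean are reported.
    """
    if len(scenarios) == 0:
        raise ValueError("empty scenario list")
    if sample_size > len(scenarios):
        raise ValueError("sample_size exceeds the number of scenarios")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    props = np.empty((iterations, 3))
    idx = np.arange(len(scenarios))
    for it in range(iterations):
        take = rng.choice(idx, size=sample_size, replace=False)
        props[it] = _proportions([scenarios[i] for i in take])
    mean = props.mean(axis=0)
    se = props.std(axis=0, ddof=1) / np.sqrt(iterations) if iterations > 1 else np.zeros(3)
    return ScenarioProbabilities(
        p_none=float(mean[0]),
        p_one=float(mean[1]),
        p_both=float(mean[2]),
        se_none=float(se[0]),
        se_one=float(se[1]),
        se_both=float(se[2]),
        n_iterations=iterations,
        sample_size=sample_size,
    )


def sigma_sweep(
    trial_logits: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    n: int,
    sigma_grid: Sequence[float],
    reference: ScenarioProbabilities,
    iterations: int = 100,
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
    noise_mixture_only: bool = False,
) -> tuple[dict[float, ScenarioProbabilities], float]:
    """Scenario proportions across noise levels and the best-matching sigma.

    Each trial supplies (mixture, source1, source2) logits. For every sigma on
    the grid, fresh noise is drawn per trial per iteration, scenarios are
    classified, a without-replacement sample of trials is taken, and the three
    proportions are averaged across iterations. ``best_sigma`` minimizes the
    total-variation distance to the reference (none, one, both) vector; ties
    break toward smaller sigma. With ``noise_mixture_only`` the source logits
    stay deterministic and only the mixture's output is perturbed.
    """
    if len(sigma_grid) == 0:
        raise ValueError("sigma grid must be non-empty")
    if any(s < 0 for s in sigma_grid):
        raise ValueError("sigma values must be >= 0")
    if len(trial_logits) == 0:
        raise ValueError("no trials provided")
    if rng is None:
        rng = np.random.default_rng()
    if sample_size is None:
        sample_size = min(90, len(trial_logits))

    results: dict[float, ScenarioProbabilities] = {}
    idx = np.arange(len(trial_logits))
    for sigma in sigma_grid:
        props = np.empty((iterations, 3))
        for it in range(iterations):
            scenarios = []
            for mix_l, o1_l, o2_l in trial_logits:
                mix_d = noisy_softmax(mix_l, sigma, rng)
                if noise_mixture_only:
                    o1_d = noisy_softmax(o1_l, 0.0)
                    o2_d = noisy_softmax(o2_l, 0.0)
                else:
                    o1_d = noisy_softmax(o1_l, sigma, rng)
                    o2_d = noisy_softmax(o2_l, sigma, rng)
                scenarios.append(classify_scenario(mix_d, o1_d, o2_d, n))
            take = rng.choice(idx, size=sample_size, replace=False)
            props[it] = _proportions([scenarios[i] for i in take])
        mean = props.mean(axis=0)
        se = (
            props.std(axis=0, ddof=1) / np.sqrt(iterations)
            if iterations > 1
            else np.zeros(3)
        )
        results[float(sigma)] = ScenarioProbabilities(
            *map(float, mean), *map(float, se), iterations, sample_size
        )

    ref = reference.as_vector()
    best_sigma = min(
        results,
        key=lambda s: (0.5 * np.abs(results[s].as_vector() - ref).sum(), s),
    )
    return results, float(best_sigma)
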