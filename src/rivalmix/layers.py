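"""Localizing where the competition is resolved in a layered perceiver.

For each mixture trial the perceiver's per-layer activation maps are compared
with those of the two source images by Pearson correlation: for
convolutional-style layers (channels x spatial) the correlation is computed
per channel map and averaged over channels; fully connected layers contribute
one correlation over their unit vector. Constant (zero-variance) maps are
assigned correlation 0 so layer averages stay comparable across images.
Profiles aggregate these correlations across trials — mean and standard error
per layer — split by the trial outcome (winner vs. loser reference, or which
of the phase/magnitude sources was chosen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "ActivationStack",
    "LayerCorrelationProfile",
    "layer_correlations",
    "winner_loser_profile",
    "outcome_grouped_profile",
]


@dataclass(frozen=True)
class ActivationStack:
    """Ordered, named per-layer activation arrays for one input image.

    Arrays with ndim >= 2 are treated as channel-major maps (axis 0 indexes
    channels); 1-D arrays are flat fully-connected activations.
    """

    layers: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        for name, arr in self.layers:
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"layer {name!r} has non-finite activations")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        for n, arr in self.layers:
            if n == name:
                return arr
        raise KeyError(name)


@dataclass(frozen=True)
class LayerCorrelationProfile:
    layer_names: tuple[str, ...]
    mean: np.ndarray
    se: np.ndarray  # NaN where only one trial contributed
    n_trials: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0  # constant map: defined as 0, still counted
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def layer_correlations(
    stack_a: ActivationStack,
    stack_b: ActivationStack,
    mode: Literal["per_channel", "flatten"] = "per_channel",
) -> np.ndarray:
    """Per-layer correlation between two activation stacks.

    ``per_channel`` averages channel-map correlations within each layer;
    ``flatten`` correlates the whole layer as one vector.
    """
    if stack_a.layer_names != stack_b.layer_names:
        raise ValueError("stacks have different layer structure")
    out = np.empty(len(stack_a.layers))
    for i, ((_, a), (_, b)) in enumerate(zip(stack_a.layers, stack_b.layers)):
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch at layer {stack_a.layer_names[i]!r}")
        if a.ndim >= 2 and mode == "per_channel":
            out[i] = np.mean([_pearson(a[c], b[c]) for c in range(a.shape[0])])
        else:
            out[i] = _pearson(a, b)
    return out


def _profile(rows: np.ndarray, names: tuple[str, ...]) -> LayerCorrelationProfile:
    n = rows.shape[0]
    mean = rows.mean(axis=0)
    if n > 1:
        se = rows.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = np.full(rows.shape[1], np.nan)
    return LayerCorrelationProfile(names, mean, se, n)


def winner_loser_profile(
    trials: Sequence[tuple[ActivationStack, ActivationStack, ActivationStack]],
    mode: Literal["per_channel", "flatten"] = "per_channel",
) -> tuple[LayerCorrelationProfile, LayerCorrelationProfile, np.ndarray]:
    """Mixture-vs-winner and mixture-vs-loser profiles and their difference.

    Each trial supplies (mixture, winner, loser) stacks; every trial enters
    both profiles, so the two are computed over identical trial counts.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")
    names = trials[0][0].layer_names
    w_rows = np.array([layer_correlations(m, w, mode) for m, w, _ in trials])
    l_rows = np.array([layer_correlations(m, l, mode) for m, _, l in trials])
    wp = _profile(w_rows, names)
    lp = _profile(l_rows, names)
    return wp, lp, wp.mean - lp.mean


def outcome_grouped_profile(
    trials: Sequence[tuple[ActivationStack, str]],
    references: tuple[ActivationStack, ActivationStack],
    mode: Literal["per_channel", "flatten"] = "per_channel",
) -> tuple[dict[str, dict[str, LayerCorrelationProfile | np.ndarray]], list[str]]:
    """Per-outcome-group correlation profiles against two fixed references.

    ``trials`` are (mixture stack, outcome label) with labels in
    {"phase_won", "magnitude_won", "neither"}; ``references`` are the
    (phase image, magnitude image) stacks. For each non-empty group the
    mixture's profile against each reference and their per-layer difference
    are returned; empty groups are omitted and listed in the warnings.
    """
    valid = ("phase_won", "magnitude_won", "neither")
    for _, label in trials:
        if label not in valid:
            raise ValueError(f"unknown outcome label {label!r}")
    phase_ref, mag_ref = references
    out: dict[str, dict] = {}
    warnings: list[str] = []
    for label in valid:
        group = [m for m, lab in trials if lab == label]
        if not group:
            warnings.append(f"empty group: {label}")
            continue
        names = group[0].layer_names
        p_rows = np.array([layer_correlations(m, phase_ref, mode) for m in group])
        m_rows = np.array([layer_correlations(m, mag_ref, mode) for m in group])
        pp = _profile(p_rows, names)
        mp = _profile(m_rows, names)
        out[label] = {
            "vs_phase": pp,
            "vs_magnitude": mp,
            "difference": pp.mean - mp.mean,
        }
    return out, warnings
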