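"""The perceiver contract and a deterministic mock perceiver.

A *perceiver* is any layered classifier the pipeline can analyze: it declares
a category count K and an ordered list of layer names, and maps an RGB image
to a ``CategoryDistribution`` (``classify``) and to an ``ActivationStack``
(``activations``). Both must be deterministic for a fixed instance and input.
The downstream pipeline never inspects anything beyond this contract, so
pretrained networks can be plugged in through an adapter without changing any
analysis code.

The mock perceiver shipped here is a fixed-seed hierarchy of block-mean
downsampling, random channel-mixing linear filters and rectification, ending
in a cosine-similarity head against K seeded templates scaled to logits. It
has no trained knowledge — it exists to give the pipeline a reproducible,
structured stimulus-to-category mapping for testing and simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .choice import CategoryDistribution, ChoiceScenario, classify_scenario, noisy_softmax
from .dominance import TrialRecord
from .features import extract_features
from .images import MixtureRecord, validate_image
from .layers import ActivationStack

__all__ = ["Perceiver", "MockPerceiver", "build_mock_perceiver", "run_competition"]

logger = logging.getLogger(__name__)


@runtime_checkable
class Perceiver(Protocol):
    """Contract any classifier must satisfy to be analyzed."""

    k: int
    layer_names: tuple[str, ...]

    def classify(self, image: np.ndarray) -> CategoryDistribution: ...

    def activations(self, image: np.ndarray) -> ActivationStack: ...


def _block_mean_downsample(x: np.ndarray, factor: int = 2) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h // factor, w // factor
    if h2 < 1 or w2 < 1:
        return x
    x = x[:, : h2 * factor, : w2 * factor]
    return x.reshape(c, h2, factor, w2, factor).mean(axis=(2, 4))


@dataclass
class MockPerceiver:
    """Seeded random feed-forward hierarchy implementing the perceiver contract."""

    seed: int = 0
    k: int = 50
    layer_widths: tuple[int, ...] = (8, 16, 32)
    input_side: int = 224
    embed_dim: int = 64
    logit_scale: float = 20.0
    layer_names: tuple[str, ...] = field(init=False)
    _weights: list[np.ndarray] = field(init=False, repr=False)
    _embed_w: np.ndarray = field(init=False, repr=False)
    _templates: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need K >= 2 categories")
        if len(self.layer_widths) < 1 or any(w < 1 for w in self.layer_widths):
            raise ValueError("invalid layer widths")
        side = self.input_side
        for _ in self.layer_widths:
            side //= 2
        if side < 1:
            raise ValueError("input_side too small for the requested depth")
        rng = np.random.default_rng(self.seed)
        self._weights = []
        prev = 3
        for width in self.layer_widths:
            w = rng.normal(0.0, 1.0 / np.sqrt(prev), size=(width, prev))
            self._weights.append(w)
            prev = width
        flat = prev * side * side
        # Random projection keeps spatial structure in the embedding (a plain
        # spatial average would make all stationary textures look alike).
        self._embed_w = rng.normal(0.0, 1.0 / np.sqrt(flat),
                                   size=(self.embed_dim, flat))
        self._templates = rng.normal(size=(self.k, self.embed_dim))
        self._templates /= np.linalg.norm(self._templates, axis=1, keepdims=True)
        self.layer_names = tuple(
            f"conv{i + 1}" for i in range(len(self.layer_widths))
        ) + ("embed",)

    def _forward(self, image: np.ndarray) -> list[np.ndarray]:
        arr = validate_image(image)
        if arr.shape[:2] != (self.input_side, self.input_side):
            from .images import standardize

            arr = standardize(arr, self.input_side)
        x = np.transpose(arr.astype(np.float64), (2, 0, 1)) / 255.0
        acts = []
        for w in self._weights:
            x = _block_mean_downsample(x, 2)
            x = np.tensordot(w, x, axes=(1, 0))  # channel mixing
            x = np.maximum(x, 0.0)  # ReLU
            acts.append(x)
        # Center each channel spatially before projecting: without this the
        # shared DC response dominates every embedding and all images land on
        # the same top categories.
        centered = x - x.mean(axis=(1, 2), keepdims=True)
        acts.append(self._embed_w @ centered.ravel())
        return acts

    def classify(self, image: np.ndarray) -> CategoryDistribution:
        embed = self._forward(image)[-1]
        norm = np.linalg.norm(embed)
        cos = self._templates @ (embed / norm) if norm > 0 else np.zeros(self.k)
        return noisy_softmax(self.logit_scale * cos, sigma=0.0)

    def activations(self, image: np.ndarray) -> ActivationStack:
        acts = self._forward(image)
        return ActivationStack(tuple(zip(self.layer_names, acts)))


def build_mock_perceiver(
    seed: int = 0,
    k: int = 50,
    layer_widths: Sequence[int] = (8, 16, 32),
    input_side: int = 224,
) -> MockPerceiver:
    """Construct the seeded mock perceiver (bit-reproducible per seed/config)."""
    return MockPerceiver(
        seed=seed, k=k, layer_widths=tuple(layer_widths), input_side=input_side
    )


def run_competition(
    perceiver: Perceiver,
    mixture_set: Sequence[MixtureRecord],
    sources: dict[str, np.ndarray],
    n: int = 5,
    sigma: float = 0.0,
    iterations: int = 1,
    seed: int | None = 0,
    keep_stacks: bool = False,
) -> list[dict]:
    """Classify every mixture against its sources and emit trial records.

    For each mixture record: classify the mixture and both sources, apply the
    top-N overlap rule, attach the sources' feature vectors, and emit one
    result dict per (mixture, iteration) holding the ``TrialRecord``, the
    three distributions and (optionally) activation stacks. With sigma > 0
    the logits are re-noised freshly per iteration; sigma = 0 collapses to a
    single deterministic iteration. Mixtures whose sources are missing are
    skipped with a logged warning.
    """
    rng = np.random.default_rng(seed)
    n_iter = iterations if sigma > 0 else 1
    dist_cache: dict[str, CategoryDistribution] = {}
    feat_cache: dict[str, dict] = {}

    def _source(sid: str):
        if sid not in dist_cache:
            dist_cache[sid] = perceiver.classify(sources[sid])
            feat_cache[sid] = extract_features(sources[sid]).as_dict()
        return dist_cache[sid], feat_cache[sid]

    results = []
    for rec in mixture_set:
        if rec.source1_id not in sources or rec.source2_id not in sources:
            logger.warning("skipping %s: missing source image", rec.id)
            continue
        mix_d0 = perceiver.classify(rec.mixed)
        d1_0, f1 = _source(rec.source1_id)
        d2_0, f2 = _source(rec.source2_id)
        for it in range(n_iter):
            if sigma > 0:
                mix_d = noisy_softmax(mix_d0.logits, sigma, rng)
                d1 = noisy_softmax(d1_0.logits, sigma, rng)
                d2 = noisy_softmax(d2_0.logits, sigma, rng)
            else:
                mix_d, d1, d2 = mix_d0, d1_0, d2_0
            scenario = classify_scenario(
                mix_d, d1, d2, n, source_ids=(rec.source1_id, rec.source2_id)
            )
            y = None
            if scenario.value == "first":
                y = 1
            elif scenario.value == "second":
                y = 0
            trial = TrialRecord(
                pair_id=rec.id,
                features1=f1,
                features2=f2,
                outcome=scenario,
                y=y,
            )
            item = {
                "trial": trial,
                "iteration": it,
                "mix_dist": mix_d,
                "source1_dist": d1,
                "source2_dist": d2,
                "mixture": rec,
            }
            if keep_stacks:
                item["stacks"] = {
                    "mix": perceiver.activations(rec.mixed),
                    "source1": perceiver.activations(sources[rec.source1_id]),
                    "source2": perceiver.activations(sources[rec.source2_id]),
                }
            results.append(item)
    return results
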