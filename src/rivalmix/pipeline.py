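"""End-to-end orchestration: simulate -> mix -> perceive -> classify -> fit -> layers.

A run is fully described by a ``RunConfig``: every stochastic stage has its
own explicit seed and no run-affecting constant lives outside the config, so
re-running the same config reproduces every analytic output byte for byte.
Outputs are flat CSV/JSON files in the run directory plus a structured log
with per-stage RNG state digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .choice import scenario_probabilities
from .dominance import best_subsets, dominance_curve, fit_dominance_glm
from .features import CORE_FEATURES
from .images import build_mixture_set
from .layers import winner_loser_profile
from .perceiver import build_mock_perceiver, run_competition
from .synthetic import make_image_bank

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    # synthetic bank
    n_images: int = 60
    image_side: int = 64
    bank_seed: int | None = 1

    # perceiver
    perceiver: str = "mock"
    perceiver_seed: int | None = 2
    k_categories: int = 50
    layer_widths: tuple[int, ...] = (8, 16, 32)

    # mixing
    mode: str = "average_5050"
    pairing: str = "all_pairwise"
    pairing_seed: int | None = 3

    # choice classification
    top_n: int = 5
    sigma: float = 0.0
    noise_seed: int | None = 4
    sample_size: int = 90
    iterations: int = 100
    sampling_seed: int | None = 5

    # dominance modeling
    feature_subset: tuple[str, ...] = CORE_FEATURES
    folds: int = 10
    subset_max: int = 2
    fit_seed: int | None = 6

    # layer analysis
    layer_trials: int = 20

    out_dir: str = "runs/run0"

    def validate(self) -> None:
        for name in ("bank_seed", "perceiver_seed", "pairing_seed",
                     "noise_seed", "sampling_seed", "fit_seed"):
            if getattr(self, name) is None:
                raise ValueError(f"config missing seed: {name}")
        if self.perceiver != "mock":
            raise ValueError("only the mock perceiver ships with the package")
        if self.n_images < 2:
            raise ValueError("need at least 2 images")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["layer_widths"] = list(self.layer_widths)
        d["feature_subset"] = list(self.feature_subset)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["layer_widths"] = tuple(d.get("layer_widths", (8, 16, 32)))
        d["feature_subset"] = tuple(d.get("feature_subset", CORE_FEATURES))
        return cls(**d)


def _rng_digest(seed: int) -> str:
    state = json.dumps(np.random.default_rng(seed).bit_generator.state, sort_keys=True)
    return hashlib.sha256(state.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list[str] = []

    def stage(name: str, fn, *seeds):
        for s in seeds:
            log.append(f"{name}: rng[{s}]={_rng_digest(s)}")
        try:
            result = fn()
        except Exception as e:
            log.append(f"{name}: FAILED ({e})")
            (out / "log.txt").write_text("\n".join(log) + "\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        log.append(f"{name}: ok")
        return result

    bank = stage(
        "bank",
        lambda: make_image_bank(config.n_images, seed=config.bank_seed,
                                side=config.image_side),
        config.bank_seed,
    )

    mixtures = stage(
        "mix",
        lambda: build_mixture_set(bank, mode=config.mode, pairing=config.pairing,
                                  seed=config.pairing_seed),
        config.pairing_seed,
    )
    stage("mix-manifest", lambda: rio.write_mixture_set(mixtures, out / "mixtures"))

    perceiver = stage(
        "perceiver",
        lambda: build_mock_perceiver(seed=config.perceiver_seed,
                                     k=config.k_categories,
                                     layer_widths=config.layer_widths,
                                     input_side=config.image_side),
        config.perceiver_seed,
    )

    sources = dict(bank)
    results = stage(
        "competition",
        lambda: run_competition(perceiver, mixtures, sources, n=config.top_n,
                                sigma=config.sigma, seed=config.noise_seed),
        config.noise_seed,
    )
    trials = [r["trial"] for r in results]
    stage("trials", lambda: rio.write_trials(trials, out / "trials.csv"))

    def _scenarios():
        scen = [t.outcome for t in trials]
        probs = scenario_probabilities(
            scen,
            sample_size=min(config.sample_size, len(scen)),
            iterations=config.iterations,
            rng=np.random.default_rng(config.sampling_seed),
        )
        (out / "scenario_probabilities.json").write_text(
            json.dumps(dataclasses.asdict(probs), indent=2)
        )
        return probs

    stage("scenarios", _scenarios, config.sampling_seed)

    def _fits():
        import pandas as pd

        fits = {}
        curve_rows = []
        for name in config.feature_subset:
            fit = fit_dominance_glm(trials, [name], lambda_grid=[0.0],
                                    folds=config.folds, rng=config.fit_seed)
            fits[name] = rio.fit_to_dict(fit)
            curve = dominance_curve(trials, name)
            for c, p, lo, hi, cnt in zip(curve.bin_centers, curve.p_choose_first,
                                         curve.ci_lower, curve.ci_upper, curve.counts):
                curve_rows.append({"feature": name, "bin_center": c,
                                   "p_choose_first": p, "ci_lower": lo,
                                   "ci_upper": hi, "count": cnt})
        pd.DataFrame(curve_rows).to_csv(out / "dominance_curves.csv", index=False)
        (out / "single_parameter_fits.json").write_text(json.dumps(fits, indent=2))
        table = best_subsets(trials, list(config.feature_subset),
                             max_size=config.subset_max, folds=config.folds,
                             seed=config.fit_seed)
        table.to_csv(out / "best_subsets.csv", index=False)
        return fits

    stage("fit", _fits, config.fit_seed)

    def _layers():
        single = [r for r in results if r["trial"].y is not None]
        subset = single[: config.layer_trials]
        if not subset:
            return None
        triples = []
        for r in subset:
            rec = r["mixture"]
            mix_stack = perceiver.activations(rec.mixed)
            s1 = perceiver.activations(sources[rec.source1_id])
            s2 = perceiver.activations(sources[rec.source2_id])
            if r["trial"].y == 1:
                triples.append((mix_stack, s1, s2))
            else:
                triples.append((mix_stack, s2, s1))
        wp, lp, diff = winner_loser_profile(triples)
        frame = rio.profile_to_frame(wp).rename(columns={"mean": "winner_mean",
                                                         "se": "winner_se"})
        lf = rio.profile_to_frame(lp)
        frame["loser_mean"] = lf["mean"]
        frame["loser_se"] = lf["se"]
        frame["difference"] = diff
        frame.to_csv(out / "layer_profiles.csv", index=False)
        return wp

    stage("layers", _layers)

    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out
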