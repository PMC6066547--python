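"""Flat-file input/output: images, manifests, trial tables, logits, profiles."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .choice import ChoiceScenario
from .dominance import LogisticFit, TrialRecord
from .images import MixtureRecord
from .layers import LayerCorrelationProfile

__all__ = [
    "read_image",
    "write_image",
    "write_mixture_set",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
    "fit_to_dict",
    "write_fit",
    "profile_to_frame",
    "read_report_table",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def write_mixture_set(
    records: Sequence[MixtureRecord], out_dir: str | Path
) -> pd.DataFrame:
    """Write mixture PNGs plus a manifest CSV; returns the manifest frame."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        fname = f"mix{i:05d}.png"
        write_image(out_dir / fname, rec.mixed)
        rows.append(
            {
                "id": rec.id,
                "file": fname,
                "mode": rec.mode,
                "source1_id": rec.source1_id,
                "source2_id": rec.source2_id,
                "phase_role": rec.role_note,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """One row per trial; per-source feature columns are suffixed _1 / _2."""
    rows = []
    for t in trials:
        row = {
            "pair_id": t.pair_id,
            "outcome": t.outcome.value,
            "winner": t.outcome.winner if t.outcome.winner is not None else "",
            "y": t.y if t.y is not None else "",
        }
        for name, val in t.features1.items():
            row[f"{name}_1"] = val
        for name, val in t.features2.items():
            row[f"{name}_2"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    feat_names = sorted(
        c[:-2] for c in frame.columns if c.endswith("_1") and c != "source_1"
    )
    trials = []
    for _, row in frame.iterrows():
        winner = row["winner"] if isinstance(row["winner"], str) and row["winner"] else None
        outcome = ChoiceScenario(row["outcome"], winner=winner)
        y = row["y"]
        y = None if (y == "" or pd.isna(y)) else int(y)
        trials.append(
            TrialRecord(
                pair_id=str(row["pair_id"]),
                features1={n: float(row[f"{n}_1"]) for n in feat_names},
                features2={n: float(row[f"{n}_2"]) for n in feat_names},
                outcome=outcome,
                y=y,
            )
        )
    return trials


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path, keep_default_na=False))


def fit_to_dict(fit: LogisticFit) -> dict:
    return {
        "feature_names": list(fit.feature_names),
        "coefficients": [float(b) for b in fit.coefficients],
        "standard_errors": [float(s) for s in fit.standard_errors],
        "n_trials": fit.n_trials,
        "lambda": fit.lambda_,
        "converged": bool(fit.converged),
        "flags": list(fit.flags),
    }


def write_fit(fit: LogisticFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2))


def profile_to_frame(profile: LayerCorrelationProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "layer": profile.layer_names,
            "mean": profile.mean,
            "se": profile.se,
            "n_trials": profile.n_trials,
        }
    )


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Read a coded human-trial table (participant_id, pair_id, condition,
    scenario_code); validates the scenario codes."""
    table = pd.read_csv(path)
    required = {"participant_id", "pair_id", "condition", "scenario_code"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"report table missing columns: {sorted(missing)}")
    bad = set(table["scenario_code"]) - {"none", "first", "second", "both"}
    if bad:
        raise ValueError(f"unknown scenario codes: {sorted(bad)}")
    return table
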