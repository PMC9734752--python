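"""Deterministic fixture suite tying all modules together.

``make_fixtures`` writes, under one directory:

- ``circle_right.csv`` / ``circle_left.csv`` — noiseless reference
  circles with known centre / radius / frequency, for estimator checks;
- ``training_right.csv`` / ``training_left.csv`` — a realistic drifting
  synthetic partner, for parameter estimation at study magnitudes;
- ``trial_<condition>/`` — one full trial per condition (four
  trajectory CSVs, a button CSV and a JSON sidecar);
- ``questionnaire.csv`` — a 34-participant synthetic questionnaire with
  documented injected effects (see ``questionnaire_effects.json``);
- ``sync_times.csv`` — a synthetic time-in-sync table with a small true
  coupling advantage hidden under participant baseline bias.

Everything is a pure function of the seed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict

import numpy as np

from .core_model import HandParams, HandTrajectory, ModelConfig
from .dyad_simulator import (
    default_profile,
    generate_questionnaire,
    generate_sync_times,
    run_trial,
)
from .io import write_button, write_config, write_trajectory

__all__ = ["make_fixtures", "noiseless_circle", "FIXTURE_EFFECTS"]

#: Injected questionnaire effects (question -> condition -> mean shift).
#: Question 9 ("moved like my mirror image") is pushed down in the
#: no-coupling condition, mirroring the strongest real effect direction.
FIXTURE_EFFECTS: Dict[int, Dict[str, float]] = {
    9: {"no_coupling": -2.0},
    7: {"no_coupling": -1.0},
}


def noiseless_circle(
    center=(0.343, 1.3, 0.25),
    radius: float = 0.163,
    omega: float = 2.695,
    side: str = "right",
    duration: float = 60.0,
    sample_rate: float = 50.0,
    phase0: float = 0.0,
) -> HandTrajectory:
    """Perfect circular trajectory with known parameters."""
    n = int(round(duration * sample_rate)) + 1
    times = np.arange(n) / sample_rate
    theta = phase0 + omega * times
    sign = 1.0 if side == "right" else -1.0
    pos = np.tile(np.asarray(center, dtype=float), (n, 1))
    pos[:, 1] += radius * np.sin(theta)
    pos[:, 2] += sign * radius * np.cos(theta)
    return HandTrajectory(side, times, pos)


def make_fixtures(seed: int = 0, out_dir="fixtures") -> Path:
    """Write the deterministic fixture suite; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = ModelConfig()

    write_trajectory(noiseless_circle(side="right"), out / "circle_right.csv")
    write_trajectory(
        noiseless_circle(center=(0.343, 1.3, -0.25), radius=0.161,
                         omega=2.698, side="left"),
        out / "circle_left.csv",
    )

    from .dyad_simulator import simulate_human

    training = default_profile(seed=seed + 101, kind="drifting")
    tr_r, tr_l = simulate_human(training, config)
    write_trajectory(tr_r, out / "training_right.csv")
    write_trajectory(tr_l, out / "training_left.csv")

    for i, condition in enumerate(("human", "no_coupling", "coupling")):
        trial_dir = out / f"trial_{condition}"
        trial_dir.mkdir(exist_ok=True)
        profile = default_profile(seed=seed + 11 + i)
        record = run_trial(condition, profile, config=config,
                           seed=seed + 21 + i)
        write_trajectory(record.human_right, trial_dir / "human_right.csv")
        write_trajectory(record.human_left, trial_dir / "human_left.csv")
        write_trajectory(record.virtual_right,
                         trial_dir / "virtual_right.csv")
        write_trajectory(record.virtual_left, trial_dir / "virtual_left.csv")
        write_button(record.human_right.times, record.button,
                     trial_dir / "button.csv")
        sidecar = {
            "condition": condition,
            "seed": record.seed,
            "model_used": condition != "human",
            "k_inter": record.config.k_inter,
            "k_intra": record.config.k_intra,
        }
        (trial_dir / "trial.json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    table = generate_questionnaire(effects=FIXTURE_EFFECTS, sd=1.0,
                                   seed=seed + 31)
    table.to_csv(out / "questionnaire.csv", index=False)
    (out / "questionnaire_effects.json").write_text(
        json.dumps(FIXTURE_EFFECTS, indent=2) + "\n"
    )

    generate_sync_times(seed=seed + 41).to_csv(
        out / "sync_times.csv", index=False
    )
    write_config(config, out / "config.yaml", seed=seed)
    return out
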