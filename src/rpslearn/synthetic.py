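"""Synthetic fixtures: deterministic streams and simulated participants.

Real participant play logs are unavailable, so every stage of the pipeline is
exercised on data generated here: the deterministic period-3 worked-example
stream used to check prediction-set bookkeeping, and full synthetic
participants -- agents with known ground-truth parameters playing the
scheduled opponent -- used for parameter-recovery and model-comparison
experiments.  Ground truth travels in a JSON sidecar next to the play-log
CSV so the log format itself stays clean.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .elph import ElphParams
from .environment import OpponentSchedule, default_schedule
from .experiment import read_playlog, run_game, write_playlog
from .relph import RelphParams

# Period-3 opponent cycle phased to start at 'paper': this is the phasing
# under which 21 observations yield the reference prediction-set counts
# (full context (paper, rock) -> rock seen 7 times; context rock@t-1 ->
# rock 7, paper 6).
WORKED_EXAMPLE_CYCLE: tuple[str, ...] = ("paper", "rock", "rock")


def worked_example_stream(length: int) -> list[str]:
    """First ``length`` symbols of the repeating (paper, rock, rock) cycle."""
    if length < 1:
        raise ValueError("stream length must be >= 1")
    return [WORKED_EXAMPLE_CYCLE[i % 3] for i in range(length)]


def synthetic_participant(
    model: str,
    params: ElphParams | RelphParams,
    schedule: OpponentSchedule | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one participant; returns (play log, ground-truth tag)."""
    if schedule is None:
        schedule = default_schedule()
    log = run_game(model, params, schedule=schedule, seed=seed)
    truth = {
        "model": model,
        "params": asdict(params),
        "seed": seed,
        "trials": int(schedule.total_trials),
    }
    return log, truth


def save_participant(log: pd.DataFrame, truth: dict, path) -> Path:
    """Write the log CSV plus a ``<log>.truth.json`` sidecar."""
    path = Path(path)
    write_playlog(log, path)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    with open(sidecar, "w") as fh:
        json.dump(truth, fh, indent=2)
    return sidecar


def load_participant(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    log = read_playlog(path)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    with open(sidecar) as fh:
        truth = json.load(fh)
    return log, truth
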