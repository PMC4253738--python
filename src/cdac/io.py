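"""Plain-text persistence: policy/value tables, trial logs, and task configs.

Policies and value functions are exported as CSV (one row per grid point and
fixation) with a JSON sidecar holding the solver metadata; floats are
written with ``repr`` so the round-trip is bit-exact.  Trial logs are one
CSV row per trial with the fixation sequence run-length encoded
(e.g. ``"0x12,1x3"`` = 12 steps at location 0 then 3 at location 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import build_belief_grid
from .simulator import TrialRecord
from .solver import Policy, ValueFunction

__all__ = [
    "save_policy",
    "load_policy",
    "trials_to_dataframe",
    "save_trials",
    "load_config",
    "rle_encode",
    "rle_decode",
]


def save_policy(path: str | Path, policy: Policy, values: ValueFunction | None = None) -> None:
    """Write a policy (and optionally its values) to CSV + JSON sidecar."""
    path = Path(path)
    grid = policy.grid
    G, F = policy.actions.shape
    gi = np.repeat(np.arange(G), F)
    fx = np.tile(np.arange(F), G)
    data = {"grid_index": gi}
    for d in range(grid.k):
        data[f"p_{d + 1}"] = grid.points[gi, d]
    data["fixation"] = fx
    data["action_code"] = policy.actions[gi, fx]
    data["value"] = (
        values.values[gi, fx] if values is not None else np.full(G * F, np.nan)
    )
    df = pd.DataFrame(data)
    # str() on Python floats round-trips exactly
    df.to_csv(path, index=False)
    sidecar = dict(policy.meta)
    sidecar.update({"k": grid.k, "grid_n": grid.n, "n_fixations": F})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_policy(path: str | Path) -> tuple[Policy, ValueFunction | None]:
    """Read back a policy written by :func:`save_policy` (bit-exact)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = build_belief_grid(int(meta["k"]), int(meta["grid_n"]))
    df = pd.read_csv(path, float_precision="round_trip")
    F = int(meta["n_fixations"])
    actions = np.empty((grid.size, F), dtype=np.int64)
    actions[df["grid_index"], df["fixation"]] = df["action_code"]
    vf = None
    if not df["value"].isna().all():
        vals = np.empty((grid.size, F))
        vals[df["grid_index"], df["fixation"]] = df["value"]
        vf = ValueFunction(grid, vals)
    return Policy(grid, actions, meta), vf


def rle_encode(seq: list[int]) -> str:
    if not seq:
        return ""
    parts = []
    run_val, run_len = seq[0], 1
    for v in seq[1:]:
        if v == run_val:
            run_len += 1
        else:
            parts.append(f"{run_val}x{run_len}")
            run_val, run_len = v, 1
    parts.append(f"{run_val}x{run_len}")
    return ",".join(parts)


def rle_decode(s: str) -> list[int]:
    if not s:
        return []
    out: list[int] = []
    for part in s.split(","):
        v, n = part.split("x")
        out.extend([int(v)] * int(n))
    return out


def trials_to_dataframe(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "condition": t.condition,
                "true_target": t.true_target,
                "initial_fixation": t.initial_fixation,
                "steps": t.steps,
                "switches": t.switches,
                "declared": t.declared,
                "correct": t.correct,
                "behavioral_cost": t.behavioral_cost,
                "fixation_sequence": rle_encode(t.fixations),
                "truncated": t.truncated,
                "seed": t.seed,
            }
        )
    return pd.DataFrame(rows)


def save_trials(path: str | Path, trials: list[TrialRecord]) -> None:
    trials_to_dataframe(trials).to_csv(Path(path), index=False)


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read back a trial log with bit-exact floats."""
    return pd.read_csv(Path(path), float_precision="round_trip")


def load_config(path: str | Path) -> dict:
    """Load a task-environment config (YAML or JSON).

    Recognized keys: ``k``, ``beta`` or ``betas`` (peripheral tiers),
    ``c``, ``cs``, ``prior``, ``grid_n``.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"malformed config {path}")
    if "beta" not in cfg and "betas" not in cfg:
        raise ValueError("config must set 'beta' (foveal) or 'betas' (peripheral)")
    cfg.setdefault("k", 3)
    cfg.setdefault("cs", 0.0)
    cfg.setdefault("grid_n", 200)
    cfg.setdefault("prior", [1.0 / cfg["k"]] * cfg["k"])
    if "c" not in cfg:
        raise ValueError("config must set the time cost 'c'")
    return cfg
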