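"""Behavioral summaries: accuracy/cost statistics, confirmation-bias tables,
and paired policy comparisons.

The confirmation-bias analysis mirrors the visual-search experiment: in a
block with target odds 1:3:9 across the three patches, trials are grouped by
the patch class fixated first ("9" = the a-priori most probable patch,
"1 and 3" = the two less probable patches pooled, which individually attract
few first fixations).  Within each class it reports the rate of declaring
the first-fixated patch when it holds the target (hits) and when it does not
(false alarms), and the dwell time on the first fixation — separately for
target-present and distractor-present first fixations, on correct trials
only.  A cost-sensitive searcher shows higher hit and false-alarm rates,
shorter target dwells, and longer distractor dwells at the "9" patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .inference import as_belief
from .simulator import TrialRecord, run_experiment
from .solver import CostParams

__all__ = [
    "SummaryStats",
    "ConfirmationBiasCell",
    "ConfirmationBiasTable",
    "summarize",
    "confirmation_bias_table",
    "compare_policies",
]


@dataclass
class SummaryStats:
    """Sample means (with standard errors) of the behavioral quantities."""

    n_trials: int
    accuracy: float
    mean_steps: float
    mean_switches: float
    mean_cost: float
    se_accuracy: float
    se_steps: float
    se_switches: float
    se_cost: float
    condition: str = ""


def _se(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / math.sqrt(x.size))


def summarize(trials: list[TrialRecord], costs: CostParams, condition: str = "") -> SummaryStats:
    """Summary statistics of a trial list; enforces the cost decomposition
    ``mean_cost = c * mean_steps + cs * mean_switches + (1 - accuracy)``."""
    if not trials:
        raise ValueError("cannot summarize an empty trial list")
    steps = np.array([t.steps for t in trials], dtype=float)
    switches = np.array([t.switches for t in trials], dtype=float)
    correct = np.array([t.correct for t in trials], dtype=float)
    cost = np.array([t.behavioral_cost for t in trials], dtype=float)
    stats = SummaryStats(
        n_trials=len(trials),
        accuracy=float(correct.mean()),
        mean_steps=float(steps.mean()),
        mean_switches=float(switches.mean()),
        mean_cost=float(cost.mean()),
        se_accuracy=_se(correct),
        se_steps=_se(steps),
        se_switches=_se(switches),
        se_cost=_se(cost),
        condition=condition,
    )
    recomposed = (
        costs.c * stats.mean_steps + costs.cs * stats.mean_switches + (1.0 - stats.accuracy)
    )
    if abs(recomposed - stats.mean_cost) > 1e-9 * max(1.0, stats.mean_cost):
        raise AssertionError("behavioral-cost decomposition identity violated")
    return stats


@dataclass
class ConfirmationBiasCell:
    """Per-class entries of the confirmation-bias table."""

    label: str
    n_target_first: int  # first-fixated patch held the target
    n_distractor_first: int
    hit_rate: float
    false_alarm_rate: float
    target_dwell: float  # mean first-fixation duration, correct target-first trials
    distractor_dwell: float  # same, correct distractor-first trials
    flagged: bool = False  # too few trials in some cell


@dataclass
class ConfirmationBiasTable:
    labeled: ConfirmationBiasCell  # the "9" patch
    others: ConfirmationBiasCell  # the "1 and 3" patches pooled
    n_conditioned: int
    n_excluded: int = 0


def confirmation_bias_table(trials: list[TrialRecord], prior,
                            min_cell: int = 20) -> ConfirmationBiasTable:
    """Hit/false-alarm rates and first-fixation dwells by first-fixated patch class.

    ``prior`` identifies the labeled ("9") patch as its argmax.  Only trials
    whose fixation sequence is non-empty enter; dwell columns use correct
    trials only.  Cells with fewer than ``min_cell`` trials are flagged
    rather than silently reported.
    """
    prior = as_belief(prior)
    labeled_loc = int(prior.argmax())
    groups: dict[str, list[TrialRecord]] = {"labeled": [], "others": []}
    excluded = 0
    for t in trials:
        if not t.fixations:
            excluded += 1
            continue
        first = t.fixations[0]
        groups["labeled" if first == labeled_loc else "others"].append(t)

    def cell(label: str, ts: list[TrialRecord]) -> ConfirmationBiasCell:
        tgt = [t for t in ts if t.fixations[0] == t.true_target]
        dis = [t for t in ts if t.fixations[0] != t.true_target]
        hits = [t.declared == t.fixations[0] for t in tgt]
        fas = [t.declared == t.fixations[0] for t in dis]
        tgt_ok = [t.first_fixation_duration() for t in tgt if t.correct]
        dis_ok = [t.first_fixation_duration() for t in dis if t.correct]
        flagged = min(len(tgt), len(dis), len(tgt_ok), len(dis_ok)) < min_cell
        return ConfirmationBiasCell(
            label=label,
            n_target_first=len(tgt),
            n_distractor_first=len(dis),
            hit_rate=float(np.mean(hits)) if hits else float("nan"),
            false_alarm_rate=float(np.mean(fas)) if fas else float("nan"),
            target_dwell=float(np.mean(tgt_ok)) if tgt_ok else float("nan"),
            distractor_dwell=float(np.mean(dis_ok)) if dis_ok else float("nan"),
            flagged=flagged,
        )

    return ConfirmationBiasTable(
        labeled=cell("9", groups["labeled"]),
        others=cell("1 and 3", groups["others"]),
        n_conditioned=len(groups["labeled"]) + len(groups["others"]),
        n_excluded=excluded,
    )


def compare_policies(entries: dict, prior, target_distribution, n_trials: int,
                     seed: int, initial_fixation="matched",
                     max_steps: int = 10_000) -> dict[str, SummaryStats]:
    """Run matched experiments for several policies and summarize each.

    ``entries`` maps a policy name to ``(policy, model, costs)``.  All
    policies share the same master seed, so target sequences and initial
    fixations are paired across policies.
    """
    out = {}
    for name, (policy, model, costs) in entries.items():
        trials = run_experiment(
            policy, model, costs, prior, n_trials, target_distribution,
            seed=seed, initial_fixation=initial_fixation, max_steps=max_steps,
            condition=name,
        )
        out[name] = summarize(trials, costs, condition=name)
    return out
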