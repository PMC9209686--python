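"""Endpoint-evaluation pipeline: score options across trials, discriminate,
pool, rank.

For every candidate option and every trial the pipeline computes the
per-arm responder counts (binary designs) or arm summaries (continuous
point sum), plus the concordance index of the outcome against arm.  Trials
judged positive or in-between by the expert panel are pooled together — a
good endpoint should show an effect there — and negative trials are pooled
separately, where the effect should vanish.  Binary options pool as odds
ratios, continuous ones as standardised mean differences.

Ranking rewards distance from the null on the positive side and penalises
it on the negative side: score = |effect_pos| − λ·|effect_neg| on the
analysis scale (log-OR or SMD), λ defaulting to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .meta import ContinuousStudy, MetaResult, TwoByTwo, pool_binary, pool_continuous
from .metrics import c_index
from .option_space import OptionSpec, responder_status, score_option
from .scoring import Response
from .trial_data import TrialDataset

__all__ = [
    "TrialOptionStats",
    "OptionEvaluation",
    "RankedOption",
    "evaluate_options",
    "rank_options",
]

logger = logging.getLogger("sjstar")

POSITIVE_CLASSES = ("positive", "in_between")


@dataclass(frozen=True)
class TrialOptionStats:
    """One option evaluated on one trial."""

    trial_id: str
    expert_class: str
    c: float
    counts: TwoByTwo | None = None  # binary designs
    excluded: int = 0  # patients with undetermined status
    continuous: ContinuousStudy | None = None  # continuous designs


@dataclass(frozen=True)
class OptionEvaluation:
    option_id: str
    kind: str  # "binary" or "continuous"
    per_trial: Mapping[str, TrialOptionStats]
    meta_positive: MetaResult | None
    meta_negative: MetaResult | None


@dataclass(frozen=True)
class RankedOption:
    option_id: str
    score: float
    evaluation: OptionEvaluation


def _binary_trial_stats(trial: TrialDataset, spec: OptionSpec) -> TrialOptionStats:
    outcomes = {"treatment": [0, 0], "placebo": [0, 0]}  # events, n
    excluded = 0
    flags: dict[str, list[int]] = {"treatment": [], "placebo": []}
    for record in trial.records:
        status = responder_status(record, spec)
        if status is Response.UNDETERMINED:
            excluded += 1
            continue
        yes = status is Response.YES
        outcomes[record.arm][0] += int(yes)
        outcomes[record.arm][1] += 1
        flags[record.arm].append(int(yes))
    counts = TwoByTwo(
        events_t=outcomes["treatment"][0], n_t=outcomes["treatment"][1],
        events_p=outcomes["placebo"][0], n_p=outcomes["placebo"][1],
    )
    c = c_index(flags["treatment"], flags["placebo"]).c
    return TrialOptionStats(
        trial_id=trial.trial_id, expert_class=trial.expert_class,
        c=c, counts=counts, excluded=excluded,
    )


def _continuous_trial_stats(trial: TrialDataset, spec: OptionSpec) -> TrialOptionStats:
    scores: dict[str, list[float]] = {"treatment": [], "placebo": []}
    for record in trial.records:
        scores[record.arm].append(float(score_option(record, spec)))
    t = np.array(scores["treatment"])
    p = np.array(scores["placebo"])
    study = ContinuousStudy(
        mean_t=float(t.mean()), sd_t=float(t.std(ddof=1)), n_t=len(t),
        mean_p=float(p.mean()), sd_p=float(p.std(ddof=1)), n_p=len(p),
    )
    return TrialOptionStats(
        trial_id=trial.trial_id, expert_class=trial.expert_class,
        c=c_index(t, p).c, continuous=study,
    )


def evaluate_options(
    trials: Sequence[TrialDataset],
    options: Sequence[OptionSpec],
    level: float = 0.95,
) -> list[OptionEvaluation]:
    """Evaluate every option on every trial and pool by expert class.

    Patients whose responder status is undetermined under an option are
    excluded from that option's 2×2 for that trial (determinate
    denominators), with the excluded count reported.  A missing expert
    class leaves the corresponding meta-analysis as None.
    """
    if not trials:
        raise ValueError("no trials supplied")
    evaluations = []
    for spec in options:
        kind = "continuous" if spec.design == "design_3b_continuous" else "binary"
        per_trial: dict[str, TrialOptionStats] = {}
        for trial in trials:
            if kind == "binary":
                per_trial[trial.trial_id] = _binary_trial_stats(trial, spec)
            else:
                per_trial[trial.trial_id] = _continuous_trial_stats(trial, spec)

        def pooled(classes: tuple[str, ...]) -> MetaResult | None:
            subset = [s for s in per_trial.values() if s.expert_class in classes]
            if not subset:
                return None
            if kind == "binary":
                return pool_binary([s.counts for s in subset], level)
            return pool_continuous([s.continuous for s in subset], level)

        evaluations.append(OptionEvaluation(
            option_id=spec.option_id,
            kind=kind,
            per_trial=per_trial,
            meta_positive=pooled(POSITIVE_CLASSES),
            meta_negative=pooled(("negative",)),
        ))
        logger.debug("evaluated option %s", spec.option_id)
    return evaluations


def rank_options(
    evaluations: Sequence[OptionEvaluation], lam: float = 1.0
) -> list[RankedOption]:
    """Order options by positive-side effect minus negative-side penalty.

    score = |pooled effect in positive-class trials| − λ·|pooled effect in
    negative-class trials| on the analysis scale; a missing side
    contributes 0.  Stable sort, ties broken by option_id.
    """
    if not evaluations:
        raise ValueError("no evaluations to rank")
    ranked = []
    for ev in evaluations:
        pos = abs(ev.meta_positive.pooled) if ev.meta_positive else 0.0
        neg = abs(ev.meta_negative.pooled) if ev.meta_negative else 0.0
        ranked.append(RankedOption(ev.option_id, pos - lam * neg, ev))
    ranked.sort(key=lambda r: (-r.score, r.option_id))
    return ranked
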