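"""Learning curves, criterion trials, ordinal-position accuracy, error
taxonomy with exponential-decay fits, reaction-time summaries, and
proficiency partitions.

The learning criterion is the first trial at which the completion rate
reaches 80% and stays there for three further consecutive trials. It is
computed on the raw per-trial completion proportions; the four-parameter
logistic fit is a purely descriptive summary of the curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .types import (DISTRACTOR, MAX_TRIALS_PER_CONTEXT, N_OBJECTS,
                    N_POSITIONS, BlockLog, ChoiceRecord, SeqswapError)

logger = logging.getLogger("seqswap")

ERROR_TYPES = ("exploration", "rule_breaking", "distractor", "perseverative")

#: Errors-per-trial cut points the study used to split sequences into
#: proficiency terciles: good <= 5.33, poor > 6.6.
PAPER_PROFICIENCY_THRESHOLDS = (5.33, 6.6)


@dataclass
class LearningCurve:
    proportions: np.ndarray  # per-trial completion proportion
    n: np.ndarray            # blocks contributing per trial
    context: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, float)
        self.n = np.asarray(self.n, int)


@dataclass
class SigmoidFit:
    lower: float
    upper: float
    midpoint: float
    slope: float
    rss: float
    converged: bool


@dataclass
class CriterionResult:
    criterion_trial: int | None   # None when censored
    threshold: float = 0.8
    sustain: int = 3

    @property
    def censored(self) -> bool:
        return self.criterion_trial is None


@dataclass
class OrdinalAccuracy:
    proportions: np.ndarray       # per position 1..5; nan when undefined
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray
    undefined: list[int] = field(default_factory=list)


@dataclass
class ErrorBreakdown:
    proportions: dict[str, np.ndarray]   # error type -> per-trial proportion
    counts: dict[str, np.ndarray]
    total_errors: np.ndarray


@dataclass
class DecayFit:
    a: float
    b: float
    c: float
    rss: float
    converged: bool


@dataclass
class RTPositionSummary:
    mean_before: float
    ci_before: tuple[float, float]
    n_before: int
    mean_after: float
    ci_after: tuple[float, float]
    n_after: int
    welch_t: float
    welch_p: float


@dataclass
class RTSummary:
    positions: dict[int, RTPositionSummary]
    missing_positions: list[int]


@dataclass
class ProficiencyPartition:
    rates: dict[str, float]       # block_id -> mean errors per trial
    assignment: dict[str, str]    # block_id -> good / mid / poor
    thresholds: tuple[float, float]


def completion_curve(blocks: list[BlockLog], context: int) -> LearningCurve:
    """Per-trial proportion of blocks whose trial was completed."""
    if not blocks:
        raise SeqswapError("no blocks given")
    counts = np.zeros(MAX_TRIALS_PER_CONTEXT)
    completed = np.zeros(MAX_TRIALS_PER_CONTEXT)
    for block in blocks:
        for trial in block.trials(context):
            counts[trial - 1] += 1
            if block.completed(context, trial):
                completed[trial - 1] += 1
    if counts.sum() == 0:
        raise SeqswapError(f"no context-{context} trials in the given blocks")
    last = int(np.max(np.nonzero(counts)[0])) + 1
    counts = counts[:last]
    with np.errstate(invalid="ignore"):
        proportions = np.where(counts > 0, completed[:last] / counts, np.nan)
    return LearningCurve(proportions=proportions, n=counts, context=context)


def trials_to_criterion(curve: LearningCurve | np.ndarray,
                        threshold: float = 0.8,
                        sustain: int = 3) -> CriterionResult:
    """First trial at or above threshold, sustained for ``sustain`` more
    consecutive trials; censored when no such trial exists."""
    values = np.asarray(curve.proportions if isinstance(curve, LearningCurve)
                        else curve, float)
    if values.size == 0:
        raise SeqswapError("empty curve")
    if not 0.0 < threshold <= 1.0:
        raise SeqswapError("threshold must be in (0, 1]")
    if sustain < 0:
        raise SeqswapError("sustain must be >= 0")
    ok = values >= threshold
    for t in range(len(values) - sustain):
        if ok[t:t + sustain + 1].all():
            return CriterionResult(criterion_trial=t + 1,
                                   threshold=threshold, sustain=sustain)
    return CriterionResult(criterion_trial=None, threshold=threshold,
                           sustain=sustain)


def block_criterion(block: BlockLog, context: int, threshold: float = 0.8,
                    sustain: int = 3) -> CriterionResult:
    """Criterion applied to one block's own 0/1 completion flags."""
    flags = np.asarray(block.completion_flags(context), float)
    if flags.size == 0:
        return CriterionResult(criterion_trial=None, threshold=threshold,
                               sustain=sustain)
    return trials_to_criterion(flags, threshold=threshold, sustain=sustain)


def _logistic4(x, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_sigmoid(curve: LearningCurve | np.ndarray) -> SigmoidFit:
    """Bounded least-squares 4-parameter logistic fit of a completion curve.

    Three starting points guard against local minima; non-convergence is
    reported through the ``converged`` flag, never as an exception.
    """
    y = np.asarray(curve.proportions if isinstance(curve, LearningCurve)
                   else curve, float)
    mask = np.isfinite(y)
    x = np.arange(1, len(y) + 1, dtype=float)[mask]
    y = y[mask]
    if y.size < 4:
        raise SeqswapError("need at least 4 trials with data")
    lo = [0.0, 0.0, -10.0, 0.0]
    hi = [1.0, 1.0, 3.0 * MAX_TRIALS_PER_CONTEXT, 20.0]
    y0, y1 = float(y[0]), float(y[-1])
    mid0 = float(x[len(x) // 2])
    starts = [
        (min(y0, y1), max(y0, y1), mid0, 1.0),
        (0.0, 1.0, 3.0, 2.0),
        (float(y.min()), float(y.max()), float(x[-1]) / 2.0, 0.5),
    ]
    best: tuple[float, np.ndarray] | None = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            popt, _ = optimize.curve_fit(_logistic4, x, y, p0=p0,
                                         bounds=(lo, hi), maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _logistic4(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        mean = float(y.mean())
        return SigmoidFit(lower=mean, upper=mean, midpoint=mid0, slope=0.0,
                          rss=float(np.sum((y - mean) ** 2)), converged=False)
    rss, popt = best
    lower, upper, midpoint, slope = (float(v) for v in popt)
    if lower > upper:
        lower, upper = upper, lower
    return SigmoidFit(lower=lower, upper=upper, midpoint=midpoint,
                      slope=slope, rss=rss, converged=True)


def forward_chance(position: int) -> float:
    """Chance correctness at a position when already-secured objects are
    never re-chosen: 1/(7 - position) among the 6 on-screen objects."""
    if not 1 <= position <= N_POSITIONS:
        raise SeqswapError(f"position must be in 1..{N_POSITIONS}")
    return 1.0 / (N_OBJECTS - position + 1)


def _first_search_attempts(block: BlockLog, context: int,
                           trials) -> dict[int, list[ChoiceRecord]]:
    """First search touch per (trial, position), keyed by position."""
    out: dict[int, list[ChoiceRecord]] = {p: [] for p in
                                          range(1, N_POSITIONS + 1)}
    for trial, recs in block.trials(context).items():
        if trial not in trials:
            continue
        seen: set[int] = set()
        for rec in recs:
            if rec.phase != "search" or rec.ordinal_target in seen:
                continue
            seen.add(rec.ordinal_target)
            out[rec.ordinal_target].append(rec)
    return out


def ordinal_accuracy(blocks: list[BlockLog],
                     trials=range(12, 16),
                     context: int = 1) -> OrdinalAccuracy:
    """Proportion of correct first search attempts per ordinal position,
    pooled over the given trials (default: the last four, trials 12-15)."""
    trials = set(trials)
    if not trials <= set(range(1, MAX_TRIALS_PER_CONTEXT + 1)):
        raise SeqswapError("trial range must lie within 1..15")
    hits = np.zeros(N_POSITIONS)
    n = np.zeros(N_POSITIONS)
    for block in blocks:
        for pos, recs in _first_search_attempts(block, context,
                                                trials).items():
            n[pos - 1] += len(recs)
            hits[pos - 1] += sum(r.is_correct for r in recs)
    undefined = [p + 1 for p in range(N_POSITIONS) if n[p] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
        half = 1.96 * np.sqrt(p * (1 - p) / np.maximum(n, 1))
    return OrdinalAccuracy(proportions=p, ci_low=p - half, ci_high=p + half,
                           n=n.astype(int), undefined=undefined)


def classify_error(record: ChoiceRecord,
                   history: list[ChoiceRecord]) -> str:
    """Assign one error type to an incorrect touch.

    Definitions overlap (a repeated distractor touch is both perseverative
    and a distractor error), so a fixed precedence resolves them:
    rule_breaking > perseverative > distractor > exploration.

    * rule_breaking - failing to re-touch the last correct object in a
      retouch phase, or re-selecting an object already correctly chosen in
      this trial.
    * perseverative - repeating the same incorrect object as the last
      search choice before the forced re-selection.
    * distractor - touching the sequence-irrelevant object X.
    * exploration - any other incorrect choice among objects not yet
      correctly chosen ("not yet learned" within the trial).
    """
    if record.is_correct:
        raise SeqswapError("classify_error called on a correct choice")
    secured = {r.chosen_label for r in history
               if r.phase == "search" and r.is_correct}
    if record.phase == "retouch" or record.chosen_label in secured:
        return "rule_breaking"
    if history and history[-1].phase == "retouch" and history[-1].is_correct:
        last_search = next((r for r in reversed(history)
                            if r.phase == "search"), None)
        if (last_search is not None and not last_search.is_correct
                and last_search.chosen_label == record.chosen_label):
            return "perseverative"
    if record.chosen_label == DISTRACTOR:
        return "distractor"
    return "exploration"


def error_breakdown(blocks: list[BlockLog],
                    context: int | None = None) -> ErrorBreakdown:
    """Per-trial proportion of each error type relative to all errors."""
    counts = {t: np.zeros(MAX_TRIALS_PER_CONTEXT) for t in ERROR_TYPES}
    contexts = (1, 2) if context is None else (context,)
    for block in blocks:
        for ctx in contexts:
            for trial, recs in block.trials(ctx).items():
                for i, rec in enumerate(recs):
                    if not rec.is_correct:
                        kind = classify_error(rec, recs[:i])
                        counts[kind][trial - 1] += 1
    total = sum(counts.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = {t: np.where(total > 0, c / np.maximum(total, 1),
                                   np.nan)
                       for t, c in counts.items()}
    return ErrorBreakdown(proportions=proportions, counts=counts,
                          total_errors=total)


def _exp_decay(x, a, b, c):
    return a * np.exp(-b * x) + c


def fit_error_decay(breakdown: ErrorBreakdown | np.ndarray,
                    error_type: str | None = None) -> DecayFit:
    """Least-squares fit of ``a * exp(-b * x) + c`` across trials.

    ``b`` is the decay speed and is reported even when non-positive.
    """
    if isinstance(breakdown, ErrorBreakdown):
        if error_type not in ERROR_TYPES:
            raise SeqswapError(f"error_type must be one of {ERROR_TYPES}")
        y = breakdown.proportions[error_type]
    else:
        y = np.asarray(breakdown, float)
    mask = np.isfinite(y)
    x = np.arange(1, len(y) + 1, dtype=float)[mask]
    y = y[mask]
    if y.size < 4:
        raise SeqswapError("need at least 4 trials with defined proportions")
    y0, yend = float(y[0]), float(y[-1])
    starts = [(y0 - yend, 0.2, yend), (max(y0, 1e-3), 0.05, 0.0),
              (y0 - yend, 1.0, yend)]
    lo = [-2.0, -5.0, -1.0]
    hi = [2.0, 5.0, 1.0]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            popt, _ = optimize.curve_fit(_exp_decay, x, y, p0=p0,
                                         bounds=(lo, hi), maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _exp_decay(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return DecayFit(a=0.0, b=0.0, c=float(y.mean()),
                        rss=float(np.sum((y - y.mean()) ** 2)),
                        converged=False)
    rss, (a, b, c) = best
    return DecayFit(a=float(a), b=float(b), c=float(c), rss=rss,
                    converged=True)


def _mean_ci(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, (math.nan, math.nan)
    half = 1.96 * float(np.std(values, ddof=1)) / math.sqrt(len(values))
    return mean, (mean - half, mean + half)


def rt_summary(blocks: list[BlockLog], criterion: CriterionResult,
               context: int = 1) -> RTSummary | None:
    """Mean reaction time of correct search touches per ordinal position,
    split into trials before versus from the criterion trial on, with a
    Welch comparison per position. Returns None when no RTs are present."""
    cut = (criterion.criterion_trial if not criterion.censored
           else MAX_TRIALS_PER_CONTEXT + 1)
    before: dict[int, list[float]] = {p: [] for p in range(1, N_POSITIONS + 1)}
    after: dict[int, list[float]] = {p: [] for p in range(1, N_POSITIONS + 1)}
    any_rt = False
    for block in blocks:
        for rec in block.records:
            if (rec.context != context or rec.phase != "search"
                    or not rec.is_correct or rec.rt is None):
                continue
            any_rt = True
            bucket = before if rec.trial_index < cut else after
            bucket[rec.ordinal_target].append(rec.rt)
    if not any_rt:
        logger.info("rt_summary: no reaction times present; skipped")
        return None
    positions: dict[int, RTPositionSummary] = {}
    missing: list[int] = []
    for p in range(1, N_POSITIONS + 1):
        b = np.asarray(before[p], float)
        a = np.asarray(after[p], float)
        if b.size == 0 and a.size == 0:
            missing.append(p)
            continue
        mb, cb = _mean_ci(b) if b.size else (math.nan, (math.nan, math.nan))
        ma, ca = _mean_ci(a) if a.size else (math.nan, (math.nan, math.nan))
        if b.size >= 2 and a.size >= 2 and (b.var() > 0 or a.var() > 0):
            t, pval = stats.ttest_ind(b, a, equal_var=False)
        elif b.size >= 2 and a.size >= 2:
            t, pval = 0.0, 1.0
        else:
            t, pval = math.nan, math.nan
        positions[p] = RTPositionSummary(
            mean_before=mb, ci_before=cb, n_before=b.size,
            mean_after=ma, ci_after=ca, n_after=a.size,
            welch_t=float(t), welch_p=float(pval))
    return RTSummary(positions=positions, missing_positions=missing)


def partition_by_proficiency(blocks: list[BlockLog],
                             thresholds: tuple[float, float] | str | None =
                             "paper",
                             context: int = 1) -> ProficiencyPartition:
    """Split blocks into good / mid / poor by mean errors per trial.

    ``thresholds="paper"`` applies the study's cut points (good <= 5.33,
    poor > 6.6); ``thresholds=None`` uses empirical terciles with a
    deterministic tie-break on block id.
    """
    if len(blocks) < 3:
        raise SeqswapError("need at least 3 blocks")
    rates = {b.block_id: b.mean_errors_per_trial(context) for b in blocks}
    assignment: dict[str, str] = {}
    if thresholds == "paper":
        thresholds = PAPER_PROFICIENCY_THRESHOLDS
    if thresholds is not None:
        good_max, poor_min = thresholds
        for bid, rate in rates.items():
            if rate <= good_max:
                assignment[bid] = "good"
            elif rate > poor_min:
                assignment[bid] = "poor"
            else:
                assignment[bid] = "mid"
        return ProficiencyPartition(rates=rates, assignment=assignment,
                                    thresholds=tuple(thresholds))
    ordered = sorted(rates, key=lambda bid: (rates[bid], bid))
    parts = np.array_split(np.arange(len(ordered)), 3)
    labels = ("good", "mid", "poor")
    for part, lab in zip(parts, labels):
        for i in part:
            assignment[ordered[i]] = lab
    good_max = rates[ordered[len(parts[0]) - 1]] if len(parts[0]) else math.nan
    poor_min = (rates[ordered[len(parts[0]) + len(parts[1])]]
                if len(parts[2]) else math.nan)
    return ProficiencyPartition(rates=rates, assignment=assignment,
                                thresholds=(good_max, poor_min))
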