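"""Transition probabilities after conditioning events, pro-/retro-active
swap indices, first-choice analyses, distractor analyses, and the small
inferential-statistics toolkit (Welch t, Bonferroni/BH adjustment,
two-proportion Z, simple OLS with Cohen's f^2).

The two headline indices:

* pro-active swapping  = P(D | after correctly choosing A)
                       - P(B | after correctly choosing A)
* retro-active swapping = P(D | after erroneously choosing B)
                        - P(C | after erroneously choosing B)

both measured in context 2 on trials before the block reached the learning
criterion. The forced retouch that follows an error is never counted as a
transition target: the next *free* search choice is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .types import (LABELS, MAX_TRIALS_PER_CONTEXT, N_POSITIONS, BlockLog,
                    SeqswapError)
from .learning import block_criterion

EVENTS = ("after_correct_A", "after_error_B", "after_correct_D")

#: (trigger label, trigger must be correct, ordinal position of the trigger)
_EVENT_SPEC = {
    "after_correct_A": ("A", True, 1),
    "after_error_B": ("B", False, 2),
    "after_correct_D": ("D", True, 2),
}


@dataclass
class TransitionTable:
    event: str
    labels: tuple[str, ...]
    counts: np.ndarray
    probabilities: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_events: int

    @property
    def empty(self) -> bool:
        return self.n_events == 0

    def probability(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])


@dataclass
class SwapIndices:
    proactive: float
    retroactive: float
    serial_contrast: float
    n_proactive_events: int = 0
    n_retroactive_events: int = 0


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p: float
    adjusted_p: float | None = None
    adjustment: str | None = None
    effect_size: float | None = None
    note: str | None = None


@dataclass
class RegressionResult:
    beta: float
    intercept: float
    r_squared: float
    p: float
    cohens_f2: float
    n: int


@dataclass
class FirstChoiceResult:
    labels: tuple[str, ...]
    p_context1: np.ndarray
    p_context2: np.ndarray
    difference: np.ndarray
    tests: dict[str, TestResult]
    n_blocks: int
    n_excluded: int


@dataclass
class TrialwiseFirstChoice:
    trials: np.ndarray
    d_minus_b: np.ndarray
    c_minus_b: np.ndarray
    d_minus_c: np.ndarray
    ci_half: dict[str, np.ndarray]
    n: np.ndarray
    first_dc_significant_trial: int | None


@dataclass
class DistractorAnalysis:
    proportions: dict[int, np.ndarray]   # context -> per-position proportion
    n: dict[int, np.ndarray]
    tests: list[TestResult]              # per position, context 1 vs 2
    flagged_positions: list[int]


def _pre_criterion_trials(block: BlockLog, context: int) -> set[int]:
    crit = block_criterion(block, context)
    if crit.censored:
        return set(range(1, MAX_TRIALS_PER_CONTEXT + 1))
    return set(range(1, crit.criterion_trial))


def iter_transitions(block: BlockLog, event: str, context: int = 2,
                     pre_criterion: bool = True,
                     trials=None):
    """Yield the label of the next free search choice after each
    conditioning event. Retouch records between the trigger and the next
    search choice are skipped."""
    if event not in EVENTS:
        raise SeqswapError(f"event must be one of {EVENTS}")
    trigger, must_be_correct, position = _EVENT_SPEC[event]
    if trials is None:
        trials = (_pre_criterion_trials(block, context) if pre_criterion
                  else set(range(1, MAX_TRIALS_PER_CONTEXT + 1)))
    else:
        trials = set(trials)
    for trial, recs in block.trials(context).items():
        if trial not in trials:
            continue
        for i, rec in enumerate(recs):
            if (rec.phase != "search" or rec.chosen_label != trigger
                    or rec.is_correct != must_be_correct
                    or rec.ordinal_target != position):
                continue
            nxt = next((r for r in recs[i + 1:] if r.phase == "search"),
                       None)
            if nxt is not None:
                yield nxt.chosen_label


def transition_after(blocks: list[BlockLog], event: str, context: int = 2,
                     pre_criterion: bool = True,
                     trials=None) -> TransitionTable:
    """Next-choice probability table conditioned on an event.

    Default scope: context-2 trials strictly before each block's own
    learning criterion (blocks that never reach criterion contribute all
    their trials).
    """
    counts = np.zeros(len(LABELS))
    for block in blocks:
        for label in iter_transitions(block, event, context, pre_criterion,
                                      trials):
            counts[LABELS.index(label)] += 1
    n = int(counts.sum())
    if n == 0:
        return TransitionTable(event=event, labels=LABELS, counts=counts,
                               probabilities=np.full(len(LABELS), np.nan),
                               ci_low=np.full(len(LABELS), np.nan),
                               ci_high=np.full(len(LABELS), np.nan),
                               n_events=0)
    probs = counts / n
    ci_low = np.empty(len(LABELS))
    ci_high = np.empty(len(LABELS))
    for k, c in enumerate(counts):
        method = "wilson" if c < 5 else "normal"
        lo, hi = proportion_confint(int(c), n, alpha=0.05, method=method)
        ci_low[k], ci_high[k] = lo, hi
    return TransitionTable(event=event, labels=LABELS, counts=counts,
                           probabilities=probs, ci_low=ci_low,
                           ci_high=ci_high, n_events=n)


def swap_indices(blocks: list[BlockLog], context: int = 2,
                 pre_criterion: bool = True, trials=None) -> SwapIndices:
    """Pooled pro-active, retro-active, and serial-contrast indices."""
    after_a = transition_after(blocks, "after_correct_A", context,
                               pre_criterion, trials)
    after_b = transition_after(blocks, "after_error_B", context,
                               pre_criterion, trials)
    proactive = serial = math.nan
    retroactive = math.nan
    if not after_a.empty:
        proactive = after_a.probability("D") - after_a.probability("B")
        serial = after_a.probability("D") - after_a.probability("C")
    if not after_b.empty:
        retroactive = after_b.probability("D") - after_b.probability("C")
    return SwapIndices(proactive=proactive, retroactive=retroactive,
                       serial_contrast=serial,
                       n_proactive_events=after_a.n_events,
                       n_retroactive_events=after_b.n_events)


def per_block_swap_indices(blocks: list[BlockLog], context: int = 2,
                           pre_criterion: bool = True) -> dict[str,
                                                               SwapIndices]:
    return {b.block_id: swap_indices([b], context, pre_criterion)
            for b in blocks}


def _first_choice_label(recs) -> str | None:
    """Second touch of a trial whose first touch was a correct A."""
    if len(recs) < 2:
        return None
    first, second = recs[0], recs[1]
    if (first.phase == "search" and first.is_correct
            and first.chosen_label == "A" and second.phase == "search"):
        return second.chosen_label
    return None


def first_choice_analysis(blocks: list[BlockLog],
                          labels: tuple[str, ...] = ("B", "C", "D", "E", "X")
                          ) -> FirstChoiceResult:
    """Feedback-free probe of re-indexing: the first choice at the second
    position in the *first* trial of context 2, against the same choice in
    the *last* trial of context 1.

    Per-label Welch tests across blocks are adjusted with the
    Benjamini-Hochberg step-up procedure.
    """
    ind1: list[np.ndarray] = []
    ind2: list[np.ndarray] = []
    excluded = 0
    for block in blocks:
        t1 = block.trials(1)
        t2 = block.trials(2)
        if not t1 or not t2:
            excluded += 1
            continue
        lab1 = _first_choice_label(t1[max(t1)])
        lab2 = _first_choice_label(t2[min(t2)])
        if lab1 is None or lab2 is None:
            excluded += 1
            continue
        ind1.append(np.array([lab1 == lab for lab in labels], float))
        ind2.append(np.array([lab2 == lab for lab in labels], float))
    if not ind1:
        raise SeqswapError("no blocks with a correct leading A on the "
                           "required trials")
    m1 = np.vstack(ind1)
    m2 = np.vstack(ind2)
    p1 = m1.mean(axis=0)
    p2 = m2.mean(axis=0)
    raw: list[TestResult] = []
    for k in range(len(labels)):
        raw.append(welch_t(m2[:, k], m1[:, k]))
    pvals = [t.p if math.isfinite(t.p) else 1.0 for t in raw]
    adjusted = adjust_p(pvals, method="bh_fdr")
    tests = {}
    for lab, t, adj in zip(labels, raw, adjusted):
        t.adjusted_p = float(adj)
        t.adjustment = "bh_fdr"
        tests[lab] = t
    return FirstChoiceResult(labels=labels, p_context1=p1, p_context2=p2,
                             difference=p2 - p1, tests=tests,
                             n_blocks=len(ind1), n_excluded=excluded)


def trialwise_first_choice(blocks: list[BlockLog]) -> TrialwiseFirstChoice:
    """D-B, C-B and D-C first-choice difference curves across the 15
    context-2 trials, with the first trial whose D-C confidence interval
    excludes zero."""
    if not blocks:
        raise SeqswapError("no blocks given")
    per_trial: dict[int, list[tuple[float, float, float]]] = {
        t: [] for t in range(1, MAX_TRIALS_PER_CONTEXT + 1)}
    for block in blocks:
        for trial, recs in block.trials(2).items():
            lab = _first_choice_label(recs)
            if lab is not None:
                per_trial[trial].append((float(lab == "D"),
                                         float(lab == "B"),
                                         float(lab == "C")))
    n_trials = MAX_TRIALS_PER_CONTEXT
    curves = {k: np.full(n_trials, np.nan) for k in ("d_b", "c_b", "d_c")}
    half = {k: np.full(n_trials, np.nan) for k in ("d_b", "c_b", "d_c")}
    n = np.zeros(n_trials, int)
    for t in range(1, n_trials + 1):
        rows = np.asarray(per_trial[t], float)
        if rows.size == 0:
            continue
        n[t - 1] = len(rows)
        d, b, c = rows[:, 0], rows[:, 1], rows[:, 2]
        for key, diff in (("d_b", d - b), ("c_b", c - b), ("d_c", d - c)):
            curves[key][t - 1] = diff.mean()
            if len(diff) > 1:
                half[key][t - 1] = 1.96 * diff.std(ddof=1) / \
                    math.sqrt(len(diff))
    first_sig = None
    for t in range(n_trials):
        lo = curves["d_c"][t] - half["d_c"][t]
        if np.isfinite(lo) and lo > 0:
            first_sig = t + 1
            break
    return TrialwiseFirstChoice(
        trials=np.arange(1, n_trials + 1), d_minus_b=curves["d_b"],
        c_minus_b=curves["c_b"], d_minus_c=curves["d_c"], ci_half=half,
        n=n, first_dc_significant_trial=first_sig)


def distractor_analysis(blocks: list[BlockLog]) -> DistractorAnalysis:
    """Distractor-choice proportion of first search attempts per ordinal
    position, compared between contexts with two-proportion Z-tests."""
    from .learning import _first_search_attempts
    all_trials = set(range(1, MAX_TRIALS_PER_CONTEXT + 1))
    hits = {ctx: np.zeros(N_POSITIONS) for ctx in (1, 2)}
    n = {ctx: np.zeros(N_POSITIONS) for ctx in (1, 2)}
    for block in blocks:
        for ctx in (1, 2):
            for pos, recs in _first_search_attempts(block, ctx,
                                                    all_trials).items():
                n[ctx][pos - 1] += len(recs)
                hits[ctx][pos - 1] += sum(r.chosen_label == "X"
                                          for r in recs)
    proportions = {}
    for ctx in (1, 2):
        with np.errstate(invalid="ignore"):
            proportions[ctx] = np.where(n[ctx] > 0,
                                        hits[ctx] / np.maximum(n[ctx], 1),
                                        np.nan)
    tests = []
    flagged = []
    for pos in range(N_POSITIONS):
        if n[1][pos] == 0 or n[2][pos] == 0:
            flagged.append(pos + 1)
            tests.append(TestResult(statistic=math.nan, df=None, p=math.nan,
                                    note="zero denominator"))
            continue
        tests.append(two_proportion_z(int(hits[1][pos]), int(n[1][pos]),
                                      int(hits[2][pos]), int(n[2][pos])))
    return DistractorAnalysis(proportions=proportions,
                              n={c: v.astype(int) for c, v in n.items()},
                              tests=tests, flagged_positions=flagged)


def welch_t(sample_a, sample_b) -> TestResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite df."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        return TestResult(statistic=math.nan, df=None, p=math.nan,
                          note="need n >= 2 per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return TestResult(statistic=0.0 if p == 1.0 else math.inf, df=None,
                          p=p, note="zero variance in both samples")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p))


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-proportion Z-test with pooled variance."""
    if n1 <= 0 or n2 <= 0:
        raise SeqswapError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom == 0:
        return TestResult(statistic=0.0, df=None, p=1.0,
                          note="degenerate pooled proportion")
    z = (p1 - p2) / math.sqrt(denom)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), df=None, p=float(p))


def adjust_p(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (``min(1, m*p)``) or Benjamini-Hochberg step-up adjusted
    p-values, in the input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise SeqswapError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh_fdr":
        return multipletests(p, method="fdr_bh")[1]
    raise SeqswapError("method must be 'bonferroni' or 'bh_fdr'")


def simple_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R^2, the F-test p-value and
    Cohen's f^2 = R^2 / (1 - R^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise SeqswapError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise SeqswapError("x is constant; slope undefined")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue ** 2)
    f2 = r2 / (1.0 - r2) if r2 < 1.0 else math.inf
    return RegressionResult(beta=float(fit.slope),
                            intercept=float(fit.intercept), r_squared=r2,
                            p=float(fit.pvalue), cohens_f2=f2, n=x.size)
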