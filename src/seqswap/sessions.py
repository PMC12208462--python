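"""Memory-, experience- and working-memory-level analyses across blocks and
sessions, plus the consolidated report.

These analyses relate swapping behavior to three memory systems: long-term
sequence memory (new-early vs repeat vs new-late block comparisons and the
proficiency regressions), rule experience (across-session trends of the
swap indices), and working memory (session-level correlation of DMTS
accuracy with pro-active swapping).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .learning import block_criterion
from .swap import (RegressionResult, TestResult, adjust_p,
                   simple_regression, swap_indices, welch_t)
from .types import CONDITIONS, BlockLog, SeqswapError, SessionLog

logger = logging.getLogger("seqswap")

#: Context-2 trial window for per-block and per-session swap indices. A
#: fixed early window is used instead of the pre-criterion filter: blocks
#: that re-index immediately reach criterion on trial 1 and would otherwise
#: contribute no trials at all, selectively discarding the strongest
#: swappers from block-level regressions.
EARLY_TRIALS = range(1, 4)


@dataclass
class ConditionSummary:
    condition: str
    mean_criterion: float
    ci_criterion: tuple[float, float]
    n_criterion: int          # blocks reaching criterion
    n_censored: int
    mean_proactive: float
    ci_proactive: tuple[float, float]
    mean_retroactive: float
    ci_retroactive: tuple[float, float]
    n_blocks: int


@dataclass
class ConditionComparison:
    summaries: dict[str, ConditionSummary]
    criterion_tests: dict[tuple[str, str], TestResult]
    proactive_tests: dict[tuple[str, str], TestResult]
    retroactive_tests: dict[tuple[str, str], TestResult]
    skipped_conditions: list[str]


@dataclass
class SessionTrend:
    session_indices: np.ndarray
    values: np.ndarray
    one_sample_t: TestResult
    regression: RegressionResult


def _mean_ci(values) -> tuple[float, tuple[float, float]]:
    v = np.asarray([x for x in values if np.isfinite(x)], float)
    if v.size == 0:
        return math.nan, (math.nan, math.nan)
    mean = float(v.mean())
    if v.size < 2:
        return mean, (math.nan, math.nan)
    half = 1.96 * float(v.std(ddof=1)) / math.sqrt(v.size)
    return mean, (mean - half, mean + half)


def _criterion_trials(blocks: list[BlockLog],
                      context: int) -> tuple[list[float], int]:
    reached, censored = [], 0
    for block in blocks:
        crit = block_criterion(block, context)
        if crit.censored:
            censored += 1
        else:
            reached.append(float(crit.criterion_trial))
    return reached, censored


def _block_indices(blocks: list[BlockLog]) -> tuple[list[float],
                                                    list[float]]:
    pro, retro = [], []
    for block in blocks:
        idx = swap_indices([block], trials=EARLY_TRIALS)
        pro.append(idx.proactive)
        retro.append(idx.retroactive)
    return pro, retro


def compare_conditions(blocks: list[BlockLog],
                       context: int = 1) -> ConditionComparison:
    """New-early / new-late / repeat comparison of learning speed and swap
    indices, with Bonferroni-adjusted pairwise Welch tests.

    Criterion trials are measured in ``context`` (context 1 by default);
    swap indices always refer to context 2 of the same blocks.
    """
    by_condition = {c: [b for b in blocks if b.condition == c]
                    for c in CONDITIONS}
    present = [c for c in CONDITIONS if by_condition[c]]
    skipped = [c for c in CONDITIONS if not by_condition[c]]
    if len(present) < 2:
        raise SeqswapError("need at least 2 conditions present")
    if skipped:
        logger.info("compare_conditions: condition(s) absent: %s", skipped)

    summaries: dict[str, ConditionSummary] = {}
    crit_samples: dict[str, list[float]] = {}
    pro_samples: dict[str, list[float]] = {}
    retro_samples: dict[str, list[float]] = {}
    for cond in present:
        blist = by_condition[cond]
        reached, censored = _criterion_trials(blist, context)
        pro, retro = _block_indices(blist)
        crit_samples[cond] = reached
        pro_samples[cond] = [v for v in pro if np.isfinite(v)]
        retro_samples[cond] = [v for v in retro if np.isfinite(v)]
        mc, cic = _mean_ci(reached)
        mp, cip = _mean_ci(pro)
        mr, cir = _mean_ci(retro)
        summaries[cond] = ConditionSummary(
            condition=cond, mean_criterion=mc, ci_criterion=cic,
            n_criterion=len(reached), n_censored=censored,
            mean_proactive=mp, ci_proactive=cip, mean_retroactive=mr,
            ci_retroactive=cir, n_blocks=len(blist))

    pairs = [(a, b) for i, a in enumerate(present)
             for b in present[i + 1:]]

    def pairwise(samples: dict[str, list[float]]
                 ) -> dict[tuple[str, str], TestResult]:
        raw = {pair: welch_t(samples[pair[0]], samples[pair[1]])
               for pair in pairs}
        pvals = [t.p if math.isfinite(t.p) else 1.0 for t in raw.values()]
        adj = adjust_p(pvals, method="bonferroni")
        for t, a in zip(raw.values(), adj):
            t.adjusted_p = float(a)
            t.adjustment = "bonferroni"
        return raw

    return ConditionComparison(
        summaries=summaries,
        criterion_tests=pairwise(crit_samples),
        proactive_tests=pairwise(pro_samples),
        retroactive_tests=pairwise(retro_samples),
        skipped_conditions=skipped)


def proficiency_vs_swap(blocks: list[BlockLog]) -> dict:
    """OLS of each swap index on the block's context-1 completion rate,
    plus a good-versus-poor tercile Welch contrast."""
    rates, pro, retro = [], [], []
    excluded = 0
    for block in blocks:
        flags = block.completion_flags(1)
        if not flags:
            excluded += 1
            continue
        idx = swap_indices([block], trials=EARLY_TRIALS)
        rates.append(float(np.mean(flags)))
        pro.append(idx.proactive)
        retro.append(idx.retroactive)
    rates = np.asarray(rates)
    out: dict = {"n_excluded_blocks": excluded}
    for name, values in (("proactive", np.asarray(pro)),
                         ("retroactive", np.asarray(retro))):
        mask = np.isfinite(values)
        if mask.sum() >= 3 and np.ptp(rates[mask]) > 0:
            out[f"regression_{name}"] = simple_regression(rates[mask],
                                                          values[mask])
        else:
            out[f"regression_{name}"] = None
        # tercile contrast on completion rate
        if mask.sum() >= 6:
            r, v = rates[mask], values[mask]
            lo_cut, hi_cut = np.quantile(r, [1 / 3, 2 / 3])
            good = v[r >= hi_cut]
            poor = v[r <= lo_cut]
            out[f"tercile_{name}"] = welch_t(good, poor)
        else:
            out[f"tercile_{name}"] = None
        logger.info("proficiency_vs_swap: %s on %d blocks", name,
                    int(mask.sum()))
    return out


def across_session_trend(sessions: list[SessionLog],
                         index: str = "proactive") -> SessionTrend:
    """Session-level swap index: one-sample t against zero and a
    regression over session number."""
    if index not in ("proactive", "retroactive"):
        raise SeqswapError("index must be 'proactive' or 'retroactive'")
    xs, ys = [], []
    for session in sorted(sessions, key=lambda s: s.session_index):
        value = getattr(swap_indices(session.blocks, trials=EARLY_TRIALS),
                        index)
        if np.isfinite(value):
            xs.append(session.session_index)
            ys.append(value)
    if len(ys) < 3:
        raise SeqswapError("need >= 3 sessions with a defined index")
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if np.allclose(ys.var(), 0.0):
        one = TestResult(statistic=math.inf if ys.mean() != 0 else 0.0,
                         df=float(len(ys) - 1),
                         p=0.0 if ys.mean() != 0 else 1.0,
                         note="constant index")
    else:
        t, p = stats.ttest_1samp(ys, 0.0)
        one = TestResult(statistic=float(t), df=float(len(ys) - 1),
                         p=float(p))
    regression = simple_regression(xs, ys)
    return SessionTrend(session_indices=xs, values=ys, one_sample_t=one,
                        regression=regression)


def dmts_correlation(sessions: list[SessionLog]) -> dict:
    """Pooled and per-subject regression of the pro-active swap index on
    session-level DMTS accuracy, with a random-intercept mixed-model slope
    from statsmodels reported alongside."""
    rows = []
    for session in sessions:
        acc = session.dmts_accuracy
        if acc is None:
            continue
        value = swap_indices(session.blocks, trials=EARLY_TRIALS).proactive
        if np.isfinite(value):
            rows.append((session.subject_id, acc, value))
    if len(rows) < 3:
        raise SeqswapError("need >= 3 sessions with DMTS accuracy and a "
                           "defined proactive index")
    subjects = np.array([r[0] for r in rows])
    x = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    out: dict = {"pooled": simple_regression(x, y), "per_subject": {},
                 "mixed_model": None}
    for subject in sorted(set(subjects)):
        mask = subjects == subject
        if mask.sum() >= 3 and np.ptp(x[mask]) > 0:
            out["per_subject"][subject] = simple_regression(x[mask],
                                                            y[mask])
        else:
            logger.info("dmts_correlation: subject %s excluded from "
                        "per-subject fits (n=%d)", subject, mask.sum())
    if len(set(subjects)) >= 2:
        try:
            import statsmodels.formula.api as smf
            import pandas as pd
            frame = pd.DataFrame({"subject": subjects, "dmts": x,
                                  "proactive": y})
            fit = smf.mixedlm("proactive ~ dmts", frame,
                              groups=frame["subject"]).fit(reml=True)
            out["mixed_model"] = {"beta": float(fit.params["dmts"]),
                                  "p": float(fit.pvalues["dmts"])}
        except Exception as exc:  # singular fits on degenerate inputs
            logger.warning("mixed model fit failed: %s", exc)
    return out


def context_effects(blocks: list[BlockLog]) -> dict:
    """Same- versus different-background contrasts for repeated sequences.

    Completion gain is the repeat block's context-1 completion rate minus
    that of the early block it re-presents (paired through the ``<id>.r``
    block-id convention).
    """
    early = {b.block_id: b for b in blocks if b.condition != "repeat"}
    gains = {True: [], False: []}
    pro = {True: [], False: []}
    retro = {True: [], False: []}
    n_pairs = 0
    for block in blocks:
        if block.condition != "repeat" or block.background_same is None:
            continue
        source = early.get(block.block_id.removesuffix(".r"))
        same = block.background_same
        idx = swap_indices([block], trials=EARLY_TRIALS)
        if np.isfinite(idx.proactive):
            pro[same].append(idx.proactive)
        if np.isfinite(idx.retroactive):
            retro[same].append(idx.retroactive)
        if source is not None:
            gain = (np.mean(block.completion_flags(1))
                    - np.mean(source.completion_flags(1)))
            gains[same].append(float(gain))
            n_pairs += 1
    if not gains[True] and not gains[False]:
        logger.info("context_effects: no repeat blocks; skipped")
        return {"skipped": True}

    def contrast(samples) -> dict:
        m_same, ci_same = _mean_ci(samples[True])
        m_diff, ci_diff = _mean_ci(samples[False])
        return {"mean_same": m_same, "ci_same": ci_same,
                "mean_different": m_diff, "ci_different": ci_diff,
                "welch": welch_t(samples[True], samples[False])}

    return {"skipped": False, "n_pairs": n_pairs,
            "completion_gain": contrast(gains),
            "proactive": contrast(pro),
            "retroactive": contrast(retro)}


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def build_report(results: dict, out_dir: str | os.PathLike,
                 config: dict | None = None,
                 seed: int | None = None) -> dict[str, str]:
    """Write a consolidated JSON + markdown report.

    The report contains only provenance (config, seed, library versions)
    and the supplied result objects; runs with the same seed and inputs
    produce identical files.
    """
    import pandas
    import scipy

    os.makedirs(out_dir, exist_ok=True)
    provenance = {
        "package": "seqswap",
        "seed": seed,
        "config": config,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pandas.__version__},
    }
    payload = {"provenance": provenance,
               "results": _jsonable(results)}
    json_path = os.path.join(out_dir, "report.json")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    lines = ["# seqswap analysis report", ""]
    lines.append(f"Seed: {seed}")
    lines.append("")
    for section in sorted(results):
        lines.append(f"## {section}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(_jsonable(results[section]), indent=2,
                                sort_keys=True))
        lines.append("```")
        lines.append("")
    md_path = os.path.join(out_dir, "report.md")
    with open(md_path, "w") as fh:
        fh.write("\n".join(lines))
    return {"json": json_path, "markdown": md_path}
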