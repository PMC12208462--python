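"""Transition tables, swap indices, first-choice analyses and the
inferential-statistics utilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from seqswap import (AgentParams, GeneratorConfig, SeqswapError, adjust_p,
                     distractor_analysis, first_choice_analysis,
                     simple_regression, simulate_block, swap_indices,
                     transition_after, trialwise_first_choice,
                     two_proportion_z, welch_t)
from seqswap.swap import iter_transitions

from conftest import PERFECT_C1, PERFECT_C2, build_block


def ten_event_block():
    """10 post-A transitions: 4 D, 3 C, 2 E, 1 X (context 2)."""
    targets = ["D"] * 4 + ["C"] * 3 + ["E"] * 2 + ["X"]
    trials = [["A", t] for t in targets]
    return build_block({2: trials})


def test_transition_all_d():
    block = build_block({2: [["A", "D"]] * 5})
    table = transition_after([block], "after_correct_A")
    assert table.probability("D") == 1.0
    assert table.n_events == 5
    assert sum(table.probabilities) == pytest.approx(1.0)


def test_transition_hand_counts():
    table = transition_after([ten_event_block()], "after_correct_A")
    assert table.n_events == 10
    assert table.probability("D") == pytest.approx(0.4)
    assert table.probability("C") == pytest.approx(0.3)
    assert table.probability("E") == pytest.approx(0.2)
    assert table.probability("X") == pytest.approx(0.1)


def test_transition_skips_forced_retouch():
    """After an error on B the retouch of A is never the counted target."""
    # A correct, B error (retouch auto-inserted), then D
    block = build_block({2: [["A", "B", "D"]]})
    table = transition_after([block], "after_error_B")
    assert table.n_events == 1
    assert table.probability("D") == 1.0
    assert table.probability("A") == 0.0


def test_transition_empty_flagged():
    block = build_block({1: [PERFECT_C1]})
    table = transition_after([block], "after_error_B")
    assert table.empty
    assert np.isnan(table.probabilities).all()


def test_transition_counts_match_bruteforce(default_blocks):
    """Table counts equal a naive recount of conditioning events."""
    blocks = default_blocks[:40]
    for event, trigger, correct, pos in [
            ("after_correct_A", "A", True, 1),
            ("after_error_B", "B", False, 2),
            ("after_correct_D", "D", True, 2)]:
        table = transition_after(blocks, event, pre_criterion=False)
        naive = {}
        for block in blocks:
            for trial, recs in block.trials(2).items():
                for i, rec in enumerate(recs):
                    if (rec.phase == "search"
                            and rec.chosen_label == trigger
                            and rec.is_correct == correct
                            and rec.ordinal_target == pos):
                        nxt = [r for r in recs[i + 1:]
                               if r.phase == "search"]
                        if nxt:
                            lab = nxt[0].chosen_label
                            naive[lab] = naive.get(lab, 0) + 1
        for k, lab in enumerate(table.labels):
            assert table.counts[k] == naive.get(lab, 0)


def test_swap_indices_arithmetic():
    """Indices equal direct differences of the table entries."""
    block = ten_event_block()
    table = transition_after([block], "after_correct_A")
    idx = swap_indices([block])
    assert idx.proactive == pytest.approx(
        table.probability("D") - table.probability("B"))
    assert idx.serial_contrast == pytest.approx(
        table.probability("D") - table.probability("C"))


def test_retroactive_from_printed_probabilities():
    """The published post-error-B probabilities give a 0.094 retro index."""
    assert 0.450 - 0.356 == pytest.approx(0.094)
    # and the implementation computes the same difference from counts
    trials = [["A", "B", "D"]] * 450 + [["A", "B", "C"]] * 356 \
        + [["A", "B", "E"]] * 194
    # split across blocks to stay within the 15-trial-per-context limit
    blocks = [build_block({2: [t]}, block_id=f"b{i:04d}")
              for i, t in enumerate(trials)]
    idx = swap_indices(blocks)
    assert idx.retroactive == pytest.approx((450 - 356) / 1000)


def test_serial_agent_has_negative_serial_contrast():
    """A pure serial-chaining agent prefers C over D after a correct A."""
    agent = AgentParams(w_position=0.0, w_serial=1.0, error_reindex_rate=0.0,
                        seed=11)
    rng = np.random.default_rng(11)
    blocks = [simulate_block(agent, GeneratorConfig(rt_lognorm=None), rng,
                             block_id=f"b{i}") for i in range(150)]
    idx = swap_indices(blocks, trials=range(1, 4))
    assert idx.serial_contrast < 0


def test_position_agent_retroactive_positive():
    """A pure re-indexing agent chooses D over C after an error on B."""
    agent = AgentParams(w_position=1.0, w_serial=0.0, seed=12)
    rng = np.random.default_rng(12)
    blocks = [simulate_block(agent, GeneratorConfig(rt_lognorm=None), rng,
                             block_id=f"b{i}") for i in range(200)]
    table = transition_after(blocks, "after_error_B", pre_criterion=False)
    assert table.n_events > 30
    assert table.probability("D") > table.probability("C")


def test_first_choice_hand_built():
    b1 = build_block({1: [PERFECT_C1] * 2, 2: [["A", "D"] + ["C", "B", "E"]]},
                     block_id="b01")
    b2 = build_block({1: [PERFECT_C1], 2: [["A", "C"]]}, block_id="b02")
    result = first_choice_analysis([b1, b2])
    # context 1 last trials: both chose B (the correct object) second
    assert result.p_context1[result.labels.index("B")] == 1.0
    # context 2 first trials: one D, one C
    assert result.p_context2[result.labels.index("D")] == 0.5
    assert result.p_context2[result.labels.index("C")] == 0.5
    assert result.n_blocks == 2


def _null_first_choice_blocks(n_blocks, rng, n_ctx2_trials=1):
    """Blocks whose context-1 last-trial and context-2 first choices are
    drawn from one shared uniform distribution (a no-change null)."""
    labels = ["B", "C", "D", "E", "X"]
    blocks = []
    for i in range(n_blocks):
        ctx1 = [[ "A", labels[rng.integers(5)] ]]
        ctx2 = [["A", labels[rng.integers(5)]]
                for _ in range(n_ctx2_trials)]
        blocks.append(build_block({1: ctx1, 2: ctx2},
                                  block_id=f"n{i:04d}"))
    return blocks


def test_first_choice_null_difference_small():
    """When both contexts draw first choices from the same distribution the
    difference vector vanishes within binomial error."""
    rng = np.random.default_rng(13)
    blocks = _null_first_choice_blocks(500, rng)
    result = first_choice_analysis(blocks)
    n = result.n_blocks
    bound = 3 * math.sqrt(2 * 0.2 * 0.8 / n)
    assert np.all(np.abs(result.difference) < bound)


def test_first_choice_position_agent_prefers_d():
    agent = AgentParams(w_position=1.0, w_serial=0.0, seed=14)
    rng = np.random.default_rng(14)
    blocks = [simulate_block(agent, GeneratorConfig(rt_lognorm=None), rng,
                             block_id=f"b{i}") for i in range(150)]
    result = first_choice_analysis(blocks)
    d = result.labels.index("D")
    b = result.labels.index("B")
    assert result.difference[d] - result.difference[b] > 0.3


def test_trialwise_first_choice_hand_built():
    trials = [["A", "D"], ["A", "C"], ["A", "D"]]
    block = build_block({2: trials})
    result = trialwise_first_choice([block])
    assert result.d_minus_c[0] == 1.0
    assert result.d_minus_c[1] == -1.0
    assert result.d_minus_b[2] == 1.0
    assert result.n[:3].tolist() == [1, 1, 1]


def test_trialwise_symmetric_choices_flat():
    """Equiprobable labels leave all three difference curves near zero."""
    rng = np.random.default_rng(15)
    blocks = _null_first_choice_blocks(300, rng, n_ctx2_trials=15)
    result = trialwise_first_choice(blocks)
    assert abs(np.nanmean(result.d_minus_c)) < 0.03
    excluding_zero = 0
    for t in range(15):
        lo = result.d_minus_c[t] - result.ci_half["d_c"][t]
        hi = result.d_minus_c[t] + result.ci_half["d_c"][t]
        if np.isfinite(lo) and (lo > 0 or hi < 0):
            excluding_zero += 1
    assert excluding_zero <= 2


def test_distractor_z_matches_hand_formula():
    res = two_proportion_z(30, 100, 20, 100)
    pooled = 50 / 200
    expected = (0.3 - 0.2) / math.sqrt(pooled * (1 - pooled) * (2 / 100))
    assert res.statistic == pytest.approx(expected)
    assert two_proportion_z(10, 50, 10, 50).statistic == 0.0


def test_distractor_peaks_at_confusable_positions(default_blocks):
    """X shares features with B: context 1 peaks at position 2, context 2
    at position 4."""
    analysis = distractor_analysis(default_blocks)
    p1, p2 = analysis.proportions[1], analysis.proportions[2]
    assert p1[1] > p1[0] and p1[1] > p1[2]   # position 2 local peak
    assert np.argmax(p2) == 3                # position 4 overall peak


def test_welch_identical_samples():
    res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1.0)


def test_welch_matches_hand_formulas():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
    res = welch_t(a, b)
    sa, sb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / 2 + sb ** 2 / 2)
    assert res.statistic == pytest.approx(t)
    assert res.df == pytest.approx(df)
    t_sp, p_sp = stats.ttest_ind(a, b, equal_var=False)
    assert res.statistic == pytest.approx(t_sp)
    assert res.p == pytest.approx(p_sp)


def test_welch_large_n_equal_variance_limit():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 5000)
    b = rng.normal(0.05, 1, 5000)
    res = welch_t(a, b)
    t_student, p_student = stats.ttest_ind(a, b, equal_var=True)
    assert res.p == pytest.approx(p_student, abs=1e-6)


def test_welch_degenerate_flagged():
    assert math.isnan(welch_t([1.0], [2.0, 3.0]).p)
    res = welch_t([2.0, 2.0], [2.0, 2.0])
    assert res.p == 1.0


@pytest.mark.parametrize("method,expected", [
    ("bonferroni", [0.03, 0.06, 0.09]),
    ("bh_fdr", [0.03, 0.03, 0.03]),
])
def test_adjust_p_formulas(method, expected):
    out = adjust_p([0.01, 0.02, 0.03], method=method)
    assert np.allclose(out, expected)


def test_adjust_p_single_and_bounds():
    assert adjust_p([0.04]).tolist() == [0.04]
    with pytest.raises(SeqswapError):
        adjust_p([1.2])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
def test_adjust_p_ordering_properties(pvals):
    bonf = adjust_p(pvals, "bonferroni")
    bh = adjust_p(pvals, "bh_fdr")
    assert np.all(bonf >= np.asarray(pvals) - 1e-12)
    assert np.all(bonf >= bh - 1e-12)       # Bonferroni >= BH everywhere
    assert np.all(bh >= min(pvals) - 1e-12)


def test_regression_exact_line():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = simple_regression(x, 2 * x + 1)
    assert res.beta == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)


def test_regression_f2_consistency():
    """The published R^2 of 0.0214 implies Cohen's f^2 of 0.0219."""
    r2 = 0.0214
    assert r2 / (1 - r2) == pytest.approx(0.0219, abs=5e-4)
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = 0.1 * x + rng.normal(size=200)
    res = simple_regression(x, y)
    assert res.cohens_f2 == pytest.approx(
        res.r_squared / (1 - res.r_squared))


def test_regression_null_pvalues_uniform():
    """Under independence the regression p-values are uniform."""
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(1000):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        pvals.append(simple_regression(x, y).p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_regression_constant_x_rejected():
    with pytest.raises(SeqswapError):
        simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
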