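"""Memory, experience, context and working-memory analyses."""

import json

import numpy as np
import pytest

from seqswap import (AgentParams, GeneratorConfig, SeqswapError,
                     across_session_trend, agent_from_wm, build_report,
                     compare_conditions, context_effects, dmts_correlation,
                     proficiency_vs_swap, simulate_session,
                     simulate_sessions)
from seqswap.learning import block_criterion

from conftest import PERFECT_C1, PERFECT_C2, build_block


def criterion_block(block_id, condition, n_fail, background_same=None):
    """Block failing its first ``n_fail`` context-1 trials, then perfect."""
    trials1 = [["X"]] * n_fail + [PERFECT_C1] * (15 - n_fail)
    trials2 = [PERFECT_C2] * 15
    return build_block({1: trials1, 2: trials2}, block_id=block_id,
                       condition=condition, background_same=background_same)


def test_compare_conditions_exact_means():
    blocks = [criterion_block("b01", "new_early", 4),
              criterion_block("b02", "new_early", 2),
              criterion_block("b03", "repeat", 0, background_same=True),
              criterion_block("b04", "new_late", 1)]
    result = compare_conditions(blocks)
    assert result.summaries["new_early"].mean_criterion == pytest.approx(4.0)
    assert result.summaries["repeat"].mean_criterion == pytest.approx(1.0)
    assert result.summaries["new_late"].mean_criterion == pytest.approx(2.0)
    assert set(result.criterion_tests) == {("new_early", "new_late"),
                                           ("new_early", "repeat"),
                                           ("new_late", "repeat")}


def test_compare_conditions_identical_behavior_null():
    blocks = [criterion_block(f"b{i:02d}", cond, 2)
              for i, cond in enumerate(["new_early"] * 5 + ["new_late"] * 5)]
    result = compare_conditions(blocks)
    test = result.criterion_tests[("new_early", "new_late")]
    assert test.p == pytest.approx(1.0)


def test_retention_speeds_repeats():
    """With full retention, repeats reach criterion no later than their
    early counterparts (median over sessions)."""
    cfg = GeneratorConfig(retention_factor=1.0, background_bonus=0.0,
                          rt_lognorm=None)
    agent = AgentParams(seed=21)
    diffs = []
    for session in simulate_sessions(agent,
                                     cfg.__class__(**{**cfg.__dict__,
                                                      "n_sessions": 60})):
        repeat = [b for b in session.blocks if b.condition == "repeat"]
        late = [b for b in session.blocks if b.condition == "new_late"]
        def crit(blocks):
            vals = [block_criterion(b, 1).criterion_trial or 16
                    for b in blocks]
            return np.mean(vals)
        if repeat and late:
            diffs.append(crit(repeat) - crit(late))
    assert np.median(diffs) < 0


def test_zero_retention_repeats_look_new():
    """With no retention, repeat and new-late criterion distributions are
    indistinguishable (rank-sum test)."""
    from scipy import stats
    cfg = GeneratorConfig(n_sessions=40, retention_factor=0.0,
                          background_bonus=0.0, rt_lognorm=None)
    agent = AgentParams(seed=22)
    repeat_crit, late_crit = [], []
    for session in simulate_sessions(agent, cfg):
        for block in session.blocks:
            value = block_criterion(block, 1).criterion_trial or 16
            if block.condition == "repeat":
                repeat_crit.append(value)
            elif block.condition == "new_late":
                late_crit.append(value)
    p = stats.ranksums(repeat_crit, late_crit).pvalue
    assert p > 0.05


def test_proficiency_vs_swap_recovers_coupling():
    """Coupling proficiency to w_position produces a positive slope."""
    from seqswap import simulate_block
    rng = np.random.default_rng(23)
    blocks = []
    for i in range(500):
        wp = float(rng.uniform(0.05, 0.95))
        agent = AgentParams(w_position=wp, w_serial=0.3 * (1 - wp),
                            learning_rate=0.03 + 0.4 * wp, seed=23)
        blocks.append(simulate_block(agent, GeneratorConfig(rt_lognorm=None),
                                     rng, block_id=f"b{i:03d}"))
    out = proficiency_vs_swap(blocks)
    reg = out["regression_proactive"]
    assert reg.beta > 0
    assert reg.p < 0.05
    tercile = out["tercile_proactive"]
    assert tercile.statistic > 0 and tercile.p < 0.05


def test_proficiency_vs_swap_null_slope_covers_zero():
    """Uncoupled generator: the slope is not systematically positive."""
    from seqswap import simulate_block
    rng = np.random.default_rng(24)
    blocks = [simulate_block(AgentParams(seed=24),
                             GeneratorConfig(rt_lognorm=None), rng,
                             block_id=f"b{i:03d}") for i in range(120)]
    out = proficiency_vs_swap(blocks)
    reg = out["regression_proactive"]
    # not a calibrated CI check at this n; the point estimate must simply
    # not show the strong coupling of the coupled test above
    assert reg.p > 1e-4 or abs(reg.beta) < 0.2


def test_perfect_linear_r2():
    blocks = []
    # construct blocks whose completion rate and proactive index are exact
    from conftest import build_trial
    from seqswap.types import BlockLog
    for i, (rate_fail, n_d) in enumerate([(0, 3), (3, 2), (6, 1)]):
        trials1 = [["X"]] * rate_fail + [PERFECT_C1] * (15 - rate_fail)
        trials2 = [["A", "D"]] * n_d + [["A", "C"]] * (3 - n_d)
        blocks.append(build_block({1: trials1, 2: trials2},
                                  block_id=f"b{i}"))
    out = proficiency_vs_swap(blocks)
    assert out["regression_proactive"].r_squared == pytest.approx(1.0,
                                                                  abs=1e-9)


def test_across_session_trend_constant_index():
    sessions = []
    for i in range(1, 7):
        block = build_block({2: [["A", "D"]] * 10}, block_id=f"b{i}")
        from seqswap.types import SessionLog
        block.session_index = i
        for r in block.records:
            r.session_index = i
        sessions.append(SessionLog(subject_id="s1", session_index=i,
                                   blocks=[block]))
    trend = across_session_trend(sessions)
    assert trend.one_sample_t.p < 0.05 or trend.one_sample_t.note
    assert abs(trend.regression.beta) < 1e-9


def test_across_session_trend_recovers_growth():
    """w_position rising across sessions yields a positive slope."""
    sessions = []
    cfg = GeneratorConfig(blocks_per_session=4, dmts_trials=10,
                          rt_lognorm=None)
    for i in range(40):
        wp = 0.1 + 0.8 * i / 39
        agent = AgentParams(w_position=wp, w_serial=0.3 * (1 - wp),
                            seed=30 + i)
        sessions.append(simulate_session(agent, cfg, session_index=i + 1))
    trend = across_session_trend(sessions)
    assert trend.regression.beta > 0
    assert trend.regression.p < 0.05


def test_dmts_correlation_recovers_wm_coupling():
    """wm_ability driving both DMTS accuracy and w_position produces a
    positive pooled slope."""
    rng = np.random.default_rng(31)
    cfg = GeneratorConfig(blocks_per_session=4, dmts_trials=60,
                          rt_lognorm=None)
    sessions = []
    for i in range(60):
        wm = float(rng.uniform(0.05, 0.95))
        agent = agent_from_wm(wm, seed=31 + i)
        sessions.append(simulate_session(agent, cfg, session_index=i + 1,
                                         subject_id=f"m{i % 3}"))
    out = dmts_correlation(sessions)
    assert out["pooled"].beta > 0
    assert out["pooled"].p < 0.05
    assert out["mixed_model"] is not None
    assert out["mixed_model"]["beta"] > 0


def test_dmts_correlation_constant_predictor_surfaces_cleanly():
    sessions = []
    from seqswap.types import DMTSRecord, SessionLog
    for i in range(1, 5):
        block = build_block({2: [["A", "D"]] * 8}, block_id=f"b{i}")
        block.session_index = i
        for r in block.records:
            r.session_index = i
        dmts = [DMTSRecord("low", 0.5, 3, True)] * 10
        sessions.append(SessionLog(subject_id="s1", session_index=i,
                                   blocks=[block], dmts=dmts))
    with pytest.raises(SeqswapError, match="constant"):
        dmts_correlation(sessions)


def test_context_effects_exact_contrast():
    blocks = [
        criterion_block("b01", "new_early", 5),
        criterion_block("b02", "new_early", 5),
        criterion_block("b01.r", "repeat", 1, background_same=True),
        criterion_block("b02.r", "repeat", 3, background_same=False),
    ]
    out = context_effects(blocks)
    assert not out["skipped"]
    assert out["n_pairs"] == 2
    assert out["completion_gain"]["mean_same"] == pytest.approx(4 / 15)
    assert out["completion_gain"]["mean_different"] == pytest.approx(2 / 15)


def test_context_effects_background_bonus_direction():
    """A same-background retention bonus yields larger completion gains for
    same-background repeats."""
    cfg = GeneratorConfig(n_sessions=50, retention_factor=0.9,
                          background_bonus=0.8, rt_lognorm=None)
    sessions = simulate_sessions(AgentParams(seed=33), cfg)
    blocks = [b for s in sessions for b in s.blocks]
    # pair repeats with their sources within each session
    same, diff = [], []
    for s in sessions:
        early = {b.block_id: b for b in s.blocks
                 if b.condition != "repeat"}
        for b in s.blocks:
            if b.condition != "repeat":
                continue
            src = early[b.block_id.removesuffix(".r")]
            gain = (np.mean(b.completion_flags(1))
                    - np.mean(src.completion_flags(1)))
            (same if b.background_same else diff).append(gain)
    assert np.mean(same) > np.mean(diff)


def test_build_report_deterministic_and_complete(tmp_path):
    sessions = simulate_sessions(AgentParams(seed=34),
                                 GeneratorConfig(n_sessions=1))
    blocks = sessions[0].blocks
    results = {"conditions": compare_conditions(blocks),
               "context": context_effects(blocks)}
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    p1 = build_report(results, d1, seed=34)
    p2 = build_report(results, d2, seed=34)
    j1 = (d1 / "report.json").read_bytes()
    j2 = (d2 / "report.json").read_bytes()
    assert j1 == j2
    payload = json.loads(j1)
    assert payload["provenance"]["seed"] == 34
    assert set(payload["results"]) == {"conditions", "context"}
    assert (d1 / "report.md").exists()


def test_build_report_empty_minimal(tmp_path):
    paths = build_report({}, tmp_path / "r", seed=1)
    payload = json.loads(open(paths["json"]).read())
    assert payload["results"] == {}
    assert "versions" in payload["provenance"]
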