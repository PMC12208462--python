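"""Synthetic choice-log generator.

The animal data behind the task are not public, so analyses are exercised on
logs produced by a parameterized agent whose behavior has the statistical
structure the analyses assume:

* In context 1 the agent learns value weights over (object, ordinal
  position) associations by reinforcement, choosing among the not-yet-
  secured objects through a softmax.
* At the context switch it draws, independently per trial, one of three
  strategies: *positional re-indexing* (probability ``w_position``; its
  context-1 weights are read out with objects B and D exchanged, so it
  pro-actively places D at position 2), *serial chaining* (``w_serial``; it
  reads out the weights of the serially next position, so it erroneously
  favors C at position 2), or unguided exploration (the remainder).
* The distractor X partially inherits the learned value of B (they share
  features), so distractor choices peak at whichever position B's value is
  highest - position 2 in context 1 and position 4 in context 2.
* Working-memory ability drives delayed match-to-sample accuracy and can be
  coupled to ``w_position`` through :func:`agent_from_wm`, reproducing the
  session-level correlation between DMTS accuracy and pro-active swapping.

Forced retouch choices are correct with probability ``1 - lapse_rate``:
rule-breaking is infrequent in trained animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import (CONTEXT_ORDERS, DISTRACTOR, DMTS_DELAYS, LABELS,
                    MAX_CHOICES_PER_TRIAL, MAX_ERRORS_PER_TRIAL,
                    MAX_TRIALS_PER_CONTEXT, N_OBJECTS, N_POSITIONS, BlockLog,
                    ChoiceRecord, DMTSRecord, SessionLog, ValidationError)

#: DMTS accuracy model: chance + (ceiling - chance) * wm * similarity factor.
#: The factors place a mid-ability (0.6) subject at 0.70 accuracy for low-
#: similarity and 0.47 for high-similarity probes.
DMTS_CEILING = 0.9444444444444444
SIMILARITY_FACTORS = {"low": 1.0, "high": 0.37272727272727274}

_IDX = {lab: i for i, lab in enumerate(LABELS)}
_SWAP_BD = {"A": "A", "B": "D", "C": "C", "D": "B", "E": "E", "X": "X"}


@dataclass
class AgentParams:
    """Generative parameters of one simulated subject.

    ``w_position`` and ``w_serial`` are the per-trial probabilities of the
    re-indexing and serial-chaining strategies in context 2 (their sum must
    not exceed 1; the remainder is exploration). ``wm_ability`` in [0, 1]
    scales delayed match-to-sample accuracy between chance and ceiling.
    """

    w_position: float = 0.45
    w_serial: float = 0.2
    learning_rate: float = 0.15
    softmax_temperature: float = 0.2
    lapse_rate: float = 0.08
    wm_ability: float = 0.6
    distractor_confusability: float = 0.5
    error_reindex_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_position <= 1.0:
            raise ValidationError("w_position must be in [0, 1]")
        if not 0.0 <= self.w_serial <= 1.0:
            raise ValidationError("w_serial must be in [0, 1]")
        if self.w_position + self.w_serial > 1.0 + 1e-12:
            raise ValidationError("w_position + w_serial must be <= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValidationError("learning_rate must be in (0, 1]")
        if self.softmax_temperature <= 0.0:
            raise ValidationError("softmax_temperature must be > 0")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValidationError("lapse_rate must be in [0, 1)")
        if not 0.0 <= self.wm_ability <= 1.0:
            raise ValidationError("wm_ability must be in [0, 1]")
        if not 0.0 <= self.distractor_confusability <= 1.0:
            raise ValidationError("distractor_confusability must be in [0, 1]")
        if not 0.0 <= self.error_reindex_rate <= 1.0:
            raise ValidationError("error_reindex_rate must be in [0, 1]")


def agent_from_wm(wm_ability: float, w_serial_share: float = 0.6,
                  **kwargs) -> AgentParams:
    """An agent whose re-indexing tendency is driven by working memory.

    The default coupling is linear: ``w_position = wm_ability``, with
    ``w_serial`` taking ``w_serial_share`` of the remaining probability
    mass. The coupling strength between working memory and swapping is not
    an empirically measured quantity; this linear form is the generator's
    modeling choice.
    """
    w_position = float(wm_ability)
    w_serial = w_serial_share * (1.0 - w_position)
    return AgentParams(w_position=w_position, w_serial=w_serial,
                       wm_ability=wm_ability, **kwargs)


@dataclass
class GeneratorConfig:
    """Session-skeleton parameters.

    Defaults reproduce the study's session layout: 10 sequence-pair blocks
    (half before and half after 120 interleaved DMTS trials), 15 trials per
    context, 6 on-screen objects, with half the late blocks repeating early
    sequence pairs, 62.5% of repeats on the same background.
    """

    n_sessions: int = 1
    blocks_per_session: int = 10
    trials_per_context: int = 15
    n_objects: int = 6
    repeat_fraction: float = 0.5
    background_same_fraction: float = 0.625
    dmts_trials: int = 120
    dmts_n_test: int = 3
    retention_factor: float = 0.8
    background_bonus: float = 0.2
    strategy_prior_weight: float = 1.0
    rt_lognorm: tuple[float, float] | None = (math.log(0.75), 0.35)
    theta_override: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_objects != N_OBJECTS:
            raise ValidationError(f"n_objects must be {N_OBJECTS}: the task "
                                  "uses 5 sequence objects plus 1 distractor")
        if not 1 <= self.trials_per_context <= MAX_TRIALS_PER_CONTEXT:
            raise ValidationError("trials_per_context outside 1..15")
        for name in ("repeat_fraction", "background_same_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.retention_factor <= 1.0:
            raise ValidationError("retention_factor must be in [0, 1]")
        if not 0.0 <= self.background_bonus <= 1.0:
            raise ValidationError("background_bonus must be in [0, 1]")
        if self.theta_override is not None:
            theta = np.asarray(self.theta_override, float)
            if theta.min() < 0 or abs(theta.sum() - 1.0) > 1e-9:
                raise ValidationError("theta_override must be a probability "
                                      "vector summing to 1")


def perfect_values() -> np.ndarray:
    """Value matrix of a fully trained context-1 agent (objects x positions)."""
    values = np.zeros((N_OBJECTS, N_POSITIONS))
    for pos, lab in enumerate(CONTEXT_ORDERS[1]):
        values[_IDX[lab], pos] = 1.0
    return values


def _softmax_pick(rng: np.random.Generator, labels: list[str],
                  values: np.ndarray, temperature: float) -> str:
    z = values / temperature
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    return labels[rng.choice(len(labels), p=p)]


def _strategy_prior(strategy: str, values1: np.ndarray, label: str,
                    position: int) -> float:
    """Context-2 read-out of the context-1 weights under one strategy."""
    if strategy == "position":
        return values1[_IDX[_SWAP_BD[label]], position - 1]
    if strategy == "serial":
        # the chain start is unchanged; from position 2 on the read-out
        # shifts to the serially next context-1 position (C at position 2)
        if position == 1:
            return values1[_IDX[label], 0]
        return values1[_IDX[label], min(position, N_POSITIONS - 1)]
    return 0.0


def _draw_strategy(rng: np.random.Generator, agent: AgentParams) -> str:
    u = rng.random()
    if u < agent.w_position:
        return "position"
    if u < agent.w_position + agent.w_serial:
        return "serial"
    return "explore"


def _redraw_strategy(rng: np.random.Generator, agent: AgentParams,
                     exclude: str) -> str:
    weights = {"position": agent.w_position, "serial": agent.w_serial,
               "explore": max(0.0, 1.0 - agent.w_position - agent.w_serial)}
    weights.pop(exclude, None)
    total = sum(weights.values())
    if total <= 0.0:
        return exclude
    u = rng.random() * total
    for name, w in weights.items():
        if u < w:
            return name
        u -= w
    return next(iter(weights))


def _simulate_trial(rng: np.random.Generator, agent: AgentParams,
                    cfg: GeneratorConfig, context: int, trial_index: int,
                    strategy: str, values_learn: np.ndarray,
                    values1: np.ndarray, meta: dict) -> list[ChoiceRecord]:
    order = CONTEXT_ORDERS[context]
    records: list[ChoiceRecord] = []
    position = 1
    errors = 0
    secured: list[str] = []

    def rt() -> float | None:
        if cfg.rt_lognorm is None:
            return None
        mu, sigma = cfg.rt_lognorm
        return float(rng.lognormal(mu, sigma))

    def emit(phase: str, chosen: str, required: str, target: int) -> None:
        records.append(ChoiceRecord(
            phase=phase, chosen_label=chosen, required_label=required,
            ordinal_target=target, is_correct=chosen == required,
            context=context, trial_index=trial_index,
            choice_index=len(records) + 1, rt=rt(), **meta))

    while (len(records) < MAX_CHOICES_PER_TRIAL
           and errors < MAX_ERRORS_PER_TRIAL and position <= N_POSITIONS):
        available = [lab for lab in LABELS if lab not in secured]
        values = np.empty(len(available))
        # the context-1 read-out fades once context-2 weights are learned
        fade = (cfg.strategy_prior_weight
                * max(0.0, 1.0 - values_learn[:, position - 1].max())
                if context == 2 else 0.0)
        for j, lab in enumerate(available):
            v = values_learn[_IDX[lab], position - 1]
            if context == 2:
                v += fade * _strategy_prior(strategy, values1, lab, position)
            values[j] = v
        if DISTRACTOR in available and "B" in available:
            # X shares features with B and inherits part of its appeal
            values[available.index(DISTRACTOR)] += (
                agent.distractor_confusability * values[available.index("B")])
        if rng.random() < agent.lapse_rate:
            chosen = available[rng.integers(len(available))]
        else:
            chosen = _softmax_pick(rng, available, values,
                                   agent.softmax_temperature)
        required = order[position - 1]
        emit("search", chosen, required, position)
        lr = agent.learning_rate
        if chosen == required:
            values_learn[_IDX[chosen], position - 1] += (
                lr * (1.0 - values_learn[_IDX[chosen], position - 1]))
            secured.append(chosen)
            position += 1
            continue
        errors += 1
        values_learn[_IDX[chosen], position - 1] *= (1.0 - lr)
        if context == 2 and rng.random() < agent.error_reindex_rate:
            # error feedback occasionally cues the agent to abandon the
            # read-out that just failed; an error on the old-order object
            # (e.g. B at position 2) directly confirms the displacement and
            # cues re-indexing (retro-active swapping)
            if chosen == CONTEXT_ORDERS[1][position - 1]:
                strategy = "position"
            else:
                strategy = _redraw_strategy(rng, agent, exclude=strategy)
        # forced retouch of the last correct object (skipped when no object
        # has been secured yet)
        while (secured and len(records) < MAX_CHOICES_PER_TRIAL
               and errors < MAX_ERRORS_PER_TRIAL):
            last = secured[-1]
            if rng.random() < agent.lapse_rate:
                others = [lab for lab in LABELS if lab != last]
                touched = others[rng.integers(len(others))]
            else:
                touched = last
            emit("retouch", touched, last, len(secured))
            if touched == last:
                break
            errors += 1
    return records


def _simulate_block_values(agent: AgentParams, cfg: GeneratorConfig,
                           rng: np.random.Generator, *, block_id: str,
                           subject_id: str, session_index: int,
                           condition: str, background_same: bool | None,
                           init_values: np.ndarray | None
                           ) -> tuple[BlockLog, np.ndarray]:
    values1 = (np.zeros((N_OBJECTS, N_POSITIONS)) if init_values is None
               else np.array(init_values, float))
    values2 = np.zeros((N_OBJECTS, N_POSITIONS))
    meta = dict(subject_id=subject_id, session_index=session_index,
                block_id=block_id, condition=condition,
                background_same=background_same)
    block = BlockLog(subject_id=subject_id, session_index=session_index,
                     block_id=block_id, condition=condition,
                     background_same=background_same)
    for context in (1, 2):
        for trial in range(1, cfg.trials_per_context + 1):
            strategy = (_draw_strategy(rng, agent) if context == 2
                        else "none")
            learn = values1 if context == 1 else values2
            block.records.extend(_simulate_trial(
                rng, agent, cfg, context, trial, strategy, learn, values1,
                meta))
    return block, values1


def simulate_block(agent: AgentParams, cfg: GeneratorConfig,
                   rng: np.random.Generator, *, block_id: str = "b01",
                   subject_id: str = "sim", session_index: int = 1,
                   condition: str = "new_early",
                   background_same: bool | None = None,
                   init_values: np.ndarray | None = None) -> BlockLog:
    """Simulate one context-1 + context-2 sequence pair.

    ``init_values`` seeds the context-1 value weights (e.g.
    :func:`perfect_values` for a pre-trained agent, or decayed weights for a
    repeated sequence); by default the sequence is novel.
    """
    block, _ = _simulate_block_values(
        agent, cfg, rng, block_id=block_id, subject_id=subject_id,
        session_index=session_index, condition=condition,
        background_same=background_same, init_values=init_values)
    return block


def simulate_dmts(agent: AgentParams, n_trials: int,
                  rng: np.random.Generator,
                  n_test: int = 3) -> list[DMTSRecord]:
    """Simulate delayed match-to-sample trials.

    Accuracy is ``chance + (ceiling - chance) * wm_ability * similarity
    factor``; it does not depend on the delay (the study found no delay
    effect).
    """
    if n_trials <= 0:
        raise ValidationError("n_trials must be > 0")
    chance = 1.0 / n_test
    out = []
    for _ in range(n_trials):
        similarity = "high" if rng.random() < 0.5 else "low"
        delay = DMTS_DELAYS[rng.integers(len(DMTS_DELAYS))]
        accuracy = chance + (DMTS_CEILING - chance) * agent.wm_ability * \
            SIMILARITY_FACTORS[similarity]
        out.append(DMTSRecord(similarity=similarity, delay=delay,
                              n_test=n_test,
                              correct=bool(rng.random() < accuracy)))
    return out


def simulate_session(agent: AgentParams, cfg: GeneratorConfig,
                     rng: np.random.Generator | None = None,
                     session_index: int = 1,
                     subject_id: str = "sim") -> SessionLog:
    """Simulate a full session.

    Early new blocks are followed by the DMTS trials, then by late blocks of
    which a ``repeat_fraction`` re-present early sequence pairs. A repeat
    reuses the early block's final context-1 weights decayed by
    ``retention_factor``; when the repeat is shown on a different background
    the retained weights are further reduced by ``background_bonus``.
    """
    if rng is None:
        rng = np.random.default_rng(agent.seed)
    session = SessionLog(subject_id=subject_id, session_index=session_index)
    n_early = cfg.blocks_per_session // 2
    n_late = cfg.blocks_per_session - n_early
    n_repeat = min(int(n_late * cfg.repeat_fraction + 0.5), n_early, n_late)

    early_values: dict[str, np.ndarray] = {}
    for i in range(n_early):
        block_id = f"b{i + 1:02d}"
        block, values = _simulate_block_values(
            agent, cfg, rng, block_id=block_id, subject_id=subject_id,
            session_index=session_index, condition="new_early",
            background_same=None, init_values=None)
        session.blocks.append(block)
        early_values[block_id] = values

    session.dmts = simulate_dmts(agent, cfg.dmts_trials, rng,
                                 n_test=cfg.dmts_n_test)

    repeat_sources = [str(s) for s in rng.choice(sorted(early_values),
                                                 size=n_repeat,
                                                 replace=False)]
    late_kinds = (["repeat"] * n_repeat + ["new_late"] * (n_late - n_repeat))
    rng.shuffle(late_kinds)
    new_index = n_early
    for kind in late_kinds:
        if kind == "repeat":
            source = repeat_sources.pop()
            same_bg = bool(rng.random() < cfg.background_same_fraction)
            retention = cfg.retention_factor
            if not same_bg:
                retention *= 1.0 - cfg.background_bonus
            block = simulate_block(
                agent, cfg, rng, block_id=f"{source}.r",
                subject_id=subject_id, session_index=session_index,
                condition="repeat", background_same=same_bg,
                init_values=retention * early_values[source])
        else:
            new_index += 1
            block = simulate_block(
                agent, cfg, rng, block_id=f"b{new_index:02d}",
                subject_id=subject_id, session_index=session_index,
                condition="new_late", background_same=None)
        session.blocks.append(block)
    return session


def simulate_sessions(agent: AgentParams, cfg: GeneratorConfig,
                      subject_id: str = "sim") -> list[SessionLog]:
    """Simulate ``cfg.n_sessions`` sessions with one seeded stream."""
    rng = np.random.default_rng(agent.seed)
    return [simulate_session(agent, cfg, rng, session_index=i + 1,
                             subject_id=subject_id)
            for i in range(cfg.n_sessions)]


def sample_categorical_counts(theta, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Multinomial counts from a probability vector over choice labels.

    The direct sampler behind the Bayesian parameter-recovery checks: its
    output feeds the Metropolis-Hastings sampler as observed counts.
    """
    theta = np.asarray(theta, float)
    if theta.min() < 0:
        raise ValidationError("theta entries must be non-negative")
    if abs(theta.sum() - 1.0) > 1e-9:
        raise ValidationError("theta must sum to 1 (tolerance 1e-9)")
    if n <= 0:
        raise ValidationError("n must be > 0")
    return rng.multinomial(n, theta)
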