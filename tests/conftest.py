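import numpy as np
import pytest

from seqswap import AgentParams, GeneratorConfig, simulate_block
from seqswap.types import CONTEXT_ORDERS, BlockLog, ChoiceRecord


def build_trial(context: int, trial_index: int, searches,
                meta: dict | None = None) -> list[ChoiceRecord]:
    """Hand-build one trial from a list of search-choice labels.

    A correct retouch of the last correct object is inserted automatically
    after every error (when an object has already been secured), mirroring
    the task's forced-retouch rule.
    """
    defaults = dict(subject_id="s1", session_index=1, block_id="b01",
                    condition="new_early", background_same=None)
    meta = {**defaults, **(meta or {})}
    order = CONTEXT_ORDERS[context]
    records: list[ChoiceRecord] = []
    position = 1
    last_correct = None
    for label in searches:
        required = order[position - 1]
        records.append(ChoiceRecord(
            context=context, trial_index=trial_index,
            choice_index=len(records) + 1, phase="search",
            chosen_label=label, required_label=required,
            ordinal_target=position, is_correct=label == required,
            rt=0.5, **meta))
        if label == required:
            last_correct = label
            position += 1
        elif last_correct is not None:
            records.append(ChoiceRecord(
                context=context, trial_index=trial_index,
                choice_index=len(records) + 1, phase="retouch",
                chosen_label=last_correct, required_label=last_correct,
                ordinal_target=position - 1, is_correct=True,
                rt=0.5, **meta))
    return records


def build_block(trials_by_context: dict[int, list[list[str]]],
                block_id: str = "b01", condition: str = "new_early",
                background_same=None) -> BlockLog:
    block = BlockLog(subject_id="s1", session_index=1, block_id=block_id,
                     condition=condition, background_same=background_same)
    meta = {"block_id": block_id, "condition": condition,
            "background_same": background_same}
    for context, trials in trials_by_context.items():
        for t, searches in enumerate(trials, start=1):
            block.records.extend(build_trial(context, t, searches, meta))
    block.validate()
    return block


PERFECT_C1 = list(CONTEXT_ORDERS[1])
PERFECT_C2 = list(CONTEXT_ORDERS[2])


@pytest.fixture(scope="session")
def default_blocks():
    """120 blocks from the default agent; shared across read-only tests."""
    rng = np.random.default_rng(2024)
    agent = AgentParams(seed=7)
    cfg = GeneratorConfig()
    return [simulate_block(agent, cfg, rng, block_id=f"b{i:03d}")
            for i in range(120)]
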