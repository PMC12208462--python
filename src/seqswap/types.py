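"""Core domain types for the context-cued serial-order learning task.

The task: on each trial six objects are shown; five of them must be touched
in a fixed serial order, the sixth is a distractor. Objects are named by
their serial role in context 1 (``A``-``E``; ``X`` is the distractor). When
the background context switches from context 1 to context 2 the required
order changes from A-B-C-D-E to A-D-C-B-E, i.e. the objects at ordinal
positions 2 and 4 swap. After any error the subject must re-touch the last
correctly chosen object (the "retouch rule") before searching again.

A block holds up to 15 trials per context; within a trial a subject has at
most 15 touches and at most 10 errors to complete the five-object sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E", "X")
SEQ_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E")
DISTRACTOR = "X"

#: Required touch order per context, in context-1 labels.
CONTEXT_ORDERS: dict[int, tuple[str, ...]] = {
    1: ("A", "B", "C", "D", "E"),
    2: ("A", "D", "C", "B", "E"),
}

CONDITIONS = ("new_early", "new_late", "repeat")
PHASES = ("search", "retouch")
SIMILARITIES = ("high", "low")
DMTS_DELAYS = (0.5, 1.25, 1.75)

MAX_TRIALS_PER_CONTEXT = 15
MAX_CHOICES_PER_TRIAL = 15
MAX_ERRORS_PER_TRIAL = 10
N_POSITIONS = 5
N_OBJECTS = 6


class SeqswapError(Exception):
    """Base class for errors raised by this package."""


class FormatError(SeqswapError):
    """A choice-log file does not have the expected layout."""


class ValidationError(SeqswapError):
    """A record or log violates a task-structure invariant."""


def label_index(label: str) -> int:
    try:
        return LABELS.index(label)
    except ValueError:
        raise ValidationError(f"unknown object label {label!r}") from None


@dataclass
class ChoiceRecord:
    """One touch event.

    ``ordinal_target`` is the sequence position (1-5) the subject is working
    on: for search touches the position whose object is required next, for
    retouch touches the position of the last correctly chosen object.
    """

    subject_id: str
    session_index: int
    block_id: str
    condition: str
    background_same: bool | None
    context: int
    trial_index: int
    choice_index: int
    phase: str
    chosen_label: str
    required_label: str
    ordinal_target: int
    is_correct: bool
    rt: float | None = None

    def validate(self) -> None:
        if self.session_index < 1:
            raise ValidationError("session_index must be >= 1")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}, "
                                  f"got {self.condition!r}")
        if self.condition != "repeat" and self.background_same is not None:
            raise ValidationError("background_same is only defined for "
                                  "repeat blocks")
        if self.context not in (1, 2):
            raise ValidationError(f"context must be 1 or 2, got {self.context}")
        if not 1 <= self.trial_index <= MAX_TRIALS_PER_CONTEXT:
            raise ValidationError(f"trial_index {self.trial_index} outside "
                                  f"1..{MAX_TRIALS_PER_CONTEXT}")
        if not 1 <= self.choice_index <= MAX_CHOICES_PER_TRIAL:
            raise ValidationError(f"choice_index {self.choice_index} outside "
                                  f"1..{MAX_CHOICES_PER_TRIAL}")
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}")
        if self.chosen_label not in LABELS:
            raise ValidationError(f"chosen_label {self.chosen_label!r} not in "
                                  f"{LABELS}")
        if self.required_label not in SEQ_LABELS:
            raise ValidationError(f"required_label {self.required_label!r} "
                                  f"not in {SEQ_LABELS}")
        if not 1 <= self.ordinal_target <= N_POSITIONS:
            raise ValidationError(f"ordinal_target {self.ordinal_target} "
                                  f"outside 1..{N_POSITIONS}")
        if self.is_correct != (self.chosen_label == self.required_label):
            raise ValidationError(
                "is_correct must equal (chosen_label == required_label)")
        if self.phase == "search":
            order = CONTEXT_ORDERS[self.context]
            if self.required_label != order[self.ordinal_target - 1]:
                raise ValidationError(
                    f"search at position {self.ordinal_target} in context "
                    f"{self.context} must require "
                    f"{order[self.ordinal_target - 1]!r}, "
                    f"got {self.required_label!r}")
        if self.rt is not None and self.rt < 0:
            raise ValidationError("rt must be >= 0 seconds")


@dataclass
class DMTSRecord:
    """One delayed match-to-sample trial."""

    similarity: str
    delay: float
    n_test: int
    correct: bool

    @property
    def chance(self) -> float:
        return 1.0 / self.n_test

    def validate(self) -> None:
        if self.similarity not in SIMILARITIES:
            raise ValidationError(f"similarity must be one of {SIMILARITIES}")
        if self.delay not in DMTS_DELAYS:
            raise ValidationError(f"delay must be one of {DMTS_DELAYS}, "
                                  f"got {self.delay}")
        if self.n_test not in (2, 3):
            raise ValidationError("n_test must be 2 or 3")


@dataclass
class BlockLog:
    """All touches of one context-1 + context-2 sequence pair."""

    subject_id: str
    session_index: int
    block_id: str
    condition: str = "new_early"
    background_same: bool | None = None
    records: list[ChoiceRecord] = field(default_factory=list)

    def required_order(self, context: int) -> tuple[str, ...]:
        return CONTEXT_ORDERS[context]

    def trials(self, context: int) -> dict[int, list[ChoiceRecord]]:
        """Records grouped by trial for one context, in touch order."""
        out: dict[int, list[ChoiceRecord]] = {}
        for rec in self.records:
            if rec.context == context:
                out.setdefault(rec.trial_index, []).append(rec)
        return out

    def completed(self, context: int, trial_index: int) -> bool:
        """A trial is completed iff position 5 was correctly reached."""
        return any(rec.phase == "search" and rec.is_correct
                   and rec.ordinal_target == N_POSITIONS
                   for rec in self.records
                   if rec.context == context and rec.trial_index == trial_index)

    def completion_flags(self, context: int) -> list[bool]:
        """Per-trial completion, for the trials present, in trial order."""
        return [self.completed(context, t) for t in sorted(self.trials(context))]

    def trial_error_count(self, context: int, trial_index: int) -> int:
        return sum(1 for rec in self.records
                   if rec.context == context and rec.trial_index == trial_index
                   and not rec.is_correct)

    def mean_errors_per_trial(self, context: int = 1) -> float:
        trials = self.trials(context)
        if not trials:
            raise ValidationError(f"block {self.block_id} has no context-"
                                  f"{context} trials")
        errors = sum(1 for recs in trials.values()
                     for r in recs if not r.is_correct)
        return errors / len(trials)

    def validate(self, row_numbers: list[int] | None = None) -> None:
        """Check every structural invariant of the task.

        ``row_numbers`` optionally maps each record to a source-file row so
        error messages can cite it.
        """
        def where(i: int) -> str:
            if row_numbers is not None:
                return f"row {row_numbers[i]}"
            return f"record {i}"

        contexts = {r.context for r in self.records}
        if contexts - {1, 2}:
            raise ValidationError("contexts other than 1 and 2 present")
        by_trial: dict[tuple[int, int], list[int]] = {}
        for i, rec in enumerate(self.records):
            try:
                rec.validate()
            except ValidationError as exc:
                raise ValidationError(f"{where(i)}: {exc}") from None
            if (rec.subject_id, rec.session_index, rec.block_id) != (
                    self.subject_id, self.session_index, self.block_id):
                raise ValidationError(f"{where(i)}: record metadata does not "
                                      "match its block")
            by_trial.setdefault((rec.context, rec.trial_index), []).append(i)

        for context in (1, 2):
            n_trials = len([k for k in by_trial if k[0] == context])
            if n_trials > MAX_TRIALS_PER_CONTEXT:
                raise ValidationError(
                    f"block {self.block_id}: more than "
                    f"{MAX_TRIALS_PER_CONTEXT} trials in context {context}")

        for (context, trial), idx in by_trial.items():
            self._validate_trial(context, idx, where)

    def _validate_trial(self, context: int, idx: list[int], where) -> None:
        order = CONTEXT_ORDERS[context]
        if len(idx) > MAX_CHOICES_PER_TRIAL:
            raise ValidationError(
                f"{where(idx[MAX_CHOICES_PER_TRIAL])}: more than "
                f"{MAX_CHOICES_PER_TRIAL} choices in a trial")
        errors = 0
        last_correct: str | None = None
        position = 1
        prev_choice_index = 0
        expect_retouch = False
        for i in idx:
            rec = self.records[i]
            if rec.choice_index <= prev_choice_index:
                raise ValidationError(f"{where(i)}: choice_index must "
                                      "strictly increase within a trial")
            prev_choice_index = rec.choice_index
            if position > N_POSITIONS:
                raise ValidationError(f"{where(i)}: choice after the "
                                      "sequence was completed")
            if expect_retouch:
                if rec.phase != "retouch":
                    raise ValidationError(
                        f"{where(i)}: after an error the next choice must "
                        "re-touch the last correct object")
                if rec.required_label != last_correct:
                    raise ValidationError(
                        f"{where(i)}: retouch must require the last "
                        f"correctly chosen object {last_correct!r}")
            elif rec.phase == "retouch":
                raise ValidationError(f"{where(i)}: unexpected retouch "
                                      "phase without a preceding error")
            if rec.phase == "search" and rec.ordinal_target != position:
                raise ValidationError(
                    f"{where(i)}: search ordinal_target {rec.ordinal_target} "
                    f"but the trial is at position {position}")
            if not rec.is_correct:
                errors += 1
                if errors > MAX_ERRORS_PER_TRIAL:
                    raise ValidationError(
                        f"{where(i)}: more than {MAX_ERRORS_PER_TRIAL} "
                        "incorrect choices in a trial")
                expect_retouch = last_correct is not None
            else:
                if rec.phase == "search":
                    last_correct = rec.chosen_label
                    position += 1
                expect_retouch = False


@dataclass
class SessionLog:
    """One experimental session: sequence blocks plus DMTS trials."""

    subject_id: str
    session_index: int
    blocks: list[BlockLog] = field(default_factory=list)
    dmts: list[DMTSRecord] = field(default_factory=list)

    @property
    def dmts_accuracy(self) -> float | None:
        if not self.dmts:
            return None
        return sum(r.correct for r in self.dmts) / len(self.dmts)

    def validate(self) -> None:
        for rec in self.dmts:
            rec.validate()
        for block in self.blocks:
            if (block.subject_id, block.session_index) != (
                    self.subject_id, self.session_index):
                raise ValidationError(
                    f"block {block.block_id} metadata does not match session")
            block.validate()
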