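"""Reading and writing the canonical tab-delimited choice log.

One file holds one or more sessions. Every row is either a touch event
(``record_type == "choice"``) or a delayed match-to-sample trial
(``record_type == "dmts"``); the two kinds share the ``subject_id`` and
``session_index`` columns and otherwise use disjoint column sets. Trial and
choice indices are 1-based. Booleans are written as ``true``/``false`` and
missing values as empty fields.

Repeated blocks carry a block id of the form ``<source block id>.r`` so a
repeat can be paired with the early block it re-presents.
"""

from __future__ import annotations

import os

import pandas as pd

from .types import (BlockLog, ChoiceRecord, DMTSRecord, FormatError,
                    SessionLog, ValidationError)

CHOICE_COLUMNS = [
    "subject_id", "session_index", "block_id", "condition",
    "background_same", "context", "trial_index", "choice_index", "phase",
    "chosen_label", "required_label", "ordinal_target", "is_correct", "rt",
]
DMTS_COLUMNS = ["similarity", "delay", "n_test", "correct"]
ALL_COLUMNS = ["record_type"] + CHOICE_COLUMNS + DMTS_COLUMNS


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_bool(text: str, column: str, row: int) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise ValidationError(f"row {row}: column {column!r} must be "
                          f"'true' or 'false', got {text!r}")


def _parse_int(text: str, column: str, row: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValidationError(f"row {row}: column {column!r} must be an "
                              f"integer, got {text!r}") from None


def _parse_float(text: str, column: str, row: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"row {row}: column {column!r} must be a "
                              f"number, got {text!r}") from None


def write_choice_log(sessions: list[SessionLog], path: str | os.PathLike) -> str:
    """Write sessions to ``path``; returns the path.

    Rows are ordered by session, then blocks in their stored order, then
    touch order; DMTS rows follow the blocks of their session. Two writes of
    the same sessions produce byte-identical files.
    """
    rows: list[dict[str, str]] = []
    for session in sessions:
        for block in session.blocks:
            for rec in block.records:
                row = {c: "" for c in ALL_COLUMNS}
                row["record_type"] = "choice"
                for c in CHOICE_COLUMNS:
                    row[c] = _fmt(getattr(rec, c))
                rows.append(row)
        for rec in session.dmts:
            row = {c: "" for c in ALL_COLUMNS}
            row["record_type"] = "dmts"
            row["subject_id"] = session.subject_id
            row["session_index"] = str(session.session_index)
            for c in DMTS_COLUMNS:
                row[c] = _fmt(getattr(rec, c))
            rows.append(row)
    frame = pd.DataFrame(rows, columns=ALL_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return str(path)


def read_choice_log(path: str | os.PathLike) -> list[SessionLog]:
    """Read a choice log and return validated sessions.

    Sessions are grouped by ``(subject_id, session_index)`` in order of first
    appearance; every structural invariant of the task is checked and
    violations raise :class:`ValidationError` naming the offending file row.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimiter layout etc.
        raise FormatError(f"could not parse {path}: {exc}") from None
    missing = [c for c in ALL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")

    sessions: dict[tuple[str, int], SessionLog] = {}
    blocks: dict[tuple[str, int, str], BlockLog] = {}
    block_rows: dict[tuple[str, int, str], list[int]] = {}

    for i, row in enumerate(frame.itertuples(index=False)):
        file_row = i + 2  # 1-based, after the header line
        kind = row.record_type
        subject = row.subject_id
        session_index = _parse_int(row.session_index, "session_index", file_row)
        key = (subject, session_index)
        if key not in sessions:
            sessions[key] = SessionLog(subject_id=subject,
                                       session_index=session_index)
        if kind == "choice":
            rec = ChoiceRecord(
                subject_id=subject,
                session_index=session_index,
                block_id=row.block_id,
                condition=row.condition,
                background_same=(None if row.background_same == ""
                                 else _parse_bool(row.background_same,
                                                  "background_same", file_row)),
                context=_parse_int(row.context, "context", file_row),
                trial_index=_parse_int(row.trial_index, "trial_index",
                                       file_row),
                choice_index=_parse_int(row.choice_index, "choice_index",
                                        file_row),
                phase=row.phase,
                chosen_label=row.chosen_label,
                required_label=row.required_label,
                ordinal_target=_parse_int(row.ordinal_target,
                                          "ordinal_target", file_row),
                is_correct=_parse_bool(row.is_correct, "is_correct", file_row),
                rt=None if row.rt == "" else _parse_float(row.rt, "rt",
                                                          file_row),
            )
            bkey = (subject, session_index, rec.block_id)
            if bkey not in blocks:
                block = BlockLog(subject_id=subject,
                                 session_index=session_index,
                                 block_id=rec.block_id,
                                 condition=rec.condition,
                                 background_same=rec.background_same)
                blocks[bkey] = block
                block_rows[bkey] = []
                sessions[key].blocks.append(block)
            blocks[bkey].records.append(rec)
            block_rows[bkey].append(file_row)
        elif kind == "dmts":
            rec = DMTSRecord(
                similarity=row.similarity,
                delay=_parse_float(row.delay, "delay", file_row),
                n_test=_parse_int(row.n_test, "n_test", file_row),
                correct=_parse_bool(row.correct, "correct", file_row),
            )
            try:
                rec.validate()
            except ValidationError as exc:
                raise ValidationError(f"row {file_row}: {exc}") from None
            sessions[key].dmts.append(rec)
        else:
            raise ValidationError(f"row {file_row}: record_type must be "
                                  f"'choice' or 'dmts', got {kind!r}")

    for bkey, block in blocks.items():
        block.validate(row_numbers=block_rows[bkey])
    return list(sessions.values())
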