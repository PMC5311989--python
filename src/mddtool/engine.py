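"""Deterministic interview state machine.

Drives a :class:`~mddtool.bank.QuestionBank` against any response source
(interactive prompt, scripted replay, synthetic responder), records a
timestamped transcript, and classifies the completed transcript with the
DSM-5 decision rule.

The engine owns one branching policy the bank document cannot express:
the *early-exit* rule.  When both core symptom screens (A1 depressed
mood, A2 anhedonia) are denied, no symptom count can satisfy the DSM-5
core-symptom requirement, so the interview may stop immediately with a
negative diagnosis.  The rule is ON by default and is guarded by an
exhaustive skip-safety property in the test suite: for every full answer
assignment the early-exit diagnosis equals the ask-everything diagnosis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

from .bank import (
    CRITERION_TO_FIELD,
    TERMINAL,
    QuestionBank,
    QuestionNode,
)
from .dsm5 import CriterionProfile, DiagnosisResult, Ternary, classify_mdd

_YES = frozenset({"yes", "y", "yeah", "yep", "oui", "true", "1", "present"})
_NO = frozenset({"no", "n", "non", "nope", "false", "0", "absent"})


class RepromptNeeded(ValueError):
    """Raw input could not be mapped onto the question's response domain."""


class TranscriptStateError(RuntimeError):
    """Transcript is inconsistent with the bank (unknown or repeated question)."""


class TruncatedInterviewError(RuntimeError):
    """Response source ran out before the interview reached a terminal.

    The partial transcript is preserved on the ``transcript`` attribute.
    """

    def __init__(self, message: str, transcript: "InterviewTranscript"):
        super().__init__(message)
        self.transcript = transcript


@dataclass(frozen=True)
class TranscriptEntry:
    question_id: str
    raw: str
    encoded: str
    timestamp: str


@dataclass(frozen=True)
class InterviewTranscript:
    """Ordered record of asked questions and encoded responses."""

    bank_id: str
    bank_version: str
    entries: tuple[TranscriptEntry, ...] = ()
    complete: bool = False

    def answers(self) -> dict[str, str]:
        return {e.question_id: e.encoded for e in self.entries}

    def with_entry(self, entry: TranscriptEntry) -> "InterviewTranscript":
        if any(e.question_id == entry.question_id for e in self.entries):
            raise TranscriptStateError(
                f"question {entry.question_id!r} already answered"
            )
        return replace(self, entries=self.entries + (entry,))

    def to_dict(self, diagnosis: DiagnosisResult | None = None) -> dict:
        doc = {
            "bank_id": self.bank_id,
            "bank_version": self.bank_version,
            "complete": self.complete,
            "entries": [
                {
                    "question_id": e.question_id,
                    "raw": e.raw,
                    "encoded": e.encoded,
                    "timestamp": e.timestamp,
                }
                for e in self.entries
            ],
        }
        if diagnosis is not None:
            doc["diagnosis"] = {
                "mdd_positive": diagnosis.mdd_positive,
                "trace": [list(step) for step in diagnosis.trace],
            }
        return doc

    @staticmethod
    def from_dict(doc: Mapping) -> "InterviewTranscript":
        return InterviewTranscript(
            bank_id=str(doc["bank_id"]),
            bank_version=str(doc.get("bank_version", "0")),
            complete=bool(doc.get("complete", False)),
            entries=tuple(
                TranscriptEntry(
                    question_id=str(e["question_id"]),
                    raw=str(e["raw"]),
                    encoded=str(e["encoded"]),
                    timestamp=str(e.get("timestamp", "")),
                )
                for e in doc.get("entries", ())
            ),
        )

    def save(self, path: str | Path, diagnosis: DiagnosisResult | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(diagnosis), indent=2) + "\n")

    @staticmethod
    def load(path: str | Path) -> "InterviewTranscript":
        return InterviewTranscript.from_dict(json.loads(Path(path).read_text()))


def encode_response(node: QuestionNode, raw: str) -> str:
    """Map a raw answer onto the node's response domain.

    Case-insensitive; common yes/no synonyms (y, oui, non, ...) are
    accepted for binary questions.  Unrecognised input raises
    :class:`RepromptNeeded` — it is never silently coerced.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise RepromptNeeded("empty response")
    token = raw.strip().lower()
    domain = node.response_domain
    if token in domain:
        return token
    if node.response_kind == "binary":
        if token in _YES:
            return "yes"
        if token in _NO:
            return "no"
    raise RepromptNeeded(
        f"cannot interpret {raw!r} for question {node.id!r}; expected one of {domain}"
    )


def _core_denied(bank: QuestionBank, answers: Mapping[str, str]) -> bool:
    """True when every core-symptom question was asked and answered 'absent'."""
    core = [n for n in bank.nodes if n.criterion in ("A1", "A2")]
    return bool(core) and all(
        n.id in answers and answers[n.id] != n.present_if for n in core
    )


def next_question(
    bank: QuestionBank,
    transcript: InterviewTranscript,
    *,
    early_exit: bool = True,
) -> QuestionNode | None:
    """The next question to ask, or None when the interview is complete.

    Deterministic: the first call returns the bank's entry node; afterwards
    the branch rule of the last answered question decides, except that with
    ``early_exit`` enabled a double denial of the core symptoms terminates
    the interview immediately.
    """
    if not transcript.entries:
        return bank[bank.entry]
    answers = transcript.answers()
    for qid in answers:
        if qid not in bank.node_ids:
            raise TranscriptStateError(f"transcript answers unknown question {qid!r}")
    if early_exit and _core_denied(bank, answers):
        return None
    last = transcript.entries[-1]
    node = bank[last.question_id]
    target = node.branch_rules[last.encoded]
    if target == TERMINAL:
        return None
    return bank[target]


def profile_from_transcript(
    bank: QuestionBank, transcript: InterviewTranscript
) -> CriterionProfile:
    """Assemble the criterion profile answered so far.

    A field is PRESENT when the encoded answer equals the node's
    ``present_if`` token (ABSENT otherwise); unanswered fields stay
    UNASKED.  When several questions feed one field (the two criterion-C
    screens), the field is PRESENT if any of them answered PRESENT —
    either a substance or a medical cause suffices to trigger the exclusion.
    """
    values: dict[str, Ternary] = {}
    for entry in transcript.entries:
        node = bank[entry.question_id]
        fieldname = CRITERION_TO_FIELD[node.criterion]
        answered = Ternary.PRESENT if entry.encoded == node.present_if else Ternary.ABSENT
        prior = values.get(fieldname)
        if prior is None:
            values[fieldname] = answered
        elif Ternary.PRESENT in (prior, answered):
            values[fieldname] = Ternary.PRESENT
    return CriterionProfile(**values)


ResponseSource = (
    Callable[[QuestionNode], str] | Mapping[str, str] | Iterable[str]
)


def _as_callable(source: ResponseSource) -> Callable[[QuestionNode], str]:
    if callable(source):
        return source
    if isinstance(source, Mapping):
        def from_mapping(node: QuestionNode) -> str:
            try:
                return source[node.id]
            except KeyError:
                raise StopIteration
        return from_mapping
    iterator: Iterator[str] = iter(source)
    return lambda node: next(iterator)


def run_interview(
    bank: QuestionBank,
    response_source: ResponseSource,
    *,
    early_exit: bool = True,
    max_reprompts: int = 2,
    now: Callable[[], str] | None = None,
) -> tuple[InterviewTranscript, DiagnosisResult]:
    """Conduct a full interview and classify the resulting transcript.

    ``response_source`` may be a callable ``question -> raw answer``, a
    mapping ``question id -> answer``, or a plain iterable of answers
    consumed in interview order.  Terminates for every valid stream (the
    bank graph is acyclic); an exhausted source raises
    :class:`TruncatedInterviewError` carrying the partial transcript.
    """
    stamp = now or (lambda: datetime.now(timezone.utc).isoformat(timespec="seconds"))
    ask = _as_callable(response_source)
    transcript = InterviewTranscript(bank_id=bank.bank_id, bank_version=bank.version)

    while True:
        node = next_question(bank, transcript, early_exit=early_exit)
        if node is None:
            break
        raw = encoded = None
        for _ in range(max_reprompts + 1):
            try:
                raw = ask(node)
            except StopIteration:
                raise TruncatedInterviewError(
                    f"response source exhausted at question {node.id!r}", transcript
                )
            try:
                encoded = encode_response(node, raw)
                break
            except RepromptNeeded:
                continue
        if encoded is None:
            raise TruncatedInterviewError(
                f"no interpretable answer for question {node.id!r} "
                f"after {max_reprompts + 1} attempts",
                transcript,
            )
        transcript = transcript.with_entry(
            TranscriptEntry(node.id, str(raw), encoded, stamp())
        )

    transcript = replace(transcript, complete=True)
    diagnosis = classify_mdd(profile_from_transcript(bank, transcript))
    return transcript, diagnosis


def classify_transcript(
    bank: QuestionBank, transcript: InterviewTranscript
) -> DiagnosisResult:
    """Re-classify a saved transcript; replaying reproduces the diagnosis."""
    return classify_mdd(profile_from_transcript(bank, transcript))
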