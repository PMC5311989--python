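"""Question banks: the interview's content, loaded from JSON or YAML.

A bank is a validated directed acyclic graph of :class:`QuestionNode`
objects.  Every node carries the DSM-5 criterion it probes, so the engine
can assemble a criterion profile from any complete transcript regardless
of the bank's wording or branching.  Two banks ship with the package:

* ``dsm5-mdd-default`` — 15 nodes: one question per A-symptom (A1..A9),
  the two-week duration gate, the impairment gate, and four exclusion
  screens (substance, general-medical, psychotic disorder, manic episode;
  the first two both feed DSM-5 criterion C).
* ``dsm5-mdd-reduced`` — A-symptoms + duration + impairment only, for
  sensitivity analyses of how much the exclusion screens matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

TERMINAL = "END"

VALID_CRITERIA = frozenset(
    {"A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8", "A9", "DUR", "B", "C", "D", "E"}
)

#: criterion label -> CriterionProfile field it resolves
CRITERION_TO_FIELD = {
    "A1": "a1", "A2": "a2", "A3": "a3", "A4": "a4", "A5": "a5",
    "A6": "a6", "A7": "a7", "A8": "a8", "A9": "a9",
    "DUR": "duration_ok", "B": "impairment",
    "C": "excl_substance_medical", "D": "excl_psychotic", "E": "excl_manic",
}

#: profile fields where a "yes" answer counts AGAINST the diagnosis
EXCLUSION_CRITERIA = frozenset({"C", "D", "E"})


class BankValidationError(ValueError):
    """The bank document violates the question-graph schema or invariants."""


@dataclass(frozen=True)
class QuestionNode:
    """One interview question with its criterion binding and branching rules.

    ``present_if`` names the encoded answer that marks the bound criterion
    state PRESENT (symptom present, gate met — or exclusion triggered).
    Exclusion screens in the bundled bank are phrased so that "yes" is the
    favourable answer (``present_if: "no"``), keeping an all-"yes" response
    stream internally consistent.
    """

    id: str
    text: str
    criterion: str
    response_kind: str = "binary"
    branch_rules: Mapping[str, str] = field(default_factory=dict)
    present_if: str = "yes"

    @property
    def response_domain(self) -> tuple[str, ...]:
        if self.response_kind == "binary":
            return ("yes", "no")
        return tuple(self.branch_rules)


@dataclass(frozen=True)
class QuestionBank:
    """Validated, acyclic bank of questions with a single entry node."""

    bank_id: str
    version: str
    entry: str
    nodes: tuple[QuestionNode, ...]

    def __post_init__(self) -> None:
        _validate(self)

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, node_id: str) -> QuestionNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"no question {node_id!r} in bank {self.bank_id!r}")

    @cached_property
    def _by_id(self) -> dict[str, QuestionNode]:
        return {n.id: n for n in self.nodes}

    @cached_property
    def node_ids(self) -> frozenset[str]:
        return frozenset(n.id for n in self.nodes)

    def enumerate_paths(self, max_paths: int = 100_000) -> list[tuple[str, ...]]:
        """All root-to-terminal answer paths (question-id sequences).

        Used by the termination property: every path must end at TERMINAL,
        which validation guarantees via acyclicity + dangling-reference
        checks, and this re-verifies constructively.
        """
        by_id = self._by_id
        paths: list[tuple[str, ...]] = []
        stack: list[tuple[str, tuple[str, ...]]] = [(self.entry, ())]
        while stack:
            node_id, prefix = stack.pop()
            if node_id == TERMINAL:
                paths.append(prefix)
                continue
            node = by_id[node_id]
            for target in set(node.branch_rules.values()):
                stack.append((target, prefix + (node_id,)))
            if len(paths) > max_paths:
                raise RuntimeError("path enumeration budget exceeded")
        return paths


def _validate(bank: QuestionBank) -> None:
    ids = [n.id for n in bank.nodes]
    if not ids:
        raise BankValidationError("bank has no questions")
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise BankValidationError(f"duplicate question ids: {sorted(dupes)}")
    if bank.entry not in ids:
        raise BankValidationError(f"entry node {bank.entry!r} is not in the bank")

    by_id = {n.id: n for n in bank.nodes}
    for node in bank.nodes:
        if node.criterion not in VALID_CRITERIA:
            raise BankValidationError(
                f"question {node.id!r}: unknown criterion {node.criterion!r}"
            )
        if not node.branch_rules:
            raise BankValidationError(f"question {node.id!r} has no branch rules")
        if node.present_if not in node.response_domain:
            raise BankValidationError(
                f"question {node.id!r}: present_if {node.present_if!r} is not "
                f"in its response domain {node.response_domain}"
            )
        missing = set(node.response_domain) - set(node.branch_rules)
        if missing:
            raise BankValidationError(
                f"question {node.id!r}: no branch for responses {sorted(missing)}"
            )
        for response, target in node.branch_rules.items():
            if target != TERMINAL and target not in by_id:
                raise BankValidationError(
                    f"question {node.id!r}: branch {response!r} targets "
                    f"missing question {target!r}"
                )

    _reject_cycles(bank, by_id)


def _reject_cycles(bank: QuestionBank, by_id: dict[str, QuestionNode]) -> None:
    """Depth-first search with an explicit stack; reports the cycle found."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {i: WHITE for i in by_id}
    trail: list[str] = []

    def visit(start: str) -> None:
        stack: list[tuple[str, bool]] = [(start, False)]
        while stack:
            node_id, done = stack.pop()
            if done:
                colour[node_id] = BLACK
                trail.pop()
                continue
            if colour[node_id] == BLACK:
                continue
            if colour[node_id] == GREY:
                cycle = trail[trail.index(node_id):] + [node_id]
                raise BankValidationError(
                    "question graph contains a cycle: " + " -> ".join(cycle)
                )
            colour[node_id] = GREY
            trail.append(node_id)
            stack.append((node_id, True))
            for target in by_id[node_id].branch_rules.values():
                if target != TERMINAL:
                    if colour[target] == GREY:
                        cycle = trail[trail.index(target):] + [target]
                        raise BankValidationError(
                            "question graph contains a cycle: " + " -> ".join(cycle)
                        )
                    if colour[target] == WHITE:
                        stack.append((target, False))

    for node_id in by_id:
        if colour[node_id] == WHITE:
            visit(node_id)


def load_question_bank(source: str | Path | Mapping) -> QuestionBank:
    """Load and validate a question bank from a JSON/YAML file or a mapping.

    Raises :class:`BankValidationError` naming the offending node when the
    document has dangling branch targets, cycles, duplicate ids or schema
    violations.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    if not isinstance(doc, Mapping):
        raise BankValidationError("bank document must be a mapping")

    try:
        questions = doc["questions"]
    except KeyError:
        raise BankValidationError("bank document lacks a 'questions' list")
    nodes = []
    for q in questions:
        try:
            nodes.append(
                QuestionNode(
                    id=str(q["id"]),
                    text=str(q["text"]),
                    criterion=str(q["criterion"]),
                    response_kind=str(q.get("response_kind", "binary")),
                    branch_rules=dict(q["branch_rules"]),
                    present_if=str(q.get("present_if", "yes")),
                )
            )
        except KeyError as exc:
            raise BankValidationError(
                f"question entry {q.get('id', '<no id>')!r} missing field {exc}"
            )
    return QuestionBank(
        bank_id=str(doc.get("bank_id", "unnamed")),
        version=str(doc.get("version", "0")),
        entry=str(doc.get("entry", nodes[0].id if nodes else "")),
        nodes=tuple(nodes),
    )


def default_bank() -> QuestionBank:
    """The bundled 15-node DSM-5 MDD bank (A1..A9, DUR, B, four C/D/E screens)."""
    return _bundled("default_bank.json")


def reduced_bank() -> QuestionBank:
    """The bundled 11-node bank without exclusion screens (sensitivity analysis)."""
    return _bundled("reduced_bank.json")


def _bundled(name: str) -> QuestionBank:
    with resources.files("mddtool.data").joinpath(name).open() as fh:
        return load_question_bank(json.load(fh))
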