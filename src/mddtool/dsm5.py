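"""DSM-5 major depressive episode decision rule.

The classifier is the decisional algorithm at the heart of the interview:
a patient screens positive when at least five of the nine A-criterion
symptoms are present, at least one of them is a core symptom (depressed
mood A1 or anhedonia A2), the symptoms have persisted for two weeks or
more, they cause clinically significant impairment (criterion B), and no
exclusion applies (substance/medical cause C, psychotic disorder D,
manic or hypomanic episode E).

Symptom and gate fields are ternary: PRESENT, ABSENT or UNASKED.  UNASKED
is tolerated only when the answer provably cannot change the decision
(e.g. A3..A9 after both core symptoms were denied); otherwise
:func:`classify_mdd` raises :class:`IncompleteProfileError` rather than
guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import Enum
from itertools import product
from typing import Iterator

SYMPTOM_FIELDS = ("a1", "a2", "a3", "a4", "a5", "a6", "a7", "a8", "a9")
GATE_FIELDS = ("duration_ok", "impairment")
EXCLUSION_FIELDS = ("excl_substance_medical", "excl_psychotic", "excl_manic")

MIN_SYMPTOMS = 5  # DSM-5: five or more of the nine A symptoms
CORE_SYMPTOMS = ("a1", "a2")  # at least one of depressed mood / anhedonia


class Ternary(str, Enum):
    """Three-valued answer state for a criterion field."""

    PRESENT = "present"
    ABSENT = "absent"
    UNASKED = "unasked"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("Ternary has no implicit truth value; compare explicitly")


class IncompleteProfileError(ValueError):
    """An unasked criterion field could still change the diagnosis."""


@dataclass(frozen=True)
class CriterionProfile:
    """Resolved (or partially resolved) DSM-5 criterion states for one respondent.

    Symptom fields a1..a9 record presence of the nine A-criterion symptoms;
    ``duration_ok`` is the two-week duration gate, ``impairment`` criterion B,
    and the ``excl_*`` fields record whether an exclusion criterion (C, D, E)
    was triggered (PRESENT means the exclusion applies and vetoes the
    diagnosis).
    """

    a1: Ternary = Ternary.UNASKED
    a2: Ternary = Ternary.UNASKED
    a3: Ternary = Ternary.UNASKED
    a4: Ternary = Ternary.UNASKED
    a5: Ternary = Ternary.UNASKED
    a6: Ternary = Ternary.UNASKED
    a7: Ternary = Ternary.UNASKED
    a8: Ternary = Ternary.UNASKED
    a9: Ternary = Ternary.UNASKED
    duration_ok: Ternary = Ternary.UNASKED
    impairment: Ternary = Ternary.UNASKED
    excl_substance_medical: Ternary = Ternary.UNASKED
    excl_psychotic: Ternary = Ternary.UNASKED
    excl_manic: Ternary = Ternary.UNASKED

    def symptoms(self) -> tuple[Ternary, ...]:
        return tuple(getattr(self, f) for f in SYMPTOM_FIELDS)

    def unasked_fields(self) -> tuple[str, ...]:
        return tuple(
            f.name for f in fields(self) if getattr(self, f.name) is Ternary.UNASKED
        )

    @staticmethod
    def from_answers(**kwargs: Ternary | str | bool) -> "CriterionProfile":
        """Build a profile accepting Ternary values, their string names, or bools."""
        coerced: dict[str, Ternary] = {}
        for name, value in kwargs.items():
            if isinstance(value, Ternary):
                coerced[name] = value
            elif isinstance(value, bool):
                coerced[name] = Ternary.PRESENT if value else Ternary.ABSENT
            else:
                coerced[name] = Ternary(value)
        return CriterionProfile(**coerced)


@dataclass(frozen=True)
class DiagnosisResult:
    """Binary MDD decision with the per-criterion evaluation trace."""

    mdd_positive: bool
    profile: CriterionProfile
    trace: tuple[tuple[str, str], ...] = field(default_factory=tuple)


def _favourable(name: str) -> Ternary:
    """The value of a field that pushes toward a positive diagnosis."""
    return Ternary.ABSENT if name in EXCLUSION_FIELDS else Ternary.PRESENT


def _unfavourable(name: str) -> Ternary:
    return Ternary.PRESENT if name in EXCLUSION_FIELDS else Ternary.ABSENT


def _decide(profile: CriterionProfile) -> tuple[bool, tuple[tuple[str, str], ...]]:
    """Decision for a fully resolved profile, with the checks actually made."""
    trace: list[tuple[str, str]] = []

    n_present = sum(1 for s in profile.symptoms() if s is Ternary.PRESENT)
    trace.append(("symptom_count", f"{n_present}/9 present (need >= {MIN_SYMPTOMS})"))
    core = any(getattr(profile, c) is Ternary.PRESENT for c in CORE_SYMPTOMS)
    trace.append(("core_symptom", "present" if core else "absent"))
    if n_present < MIN_SYMPTOMS or not core:
        return False, tuple(trace)

    for gate in GATE_FIELDS:
        ok = getattr(profile, gate) is Ternary.PRESENT
        trace.append((gate, "met" if ok else "not met"))
        if not ok:
            return False, tuple(trace)

    for excl in EXCLUSION_FIELDS:
        triggered = getattr(profile, excl) is Ternary.PRESENT
        trace.append((excl, "triggered" if triggered else "clear"))
        if triggered:
            return False, tuple(trace)

    return True, tuple(trace)


def classify_mdd(profile: CriterionProfile) -> DiagnosisResult:
    """Apply the DSM-5 MDD decision rule to a criterion profile.

    Positive iff >= 5 of the 9 A-symptoms are present including a core
    symptom (A1 depressed mood or A2 anhedonia), the two-week duration and
    impairment gates are met, and no C/D/E exclusion is triggered.

    UNASKED fields are tolerated only when irrelevant: the rule is evaluated
    under the best and worst resolution of every unasked field, and if the
    two disagree an :class:`IncompleteProfileError` is raised.
    """
    unasked = profile.unasked_fields()
    if not unasked:
        positive, trace = _decide(profile)
        return DiagnosisResult(positive, profile, trace)

    best = replace(profile, **{n: _favourable(n) for n in unasked})
    worst = replace(profile, **{n: _unfavourable(n) for n in unasked})
    pos_best, _ = _decide(best)
    pos_worst, trace_worst = _decide(worst)
    if pos_best != pos_worst:
        raise IncompleteProfileError(
            f"unasked field(s) {unasked} could change the diagnosis"
        )
    # Outcome is invariant to the unasked fields; report the worst-case trace,
    # which only walks checks whose inputs were actually asked.
    return DiagnosisResult(pos_worst, profile, trace_worst)


def iter_symptom_patterns() -> Iterator[tuple[bool, ...]]:
    """All 512 presence/absence patterns over the nine A-criterion symptoms."""
    yield from product((False, True), repeat=9)


def qualifying_symptom_patterns() -> list[tuple[bool, ...]]:
    """The A-symptom patterns that satisfy the symptom half of the rule.

    With the duration/impairment gates met and no exclusions, these are
    exactly the patterns a positive diagnosis requires: >= 5 of 9 present
    including at least one core symptom.  There are 227 of them.
    """
    out = []
    for pattern in iter_symptom_patterns():
        if sum(pattern) >= MIN_SYMPTOMS and (pattern[0] or pattern[1]):
            out.append(pattern)
    return out


def profile_from_pattern(
    pattern: tuple[bool, ...],
    *,
    duration_ok: bool = True,
    impairment: bool = True,
    exclusions: bool = False,
) -> CriterionProfile:
    """Fully resolved profile from a 9-symptom pattern plus gate settings."""
    if len(pattern) != 9:
        raise ValueError("symptom pattern must have 9 entries")
    values = {
        name: (Ternary.PRESENT if flag else Ternary.ABSENT)
        for name, flag in zip(SYMPTOM_FIELDS, pattern)
    }
    values["duration_ok"] = Ternary.PRESENT if duration_ok else Ternary.ABSENT
    values["impairment"] = Ternary.PRESENT if impairment else Ternary.ABSENT
    for excl in EXCLUSION_FIELDS:
        values[excl] = Ternary.PRESENT if exclusions else Ternary.ABSENT
    return CriterionProfile(**values)
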