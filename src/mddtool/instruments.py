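"""Questionnaire scoring and internal-consistency reliability.

Two self-report instruments are supported:

* **BDI-II** — 21 items scored 0..3, total 0..63, with the revised-manual
  severity cut-offs: 0-13 minimal, 14-19 mild, 20-28 moderate, 29-63
  severe (boundaries inclusive).
* **AES** (acceptability scale) — 6 items on a balanced 1..5 Likert
  scale, total 6..30.

Reliability is Cronbach's alpha,
``alpha = k/(k-1) * (1 - sum(item variances) / variance(totals))``,
computed with the sample-variance convention (n-1 denominator) for both
item and total variances.  Missing item responses are rejected, never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

BDI_CUTOFFS = (("minimal", 0, 13), ("mild", 14, 19), ("moderate", 20, 28), ("severe", 29, 63))

_SPECS = {
    "bdi2": {"n_items": 21, "item_min": 0, "item_max": 3},
    "aes": {"n_items": 6, "item_min": 1, "item_max": 5},
}


class InstrumentValidationError(ValueError):
    """Wrong item count or an out-of-range item score."""


@dataclass(frozen=True)
class ItemResponseSet:
    """One respondent's raw item scores for a named instrument."""

    instrument: str
    items: tuple[int, ...]
    respondent_id: str = ""

    def __post_init__(self) -> None:
        spec = _SPECS.get(self.instrument)
        if spec is None:
            raise InstrumentValidationError(
                f"unknown instrument {self.instrument!r}; expected one of {sorted(_SPECS)}"
            )
        if len(self.items) != spec["n_items"]:
            raise InstrumentValidationError(
                f"{self.instrument} expects {spec['n_items']} items, got {len(self.items)}"
            )
        for idx, score in enumerate(self.items, start=1):
            if not isinstance(score, (int, np.integer)):
                raise InstrumentValidationError(
                    f"{self.instrument} item {idx}: non-integer score {score!r}"
                )
            if not spec["item_min"] <= score <= spec["item_max"]:
                raise InstrumentValidationError(
                    f"{self.instrument} item {idx}: score {score} outside "
                    f"[{spec['item_min']}, {spec['item_max']}]"
                )


@dataclass(frozen=True)
class ScoredInstrument:
    instrument: str
    respondent_id: str
    total: int
    severity: str | None = None


def bdi_severity(total: int) -> str:
    """Severity category for a BDI-II total (0-13/14-19/20-28/29-63)."""
    for label, lo, hi in BDI_CUTOFFS:
        if lo <= total <= hi:
            return label
    raise InstrumentValidationError(f"BDI-II total {total} outside 0..63")


def score_bdi(items: ItemResponseSet) -> ScoredInstrument:
    """Total (sum of 21 items) and severity category for a BDI-II response set."""
    if items.instrument != "bdi2":
        raise InstrumentValidationError(f"expected bdi2 responses, got {items.instrument!r}")
    total = int(sum(items.items))
    return ScoredInstrument("bdi2", items.respondent_id, total, bdi_severity(total))


def score_aes(items: ItemResponseSet) -> ScoredInstrument:
    """Total (sum of 6 items, range 6..30) for an acceptability-scale response set."""
    if items.instrument != "aes":
        raise InstrumentValidationError(f"expected aes responses, got {items.instrument!r}")
    return ScoredInstrument("aes", items.respondent_id, int(sum(items.items)))


def cronbach_alpha(score_matrix: np.ndarray | pd.DataFrame | Sequence[Sequence[float]]) -> float:
    """Cronbach's alpha of a respondents x items score matrix.

    Requires at least 2 items, 3 respondents and non-zero total-score
    variance.  Sample variances (ddof=1) throughout.
    """
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim != 2:
        raise InstrumentValidationError("score matrix must be 2-dimensional")
    n, k = X.shape
    if k < 2:
        raise InstrumentValidationError(f"need >= 2 items, got {k}")
    if n < 3:
        raise InstrumentValidationError(f"need >= 3 respondents, got {n}")
    if np.isnan(X).any():
        raise InstrumentValidationError("missing item responses are not accepted")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise InstrumentValidationError("total-score variance is zero; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def read_item_table(path, instrument: str) -> pd.DataFrame:
    """Read an item CSV (``respondent_id,item_1..item_k``) and validate rows."""
    df = pd.read_csv(path)
    spec = _SPECS.get(instrument)
    if spec is None:
        raise InstrumentValidationError(f"unknown instrument {instrument!r}")
    item_cols = [f"item_{i}" for i in range(1, spec["n_items"] + 1)]
    missing = [c for c in ("respondent_id", *item_cols) if c not in df.columns]
    if missing:
        raise InstrumentValidationError(f"item table missing columns {missing}")
    for _, row in df.iterrows():
        ItemResponseSet(
            instrument,
            tuple(int(row[c]) for c in item_cols),
            str(row["respondent_id"]),
        )
    return df[["respondent_id", *item_cols]]


def score_table(df: pd.DataFrame, instrument: str) -> pd.DataFrame:
    """Score every row of an item table; returns respondent_id, total (, severity)."""
    spec = _SPECS[instrument]
    item_cols = [f"item_{i}" for i in range(1, spec["n_items"] + 1)]
    scorer = score_bdi if instrument == "bdi2" else score_aes
    records = []
    for _, row in df.iterrows():
        scored = scorer(
            ItemResponseSet(
                instrument,
                tuple(int(row[c]) for c in item_cols),
                str(row["respondent_id"]),
            )
        )
        rec = {"respondent_id": scored.respondent_id, "total": scored.total}
        if scored.severity is not None:
            rec["severity"] = scored.severity
        records.append(rec)
    return pd.DataFrame.from_records(records)
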