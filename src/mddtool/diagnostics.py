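"""Diagnostic test evaluation against a reference standard.

Given paired index-test / reference-standard results this module computes
the confusion table, sensitivity, specificity, positive and negative
predictive values with exact Clopper-Pearson 95% confidence intervals,
and a single-operating-point ROC analysis.

For a binary (single threshold) classifier the ROC curve is the polyline
(0,0) -> (1 - specificity, sensitivity) -> (1,1), so the area under it
is (sensitivity + specificity) / 2.  Its confidence interval and the
test against the chance value 0.5 use the Hanley-McNeil standard-error
approximation; this choice is configurable at the reporting layer and is
an approximation — exact small-sample AUC inference for a single
operating point is not well defined.

Metrics whose denominator is empty (e.g. sensitivity with no
reference-positives) are flagged *undefined* rather than silently set to
zero.  Display rounding is half-up to integer percents for proportions
and two decimals for AUC, the convention of diagnostic-accuracy tables;
raw proportions are always retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: BDI-II severity strata used for the stratified analysis, as (label, lo, hi)
DEFAULT_STRATA = (("mild", 14, 19), ("moderate", 20, 28), ("severe", 29, 63))


class EvaluationError(ValueError):
    pass


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    scale = 10.0 ** digits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def percent(p: float) -> int:
    """Proportion -> integer percent, half-up."""
    return int(round_half_up(p * 100))


@dataclass(frozen=True)
class ConfusionTable:
    """Paired index-test vs reference-standard counts."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise EvaluationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def reference_positives(self) -> int:
        return self.tp + self.fn

    @property
    def reference_negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact 95% CI; ``defined`` is False when the
    denominator was empty, in which case the numeric fields are NaN."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int = 0
    denominator: int = 0
    defined: bool = True

    @property
    def as_percent(self) -> int:
        if not self.defined:
            raise EvaluationError("metric is undefined (empty denominator)")
        return percent(self.value)

    @property
    def ci_percent(self) -> tuple[int, int]:
        if not self.defined:
            raise EvaluationError("metric is undefined (empty denominator)")
        return percent(self.ci_low), percent(self.ci_high)


UNDEFINED = MetricEstimate(math.nan, math.nan, math.nan, 0, 0, defined=False)


@dataclass(frozen=True)
class AucEstimate:
    value: float
    ci_low: float
    ci_high: float
    se: float
    p_value: float
    defined: bool = True


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    auc: AucEstimate
    table: ConfusionTable


def build_confusion(records: pd.DataFrame | Iterable[Mapping]) -> ConfusionTable:
    """Cross-tabulate paired diagnoses.

    ``records`` is a DataFrame (or iterable of mappings) with boolean-like
    columns ``index_test`` and ``reference`` and unique ``respondent_id``.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise EvaluationError("no records")
    for col in ("index_test", "reference"):
        if col not in df.columns:
            raise EvaluationError(f"records lack column {col!r}")
    if "respondent_id" in df.columns and df["respondent_id"].duplicated().any():
        dupes = df.loc[df["respondent_id"].duplicated(), "respondent_id"].tolist()
        raise EvaluationError(f"duplicate respondent ids: {dupes}")
    idx = _as_bool(df["index_test"])
    ref = _as_bool(df["reference"])
    return ConfusionTable(
        tp=int((idx & ref).sum()),
        fn=int((~idx & ref).sum()),
        fp=int((idx & ~ref).sum()),
        tn=int((~idx & ~ref).sum()),
    )


def _as_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    mapping = {
        "positive": True, "negative": False, "pos": True, "neg": False,
        "1": True, "0": False, "true": True, "false": False,
        "yes": True, "no": False,
    }
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = col[out.isna()].unique().tolist()
        raise EvaluationError(f"unrecognised diagnosis labels: {bad}")
    return out.astype(bool)


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact central (Clopper-Pearson) binomial confidence interval.

    Obtained from beta-distribution quantiles, the closed form of
    inverting the binomial tails.  The lower bound is 0 when successes=0
    and the upper bound 1 when successes=trials.
    """
    if not 0 <= successes <= trials or trials < 1:
        raise EvaluationError(f"need 0 <= successes <= trials >= 1, got {successes}/{trials}")
    if not 0 < level < 1:
        raise EvaluationError(f"confidence level must be in (0,1), got {level}")
    a = (1.0 - level) / 2.0
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(a, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(stats.beta.ppf(1 - a, successes + 1, trials - successes))
    return lo, hi


def _proportion(successes: int, trials: int, level: float = 0.95) -> MetricEstimate:
    if trials == 0:
        return UNDEFINED
    lo, hi = clopper_pearson(successes, trials, level)
    return MetricEstimate(successes / trials, lo, hi, successes, trials)


def auc_binary(ct: ConfusionTable, level: float = 0.95) -> AucEstimate:
    """ROC area for a single-operating-point binary classifier.

    AUC = (sensitivity + specificity)/2 — the trapezoidal area through
    (0,0), (1-spec, sens), (1,1).  CI and the two-sided test against 0.5
    use the Hanley-McNeil standard error with a normal approximation.
    """
    n_pos, n_neg = ct.reference_positives, ct.reference_negatives
    if n_pos == 0 or n_neg == 0:
        return AucEstimate(math.nan, math.nan, math.nan, math.nan, math.nan, defined=False)
    sens = ct.tp / n_pos
    spec = ct.tn / n_neg
    auc = (sens + spec) / 2.0
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc * auc) + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = float(stats.norm.ppf(1 - (1 - level) / 2))
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    if se == 0.0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    return AucEstimate(auc, lo, hi, se, p)


def performance(ct: ConfusionTable, level: float = 0.95) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV (exact CIs) and single-point AUC."""
    return DiagnosticPerformance(
        sensitivity=_proportion(ct.tp, ct.tp + ct.fn, level),
        specificity=_proportion(ct.tn, ct.fp + ct.tn, level),
        ppv=_proportion(ct.tp, ct.tp + ct.fp, level),
        npv=_proportion(ct.tn, ct.fn + ct.tn, level),
        auc=auc_binary(ct, level),
        table=ct,
    )


def format_p(p: float) -> str:
    """Three-decimal p-value with the conventional '<0.001' floor."""
    if math.isnan(p):
        return "n/a"
    return "<0.001" if p < 0.001 else f"{round_half_up(p, 3):.3f}"


def stratified_performance(
    records: pd.DataFrame,
    strata: Sequence[tuple[str, int, int]] = DEFAULT_STRATA,
    *,
    restrict_negatives: bool = False,
    level: float = 0.95,
) -> dict[str, DiagnosticPerformance]:
    """Performance stratified on the severity score of the reference-positives.

    Per stratum, sensitivity is computed over reference-positive records
    whose ``bdi_total`` falls in the stratum's bounds.  By default the
    specificity denominator is the full reference-negative pool, shared
    across strata (set ``restrict_negatives=True`` to restrict negatives
    to the stratum's score band as well).  Strata must not overlap.
    """
    df = pd.DataFrame(records)
    if "bdi_total" not in df.columns or df["bdi_total"].isna().any():
        raise EvaluationError("stratified analysis requires a complete bdi_total column")
    spans = sorted((lo, hi) for _, lo, hi in strata)
    for (_, hi_prev), (lo, _) in zip(spans, spans[1:]):
        if lo <= hi_prev:
            raise EvaluationError("strata overlap")
    idx = _as_bool(df["index_test"])
    ref = _as_bool(df["reference"])
    bdi = df["bdi_total"].astype(int)

    out: dict[str, DiagnosticPerformance] = {}
    for label, lo, hi in strata:
        in_stratum = (bdi >= lo) & (bdi <= hi)
        pos = ref & in_stratum
        neg = (~ref) & (in_stratum if restrict_negatives else True)
        ct = ConfusionTable(
            tp=int((idx & pos).sum()),
            fn=int((~idx & pos).sum()),
            fp=int((idx & neg).sum()),
            tn=int((~idx & neg).sum()),
        )
        out[label] = performance(ct, level)
    return out


def parse_strata(text: str) -> tuple[tuple[str, int, int], ...]:
    """Parse a CLI strata spec like ``14:19,20:28,29:63``."""
    out = []
    for i, chunk in enumerate(text.split(",")):
        lo, _, hi = chunk.partition(":")
        try:
            out.append((f"stratum_{i + 1}_{int(lo)}_{int(hi)}", int(lo), int(hi)))
        except ValueError:
            raise EvaluationError(f"cannot parse stratum {chunk!r}; expected lo:hi")
    return tuple(out)
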