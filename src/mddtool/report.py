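"""Study-style report assembly.

Builds a deterministic JSON + Markdown report from a paired-diagnosis
cohort table and optional questionnaire item tables: cohort summary,
an all-patients performance block (AUC, sensitivity, specificity, PPV,
NPV with 95% CIs), a severity-stratified block, and instrument
reliability.  Every number is produced by the diagnostics/instruments
modules and rounded with their conventions, so the report is re-derivable
from the raw tables it ships alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .diagnostics import (
    DEFAULT_STRATA,
    DiagnosticPerformance,
    MetricEstimate,
    build_confusion,
    format_p,
    percent,
    performance,
    round_half_up,
    stratified_performance,
)
from .instruments import cronbach_alpha

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyReport:
    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True) + "\n"

    def to_markdown(self) -> str:
        p = self.payload
        lines = [
            "# Diagnostic validation report",
            "",
            f"Tool version {p['meta']['tool_version']}; input digest "
            f"{p['meta']['input_digest']}; seed {p['meta'].get('seed', 'n/a')}.",
            "",
            f"Cohort: n = {p['cohort']['n']}, reference-positive "
            f"{p['cohort']['reference_positives']} "
            f"({p['cohort']['prevalence_percent']}%).",
            "",
            "## Overall performance",
            "",
            "| Group | AUC | P value | Sensitivity | Specificity | PPV | NPV | TP | FN | FP |",
            "|---|---|---|---|---|---|---|---|---|---|",
            _perf_row("All patients", p["overall"]),
        ]
        if p.get("stratified"):
            lines += [
                "",
                "## Performance stratified on severity",
                "",
                "| Group | AUC | P value | Sensitivity | Specificity |",
                "|---|---|---|---|---|",
            ]
            for label, block in p["stratified"].items():
                lines.append(_strat_row(label, block))
        if p.get("reliability"):
            lines += ["", "## Instrument reliability", ""]
            for instr, alpha in p["reliability"].items():
                lines.append(f"- Cronbach's alpha ({instr}): {alpha:.2f}")
        return "\n".join(lines) + "\n"


def _metric_cell(block: dict) -> str:
    if not block["defined"]:
        return "undefined"
    return f"{block['percent']} [{block['ci_percent'][0]}-{block['ci_percent'][1]}]"


def _auc_cell(block: dict) -> str:
    if not block["defined"]:
        return "undefined"
    return f"{block['value_2dp']:.2f} [{block['ci_2dp'][0]:.2f}-{block['ci_2dp'][1]:.2f}]"


def _perf_row(label: str, p: dict) -> str:
    ct = p["confusion"]
    return (
        f"| {label} | {_auc_cell(p['auc'])} | {p['auc'].get('p_value', 'n/a')} | "
        f"{_metric_cell(p['sensitivity'])} | {_metric_cell(p['specificity'])} | "
        f"{_metric_cell(p['ppv'])} | {_metric_cell(p['npv'])} | "
        f"{ct['tp']} | {ct['fn']} | {ct['fp']} |"
    )


def _strat_row(label: str, p: dict) -> str:
    return (
        f"| {label} | {_auc_cell(p['auc'])} | {p['auc'].get('p_value', 'n/a')} | "
        f"{_metric_cell(p['sensitivity'])} | {_metric_cell(p['specificity'])} |"
    )


def _metric_dict(m: MetricEstimate) -> dict:
    if not m.defined:
        return {"defined": False}
    return {
        "defined": True,
        "proportion": m.value,
        "percent": m.as_percent,
        "ci_proportion": [m.ci_low, m.ci_high],
        "ci_percent": list(m.ci_percent),
        "numerator": m.numerator,
        "denominator": m.denominator,
    }


def performance_dict(perf: DiagnosticPerformance) -> dict:
    auc = perf.auc
    return {
        "confusion": {
            "tp": perf.table.tp, "fn": perf.table.fn,
            "fp": perf.table.fp, "tn": perf.table.tn,
        },
        "sensitivity": _metric_dict(perf.sensitivity),
        "specificity": _metric_dict(perf.specificity),
        "ppv": _metric_dict(perf.ppv),
        "npv": _metric_dict(perf.npv),
        "auc": (
            {"defined": False}
            if not auc.defined
            else {
                "defined": True,
                "value": auc.value,
                "value_2dp": round_half_up(auc.value, 2),
                "ci": [auc.ci_low, auc.ci_high],
                "ci_2dp": [round_half_up(auc.ci_low, 2), round_half_up(auc.ci_high, 2)],
                "se": auc.se,
                "p_value": format_p(auc.p_value),
                "p_value_raw": auc.p_value,
            }
        ),
    }


def make_report(
    cohort: pd.DataFrame,
    *,
    bdi_items: pd.DataFrame | None = None,
    aes_items: pd.DataFrame | None = None,
    strata=DEFAULT_STRATA,
    seed: int | None = None,
    timestamp: bool = True,
) -> StudyReport:
    """Assemble the full validation report from raw tables.

    The severity-stratified block is included only when the cohort table
    carries a complete ``bdi_total`` column; otherwise it is omitted with
    a logged warning.  Identical inputs yield byte-identical reports apart
    from the timestamp field (suppress it with ``timestamp=False``).
    """
    ct = build_confusion(cohort)
    overall = performance(ct)
    digest = hashlib.sha256(
        cohort.to_csv(index=False).encode()
    ).hexdigest()[:16]

    payload: dict = {
        "meta": {
            "tool_version": __version__,
            "input_digest": digest,
            "seed": seed,
        },
        "cohort": {
            "n": ct.n,
            "reference_positives": ct.reference_positives,
            "prevalence_percent": round_half_up(
                100.0 * ct.reference_positives / ct.n, 1
            ),
        },
        "overall": performance_dict(overall),
    }
    if timestamp:
        payload["meta"]["generated_at"] = datetime.now(timezone.utc).isoformat(
            timespec="seconds"
        )

    has_bdi = "bdi_total" in cohort.columns and not cohort["bdi_total"].isna().any()
    if has_bdi:
        payload["stratified"] = {
            label: performance_dict(perf)
            for label, perf in stratified_performance(cohort, strata).items()
        }
    else:
        log.warning("cohort table has no complete bdi_total column; "
                    "severity-stratified block omitted")

    reliability = {}
    for name, items in (("BDI-II", bdi_items), ("AES", aes_items)):
        if items is not None:
            cols = [c for c in items.columns if c.startswith("item_")]
            reliability[name] = cronbach_alpha(items[cols].to_numpy(dtype=float))
    if reliability:
        payload["reliability"] = reliability

    return StudyReport(payload)


def write_report(report: StudyReport, out: str | Path) -> tuple[Path, Path]:
    out = Path(out)
    json_path = out if out.suffix == ".json" else out.with_suffix(".json")
    md_path = json_path.with_suffix(".md")
    json_path.write_text(report.to_json())
    md_path.write_text(report.to_markdown())
    return json_path, md_path
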