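"""Synthetic patient-cohort generator.

Emulates the statistical structure of a sleep-clinic validation cohort
for a structured depression interview, so the whole pipeline is testable
without clinical data:

* latent MDD status at a configurable prevalence (default 19.6%);
* a mild/moderate/severe mixture among cases (default 40/34.3/25.7%);
* severity-dependent detection by the structured interview (default
  sensitivities 0.21/0.57/0.73 by severity, false-alarm rate 10/144);
* interview symptom profiles sampled uniformly within the qualifying or
  non-qualifying DSM-5 pattern class implied by the detection outcome, so
  running the generated answers through the interview engine reproduces
  the sampled outcome exactly;
* BDI-II item vectors from a discretised one-factor model whose group
  means and internal consistency (Cronbach's alpha ~ 0.89 at n = 179)
  are calibrated to the study the defaults emulate;
* AES acceptability item vectors from the same item machinery.

Latent severity classes map onto BDI-II score bands: a case's latent
depression score is drawn from the case distribution truncated to its
class band (mild 14-19, moderate 20-28, severe 29-63), then expressed as
correlated item responses.  Observed item totals scatter around the
latent class, as questionnaire totals do in practice.

All randomness flows from one master seed through named child streams,
so cohorts are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .bank import CRITERION_TO_FIELD, QuestionBank
from .dsm5 import (
    CriterionProfile,
    Ternary,
    iter_symptom_patterns,
    profile_from_pattern,
    qualifying_symptom_patterns,
)

SEVERITY_CLASSES = ("mild", "moderate", "severe")
SEVERITY_BANDS = {"mild": (14, 19), "moderate": (20, 28), "severe": (29, 63)}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator parameters; defaults are the emulated study conditions."""

    n: int = 179
    prevalence: float = 0.196
    severity_mix: tuple[float, float, float] = (0.40, 0.343, 0.257)
    detect_prob: Mapping[str, float] = field(
        default_factory=lambda: {"mild": 0.21, "moderate": 0.57, "severe": 0.73}
    )
    false_alarm: float = 10 / 144
    bdi_mean_pos: float = 22.3
    bdi_sd_pos: float = 6.9
    bdi_mean_neg: float = 7.8
    bdi_sd_neg: float = 7.3
    #: cohort composition: "fixed" realises exactly round(n * prevalence)
    #: cases with severity counts apportioned by largest remainder (the
    #: fixed observed composition of a validation cohort); "bernoulli"
    #: samples each patient's status and class independently
    composition: str = "fixed"
    #: common inter-item correlation of the latent (pre-discretisation) BDI items
    inter_item_corr: float = 0.08
    #: marginal SD of a latent BDI item before rounding/clipping to 0..3
    bdi_item_sd: float = 0.65
    aes_mean: float = 25.4
    aes_item_sd: float = 1.2
    aes_inter_item_corr: float = 0.28
    seed: int | None = None

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        probs = {
            "prevalence": self.prevalence,
            "false_alarm": self.false_alarm,
            "inter_item_corr": self.inter_item_corr,
            "aes_inter_item_corr": self.aes_inter_item_corr,
            **{f"detect_prob[{k}]": v for k, v in self.detect_prob.items()},
            **{f"severity_mix[{i}]": v for i, v in enumerate(self.severity_mix)},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ConfigError(f"severity_mix must sum to 1, got {sum(self.severity_mix)}")
        if set(self.detect_prob) != set(SEVERITY_CLASSES):
            raise ConfigError(f"detect_prob must have keys {SEVERITY_CLASSES}")
        for name in ("bdi_sd_pos", "bdi_sd_neg", "bdi_item_sd", "aes_item_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.composition not in ("fixed", "bernoulli"):
            raise ConfigError(
                f"composition must be 'fixed' or 'bernoulli', got {self.composition!r}"
            )

    @staticmethod
    def from_file(path: str | Path) -> "GeneratorConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) if path.suffix in {".yaml", ".yml"} else json.loads(path.read_text())
        try:
            cfg = GeneratorConfig(**{k: tuple(v) if k == "severity_mix" else v for k, v in doc.items()})
        except TypeError as exc:
            raise ConfigError(f"bad generator config: {exc}")
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detect_prob"] = dict(self.detect_prob)
        d["severity_mix"] = list(self.severity_mix)
        return d


@dataclass(frozen=True)
class SyntheticPatient:
    """Latent truth plus the observables generated from it."""

    respondent_id: str
    reference_positive: bool
    severity: str | None          # latent class; None for reference-negatives
    detected: bool                # does the interview classifier fire?
    symptom_pattern: tuple[bool, ...]
    profile: CriterionProfile
    bdi_items: tuple[int, ...]
    aes_items: tuple[int, ...]

    @property
    def bdi_total(self) -> int:
        return int(sum(self.bdi_items))


@dataclass(frozen=True)
class Cohort:
    config: GeneratorConfig
    patients: tuple[SyntheticPatient, ...]
    table: pd.DataFrame  # respondent_id, index_test, reference, bdi_total (+ bookkeeping)


# --- discretised one-factor item model -------------------------------------

def _expected_item_mean(m: float, s: float, levels: Sequence[int]) -> float:
    """Mean of clip(round(N(m, s^2))) onto integer ``levels`` (contiguous)."""
    lo = levels[0]
    thresholds = [lv - 0.5 for lv in levels[1:]]
    return lo + sum(stats.norm.sf((t - m) / s) for t in thresholds)


def _calibrate_location(target_item_mean: float, s: float, levels: Sequence[int]) -> float:
    """Latent location whose discretised mean hits the target item mean."""
    lo, hi = levels[0], levels[-1]
    if not lo < target_item_mean < hi:
        raise ConfigError(
            f"target item mean {target_item_mean} outside open interval ({lo}, {hi})"
        )
    f = lambda m: _expected_item_mean(m, s, levels) - target_item_mean
    return float(optimize.brentq(f, lo - 10 * s - 1, hi + 10 * s + 1, xtol=1e-10))


def _factor_items(
    rng: np.random.Generator,
    n: int,
    k: int,
    location: float,
    item_sd: float,
    rho: float,
    levels: Sequence[int],
) -> np.ndarray:
    """n x k integer item matrix with common inter-item correlation ``rho``."""
    lo, hi = levels[0], levels[-1]
    if item_sd == 0.0:
        return np.full((n, k), int(np.clip(np.round(location), lo, hi)))
    f = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, k))
    x = location + item_sd * (np.sqrt(rho) * f + np.sqrt(1.0 - rho) * e)
    return np.clip(np.round(x), lo, hi).astype(int)


def _class_item_means(cfg: GeneratorConfig) -> dict[str, float]:
    """Per-group target BDI item means (group total mean / 21).

    Case classes use the case score distribution truncated to the class's
    BDI band, so the severity mixture reproduces the overall case mean.
    """
    targets = {"negative": cfg.bdi_mean_neg}
    for cls, (lo, hi) in SEVERITY_BANDS.items():
        a = (lo - cfg.bdi_mean_pos) / cfg.bdi_sd_pos
        b = (hi - cfg.bdi_mean_pos) / cfg.bdi_sd_pos
        targets[cls] = float(stats.truncnorm.mean(a, b, cfg.bdi_mean_pos, cfg.bdi_sd_pos))
    return {g: t / 21.0 for g, t in targets.items()}


def generate_bdi_items(
    group: str, cfg: GeneratorConfig, n: int = 1, rng: np.random.Generator | None = None
) -> np.ndarray:
    """n x 21 BDI-II item matrix for a latent group.

    ``group`` is "negative" or a severity class ("mild"/"moderate"/
    "severe").  Items come from a one-factor Gaussian model rounded and
    clipped to 0..3; the latent location is calibrated so the discretised
    group mean matches the group's target total.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    try:
        item_mean = _class_item_means(cfg)[group]
    except KeyError:
        raise ConfigError(f"unknown group {group!r}")
    levels = (0, 1, 2, 3)
    if cfg.bdi_item_sd == 0.0:
        return _factor_items(rng, n, 21, item_mean, 0.0, cfg.inter_item_corr, levels)
    loc = _calibrate_location(item_mean, cfg.bdi_item_sd, levels)
    return _factor_items(rng, n, 21, loc, cfg.bdi_item_sd, cfg.inter_item_corr, levels)


def generate_aes_items(
    cfg: GeneratorConfig, n: int = 1, rng: np.random.Generator | None = None
) -> np.ndarray:
    """n x 6 acceptability-scale item matrix (1..5 Likert)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    levels = (1, 2, 3, 4, 5)
    if cfg.aes_item_sd == 0.0:
        return _factor_items(rng, n, 6, cfg.aes_mean / 6.0, 0.0, cfg.aes_inter_item_corr, levels)
    loc = _calibrate_location(cfg.aes_mean / 6.0, cfg.aes_item_sd, levels)
    return _factor_items(rng, n, 6, loc, cfg.aes_item_sd, cfg.aes_inter_item_corr, levels)


def _apportion(total: int, proportions: np.ndarray) -> np.ndarray:
    """Integer counts summing to ``total``, by largest-remainder rounding."""
    quotas = proportions * total
    counts = np.floor(quotas).astype(int)
    remainder = total - int(counts.sum())
    order = np.argsort(-(quotas - np.floor(quotas)), kind="stable")
    counts[order[:remainder]] += 1
    return counts


# --- symptom-pattern sampling ----------------------------------------------

def _pattern_classes() -> tuple[np.ndarray, np.ndarray]:
    """(qualifying, non-qualifying) A-symptom patterns as boolean arrays."""
    qualifying = {p for p in qualifying_symptom_patterns()}
    q, nq = [], []
    for p in iter_symptom_patterns():
        (q if p in qualifying else nq).append(p)
    return np.array(q, dtype=bool), np.array(nq, dtype=bool)


_QUALIFYING, _NON_QUALIFYING = _pattern_classes()


def generate_cohort(cfg: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort.

    ``seed`` overrides ``cfg.seed``.  Reference status, severity class and
    detection outcome are sampled first; each patient's interview symptom
    pattern is then drawn uniformly within the qualifying (>= 5 of 9
    symptoms incl. a core symptom) or non-qualifying class implied by the
    detection outcome, with duration/impairment gates met and exclusions
    clear, so classification of the profile reproduces the outcome exactly.
    """
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng_status, rng_pattern, rng_bdi, rng_aes = (
        np.random.default_rng(s) for s in master.spawn(4)
    )
    n = cfg.n

    severity = np.full(n, "", dtype=object)
    if cfg.composition == "fixed":
        n_pos = int(round(n * cfg.prevalence))
        reference = np.zeros(n, dtype=bool)
        pos_idx = rng_status.permutation(n)[:n_pos]
        reference[pos_idx] = True
        counts = _apportion(n_pos, np.asarray(cfg.severity_mix))
        labels = np.repeat(np.array(SEVERITY_CLASSES, dtype=object), counts)
        severity[rng_status.permutation(pos_idx)] = labels
    else:
        reference = rng_status.random(n) < cfg.prevalence
        n_pos = int(reference.sum())
        severity[reference] = rng_status.choice(
            SEVERITY_CLASSES, size=n_pos, p=np.asarray(cfg.severity_mix)
        )
    p_fire = np.where(reference, 0.0, cfg.false_alarm)
    for cls in SEVERITY_CLASSES:
        p_fire = np.where(reference & (severity == cls), cfg.detect_prob[cls], p_fire)
    detected = rng_status.random(n) < p_fire

    patterns = np.empty((n, 9), dtype=bool)
    fire_idx = rng_pattern.integers(0, len(_QUALIFYING), size=n)
    quiet_idx = rng_pattern.integers(0, len(_NON_QUALIFYING), size=n)
    patterns[detected] = _QUALIFYING[fire_idx[detected]]
    patterns[~detected] = _NON_QUALIFYING[quiet_idx[~detected]]

    bdi = np.empty((n, 21), dtype=int)
    groups = np.where(reference, severity, "negative")
    for grp in ("negative", *SEVERITY_CLASSES):
        mask = groups == grp
        if mask.any():
            bdi[mask] = generate_bdi_items(grp, cfg, n=int(mask.sum()), rng=rng_bdi)
    aes = generate_aes_items(cfg, n=n, rng=rng_aes)

    patients = tuple(
        SyntheticPatient(
            respondent_id=f"p{i + 1:06d}",
            reference_positive=bool(reference[i]),
            severity=str(severity[i]) if reference[i] else None,
            detected=bool(detected[i]),
            symptom_pattern=tuple(bool(b) for b in patterns[i]),
            profile=profile_from_pattern(tuple(bool(b) for b in patterns[i])),
            bdi_items=tuple(int(v) for v in bdi[i]),
            aes_items=tuple(int(v) for v in aes[i]),
        )
        for i in range(n)
    )
    table = pd.DataFrame(
        {
            "respondent_id": [p.respondent_id for p in patients],
            "index_test": ["positive" if p.detected else "negative" for p in patients],
            "reference": ["positive" if p.reference_positive else "negative" for p in patients],
            "bdi_total": [p.bdi_total for p in patients],
            "severity": [p.severity or "" for p in patients],
        }
    )
    return Cohort(config=cfg, patients=patients, table=table)


def respond_to_interview(patient: SyntheticPatient, bank: QuestionBank) -> dict[str, str]:
    """Scripted answers (question id -> yes/no) realising the patient's profile.

    Feeding the result to :func:`mddtool.engine.run_interview` reproduces
    the patient's stored detection outcome.
    """
    answers: dict[str, str] = {}
    for node in bank.nodes:
        state = getattr(patient.profile, CRITERION_TO_FIELD[node.criterion])
        if state is Ternary.UNASKED:
            raise ConfigError(
                f"patient profile does not cover criterion {node.criterion!r}"
            )
        affirm = node.present_if
        deny = "no" if affirm == "yes" else "yes"
        answers[node.id] = affirm if state is Ternary.PRESENT else deny
    return answers


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the evaluation CSV plus per-instrument item CSVs; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "bdi_items": out / "bdi_items.csv",
        "aes_items": out / "aes_items.csv",
        "config": out / "generator_config.json",
    }
    cohort.table[["respondent_id", "index_test", "reference", "bdi_total"]].to_csv(
        paths["cohort"], index=False
    )
    for key, k, attr in (("bdi_items", 21, "bdi_items"), ("aes_items", 6, "aes_items")):
        pd.DataFrame(
            [
                {"respondent_id": p.respondent_id}
                | {f"item_{j + 1}": getattr(p, attr)[j] for j in range(k)}
                for p in cohort.patients
            ]
        ).to_csv(paths[key], index=False)
    paths["config"].write_text(json.dumps(cohort.config.to_dict(), indent=2) + "\n")
    return paths
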