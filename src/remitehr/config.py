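"""Configuration objects shared across the pipeline.

All glycemic cut-offs, window lengths and the diabetes ICD-10 code range live
in :class:`DiagnosticThresholds` so that every rule in the phenotyping and
remission modules reads from one place.  Dates are ISO calendar dates and all
interval arithmetic is done in whole days; windows are closed on the left and
open on the right except where a rule is phrased "between X and Y", which is
closed on both ends.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import yaml

logger = logging.getLogger("remitehr")

#: calendar window of the study population (inclusive on both ends)
DEFAULT_WINDOW = (dt.date(2020, 3, 1), dt.date(2022, 5, 31))

#: administrative end of data capture; events (labs, visits, dispenses) may
#: occur after the exposure window but not after this date
DEFAULT_HORIZON = dt.date(2022, 12, 31)

ComparatorFlavor = Literal["any_lab", "negative_swab"]


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class DiagnosticThresholds:
    """Glycemic thresholds, lookback windows and code ranges.

    Defaults implement the ADA laboratory criteria (random glucose
    >= 200 mg/dL, fasting glucose >= 126 mg/dL, 2-h OGTT glucose
    >= 200 mg/dL, HbA1c >= 6.5%) and the study's window rules.
    """

    random_glucose_dm: float = 200.0  # mg/dL
    fasting_glucose_dm: float = 126.0  # mg/dL
    ogtt_glucose_dm: float = 200.0  # mg/dL
    hba1c_dm: float = 6.5  # percent
    remission_hba1c: float = 6.5  # percent; sensitivity analysis uses 5.7
    icd10_range: tuple[str, str] = ("E08", "E13")  # inclusive
    pre_index_lab_lookback: int = 730  # days
    visit_lookback: int = 365  # days
    steroid_exclusion_window: int = 30  # days post-index, glucose only
    remission_gap: int = 90  # days between qualifying HbA1c pair
    remission_latency: int = 90  # days from detection to first qualifying HbA1c
    hosp_window: tuple[int, int] = (-7, 30)  # days around index, closed-closed

    def __post_init__(self) -> None:
        for name in (
            "random_glucose_dm",
            "fasting_glucose_dm",
            "ogtt_glucose_dm",
            "hba1c_dm",
            "remission_hba1c",
            "pre_index_lab_lookback",
            "visit_lookback",
            "steroid_exclusion_window",
            "remission_gap",
            "remission_latency",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")
        if self.remission_hba1c not in (6.5, 5.7):
            raise ConfigurationError("remission_hba1c must be 6.5 or 5.7")
        if self.remission_hba1c > self.hba1c_dm:
            raise ConfigurationError(
                "remission threshold cannot exceed the diagnostic HbA1c threshold"
            )

    def glucose_threshold(self, kind: str) -> float:
        return {
            "random_glucose": self.random_glucose_dm,
            "fasting_glucose": self.fasting_glucose_dm,
            "ogtt_2h_glucose": self.ogtt_glucose_dm,
        }[kind]

    def icd10_is_diabetes(self, code: str) -> bool:
        """True if an ICD-10 code falls in the diabetes range (E08-E13)."""
        prefix = code[:3].upper()
        lo, hi = self.icd10_range
        return len(prefix) == 3 and lo <= prefix <= hi

    def with_remission_threshold(self, value: float) -> "DiagnosticThresholds":
        return replace(self, remission_hba1c=value)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic EHR generator.

    The generator emulates an enriched study population: every patient has
    background care (visits, routine glucose and HbA1c testing) inside the
    exposure window, a fraction develop incident diabetes after their anchor
    date, and latent remitters are given definition-satisfying sub-threshold
    HbA1c trajectories off glucose-lowering medication.  ``true_remission_rr``
    multiplies the base remission probability for exposed diabetic patients
    and is the ground-truth effect that the inference stage should recover.
    """

    n_patients: int = 20_000
    p_exposed: float = 0.25
    true_remission_rr: float = 1.25
    p_remission_base: float = 0.19
    p_hospitalized_given_exposed: float = 0.21
    p_hospitalized_given_unexposed: float = 0.04
    surveillance_ratio: float = 1.0
    surveillance_hospitalized_only: bool = False
    p_incident_diabetes: float = 0.30
    p_prevalent_diabetes: float = 0.05
    bmi_missing_rate: float = 0.10
    calendar_window: tuple[dt.date, dt.date] = DEFAULT_WINDOW
    data_horizon: dt.date = DEFAULT_HORIZON
    # background event-process rates (per year unless noted)
    visit_rate: float = 18.0
    glucose_rate_pre: float = 3.0
    glucose_rate_post: float = 6.0
    a1c_rate_post: float = 2.0
    glucose_spike_prob: float = 0.01  # transient hyperglycemia per glucose test
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for name in (
            "p_exposed",
            "p_remission_base",
            "p_hospitalized_given_exposed",
            "p_hospitalized_given_unexposed",
            "p_incident_diabetes",
            "p_prevalent_diabetes",
            "glucose_spike_prob",
        ):
            _check_prob(name, getattr(self, name))
        if not (0.0 <= self.bmi_missing_rate < 1.0):
            raise ConfigurationError("bmi_missing_rate must be in [0, 1)")
        if self.true_remission_rr <= 0:
            raise ConfigurationError("true_remission_rr must be positive")
        if self.surveillance_ratio <= 0:
            raise ConfigurationError("surveillance_ratio must be positive")
        start, end = self.calendar_window
        if not start < end:
            raise ConfigurationError("calendar_window start must precede end")
        if self.data_horizon < end:
            raise ConfigurationError("data_horizon must not precede the window end")
        if self.p_remission_base * max(self.true_remission_rr, 1.0) > 1.0:
            raise ConfigurationError(
                "p_remission_base * true_remission_rr exceeds 1; not a probability"
            )


#: covariate adjustment set of the main model; reference levels per the
#: published model layout
ADJUSTMENT_TERMS: tuple[str, ...] = (
    "age_cat",
    "female",
    "race_flags",
    "bmi_cat",
    "charlson",
    "n_a1c_prior_year",
    "era",
    "vaccine_cat",
    "region",
)

REFERENCE_LEVELS: dict[str, str] = {
    "age_cat": "50-59",
    "bmi_cat": "30-34",
    "vaccine_cat": "0",
    "era": "wild_type",
    "region": "Other",
}


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, exposure and adjustment terms of a regression model."""

    outcome: str = "remission"
    exposure: str = "exposed"
    adjustment: tuple[str, ...] = ADJUSTMENT_TERMS
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(REFERENCE_LEVELS)
    )

    def unadjusted(self) -> "ModelSpec":
        return replace(self, adjustment=())


@dataclass
class RunConfig:
    """One end-to-end pipeline run.

    Exactly one of ``generator`` (generate mode) or ``data_dir`` (read mode)
    must be set.  ``seed`` is split into fixed per-stage substreams so stages
    are reproducible in isolation.
    """

    generator: GeneratorConfig | None = None
    data_dir: Path | None = None
    cohorts: tuple[int, ...] = (1, 2)
    comparator: ComparatorFlavor = "any_lab"
    sensitivity: tuple[str, ...] = ()
    thresholds: DiagnosticThresholds = field(default_factory=DiagnosticThresholds)
    m_imputations: int = 10
    output_dir: Path = Path("remitehr_out")
    seed: int = 0

    VALID_SENSITIVITY = ("threshold_5_7", "non_hospitalized", "negative_swab_comparator")

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.data_dir is None):
            raise ConfigurationError(
                "exactly one of generator (generate mode) or data_dir (read mode) "
                "must be provided"
            )
        for s in self.sensitivity:
            if s not in self.VALID_SENSITIVITY:
                raise ConfigurationError(f"unknown sensitivity analysis: {s!r}")
        for c in self.cohorts:
            if c not in (1, 2):
                raise ConfigurationError(f"cohort id must be 1 or 2, got {c}")


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def load_run_config(path: Path | str) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    gen = None
    if "generator" in raw:
        g = dict(raw["generator"] or {})
        if "calendar_window" in g:
            g["calendar_window"] = tuple(_parse_date(x) for x in g["calendar_window"])
        if "data_horizon" in g:
            g["data_horizon"] = _parse_date(g["data_horizon"])
        gen = GeneratorConfig(**g)
    th = DiagnosticThresholds(**(raw.get("thresholds") or {}))
    return RunConfig(
        generator=gen,
        data_dir=Path(raw["data_dir"]) if raw.get("data_dir") else None,
        cohorts=tuple(raw.get("cohorts", (1, 2))),
        comparator=raw.get("comparator", "any_lab"),
        sensitivity=tuple(raw.get("sensitivity", ())),
        thresholds=th,
        m_imputations=int(raw.get("m_imputations", 10)),
        output_dir=Path(raw.get("output_dir", "remitehr_out")),
        seed=int(raw.get("seed", 0)),
    )


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage 31-bit substream seed from the run seed."""
    import hashlib

    import numpy as np

    digest = hashlib.blake2s(stage.encode("utf-8"), digest_size=4).digest()
    label = int.from_bytes(digest, "little") % (2**31)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(label,))
    return int(ss.generate_state(1)[0] % (2**31))
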