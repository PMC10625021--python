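"""Synthetic claims-style cohort generator.

Produces long-format event calendars, a covariate table and ground-truth
archetype labels for cohorts of patients initiating a home therapy
(the *index event*, day 0).  Four trajectory archetypes are supported:

1. ambulatory start, or at most one hospitalisation before the index;
2. at least two severe-exacerbation stays in the final six months;
3. frequent exacerbation stays spread over the whole pre-index year;
4. few but very long hospitalisations (median stay > 7 days).

All dates are integer day offsets relative to the index event.  Pre-index
events live in ``[-window_days, 0)``; the index event occupies day 0;
death and censoring happen strictly after day 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "ArchetypeParams",
    "CovariateParams",
    "ConfigError",
    "generate_cohort",
    "generate_patient",
    "INDEX_EVENT",
    "EXACERBATION",
    "CARDIO_RESP",
    "ICU",
    "COPD_MARKER",
    "OXYGEN_START",
    "POINT_EVENT_TYPES",
    "HOSPITAL_STAY_TYPES",
    "EVENT_COLUMNS",
    "COMORBIDITY_FLAGS",
]

# Canonical event-type names used across the pipeline.
INDEX_EVENT = "niv_init"
EXACERBATION = "copd_exacerbation_stay"
CARDIO_RESP = "cardio_resp_stay"
ICU = "icu_stay"
COPD_MARKER = "bronchodilator_dispensing"
OXYGEN_START = "oxygen_start"
POINT_EVENT_TYPES = (
    "gp_consult",
    "hospital_consult",
    "pulmonologist_consult",
    "pulmonary_function_test",
    "sleep_study",
)
HOSPITAL_STAY_TYPES = (EXACERBATION, CARDIO_RESP, ICU)

EVENT_COLUMNS = ("patient_id", "event_type", "start_day", "end_day")

COMORBIDITY_FLAGS = (
    "undernutrition",
    "morbid_obesity",
    "sleep_apnoea",
    "hypertension_cvd",
    "diabetes",
    "psychiatric",
)


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass(frozen=True)
class CovariateParams:
    """Covariate sampling parameters for one archetype."""

    age_mean: float = 70.0
    age_sd: float = 10.0
    male_prob: float = 0.51
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.3 for k in COMORBIDITY_FLAGS}
    )
    hospital_prescriber_prob: float = 0.65
    private_pulmo_prescriber_prob: float = 0.26


@dataclass(frozen=True)
class ArchetypeParams:
    """Event-intensity parameters for one trajectory archetype.

    Hospitalisation episodes are placed at archetype-specific anchor days
    (mean end day of each episode, most recent first) with independent
    per-patient jitter, which reproduces the block-aligned raster structure
    of real pre-index calendars: patients of the same archetype share
    episode timing up to a few days.  The episode count is
    ``min_episodes + Poisson(extra_episode_lambda)`` capped at the number
    of anchors.
    """

    episode_end_anchors: tuple[float, ...] = ()
    min_episodes: int = 0
    extra_episode_lambda: float = 0.0
    anchor_jitter_sd: float = 4.0
    duration_median: float = 9.0  # log-normal median, days
    duration_sigma: float = 0.3
    icu_prob: float = 0.1
    icu_days_lambda: float = 2.0
    exacerbation_prob: float = 0.85  # else coded as a cardio/respiratory stay
    # Episodes [0, forced_recent_exacerbations) are forced to be
    # exacerbation-typed and to start within the last `recent_window` days.
    forced_recent_exacerbations: int = 0
    recent_window: int = 180
    ambulatory_fraction: float = 0.0  # zero-hospitalisation sub-archetype
    mortality_rate: float = 0.2  # exponential hazard per year, post-index
    oxygen_prob: float = 0.5
    oxygen_lead_lambda: float = 60.0  # days before index
    point_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "gp_consult": 9.0,
            "hospital_consult": 1.5,
            "pulmonologist_consult": 0.2,
            "pulmonary_function_test": 1.2,
            "sleep_study": 0.3,
        }
    )
    covariates: CovariateParams = field(default_factory=CovariateParams)


def _default_archetypes() -> tuple[ArchetypeParams, ...]:
    def cov(age_mean, male, undernut, obesity, apnoea, htn, diabetes, psych,
            hospital=0.65, pulmo=0.26):
        return CovariateParams(
            age_mean=age_mean,
            male_prob=male,
            comorbidity_prevalence={
                "undernutrition": undernut,
                "morbid_obesity": obesity,
                "sleep_apnoea": apnoea,
                "hypertension_cvd": htn,
                "diabetes": diabetes,
                "psychiatric": psych,
            },
            hospital_prescriber_prob=hospital,
            private_pulmo_prescriber_prob=pulmo,
        )

    a1 = ArchetypeParams(
        episode_end_anchors=(-18.0,),
        min_episodes=1,
        extra_episode_lambda=0.0,  # never more than one stay
        duration_median=9.0,
        duration_sigma=0.3,
        anchor_jitter_sd=4.0,
        icu_prob=0.05,
        ambulatory_fraction=0.32,
        mortality_rate=0.10,
        oxygen_prob=0.42,
        oxygen_lead_lambda=50.0,
        covariates=cov(69, 0.50, 0.22, 0.46, 0.33, 0.72, 0.29, 0.33),
    )
    a2 = ArchetypeParams(
        episode_end_anchors=(-8.0, -38.0, -68.0),
        min_episodes=2,
        extra_episode_lambda=0.35,
        duration_median=8.0,
        duration_sigma=0.25,
        anchor_jitter_sd=3.0,
        icu_prob=0.10,
        forced_recent_exacerbations=2,
        recent_window=180,
        mortality_rate=0.22,
        oxygen_prob=0.59,
        oxygen_lead_lambda=150.0,
        point_rates={
            "gp_consult": 10.0,
            "hospital_consult": 2.5,
            "pulmonologist_consult": 0.2,
            "pulmonary_function_test": 1.8,
            "sleep_study": 0.3,
        },
        covariates=cov(72, 0.53, 0.39, 0.46, 0.34, 0.83, 0.29, 0.43),
    )
    a3 = ArchetypeParams(
        episode_end_anchors=(-12.0, -75.0, -140.0, -205.0, -270.0, -330.0),
        min_episodes=4,
        extra_episode_lambda=1.2,
        duration_median=10.0,
        duration_sigma=0.25,
        anchor_jitter_sd=3.0,
        icu_prob=0.15,
        mortality_rate=0.40,
        oxygen_prob=0.66,
        oxygen_lead_lambda=270.0,
        point_rates={
            "gp_consult": 12.0,
            "hospital_consult": 3.0,
            "pulmonologist_consult": 0.2,
            "pulmonary_function_test": 2.2,
            "sleep_study": 0.3,
        },
        covariates=cov(71, 0.54, 0.38, 0.47, 0.36, 0.83, 0.38, 0.46),
    )
    a4 = ArchetypeParams(
        episode_end_anchors=(-8.0, -55.0, -102.0, -149.0, -196.0, -243.0,
                             -290.0, -337.0),
        min_episodes=6,
        extra_episode_lambda=1.0,
        duration_median=22.0,
        duration_sigma=0.3,
        anchor_jitter_sd=4.0,
        icu_prob=0.30,
        icu_days_lambda=4.0,
        exacerbation_prob=0.90,
        mortality_rate=1.2,
        oxygen_prob=0.78,
        oxygen_lead_lambda=200.0,
        point_rates={
            "gp_consult": 5.0,
            "hospital_consult": 3.0,
            "pulmonologist_consult": 0.13,
            "pulmonary_function_test": 2.5,
            "sleep_study": 0.15,
        },
        covariates=cov(71, 0.56, 0.66, 0.38, 0.28, 0.83, 0.66, 0.62,
                       hospital=0.74, pulmo=0.19),
    )
    return (a1, a2, a3, a4)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of a synthetic cohort draw."""

    n_patients: int = 5000
    cluster_weights: tuple[float, float, float, float] = (0.66, 0.12, 0.21, 0.01)
    archetypes: tuple[ArchetypeParams, ...] = field(default_factory=_default_archetypes)
    window_days: int = 365
    followup_min_days: int = 365
    followup_max_days: int = 2190
    min_age: float = 40.0
    max_age: float = 95.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients > 0):
            raise ConfigError("n_patients must be a positive integer")
        w = np.asarray(self.cluster_weights, dtype=float)
        if w.shape != (4,):
            raise ConfigError("cluster_weights must have exactly 4 entries")
        if (w < 0).any():
            raise ConfigError("cluster_weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ConfigError("cluster_weights must sum to 1 (got %.15f)" % w.sum())
        if len(self.archetypes) != 4:
            raise ConfigError("archetypes must have exactly 4 entries")
        for i, a in enumerate(self.archetypes):
            tag = f"archetypes[{i}]"
            if a.min_episodes < 0 or a.extra_episode_lambda < 0:
                raise ConfigError(f"{tag}: episode rates must be >= 0")
            if a.min_episodes > 0 and len(a.episode_end_anchors) < a.min_episodes:
                raise ConfigError(
                    f"{tag}: needs at least min_episodes episode_end_anchors")
            if any(e > 0 for e in a.episode_end_anchors):
                raise ConfigError(f"{tag}: episode_end_anchors must be <= 0")
            if a.duration_median < 1.0:
                raise ConfigError(f"{tag}.duration_median: episode durations must be >= 1 day")
            if not (0.0 <= a.icu_prob <= 1.0):
                raise ConfigError(f"{tag}.icu_prob must be in [0, 1]")
            if not (0.0 <= a.ambulatory_fraction <= 1.0):
                raise ConfigError(f"{tag}.ambulatory_fraction must be in [0, 1]")
            if a.mortality_rate < 0:
                raise ConfigError(f"{tag}.mortality_rate must be >= 0")
            if any(r < 0 for r in a.point_rates.values()):
                raise ConfigError(f"{tag}.point_rates must be >= 0")
        if self.window_days <= 0:
            raise ConfigError("window_days must be > 0")
        if not (0 < self.followup_min_days <= self.followup_max_days):
            raise ConfigError("followup bounds must satisfy 0 < min <= max")


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # Independent substream per patient: generation is order-independent.
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index]))


def _sample_episodes(rng: np.random.Generator, p: ArchetypeParams,
                     window: int) -> list[tuple[int, int, bool]]:
    """Sample non-overlapping hospital episodes, most recent first.

    Episode ``k`` ends near ``episode_end_anchors[k]`` (Gaussian jitter);
    durations are log-normal.  Returns half-open ``(start, end,
    is_exacerbation)`` intervals with ``-window <= start < end <= 0``.
    """
    if not p.episode_end_anchors:
        return []
    n_ep = p.min_episodes + int(rng.poisson(p.extra_episode_lambda))
    n_ep = min(max(n_ep, 0), len(p.episode_end_anchors))
    mu = math.log(p.duration_median)
    episodes: list[tuple[int, int, bool]] = []
    for k in range(n_ep):
        forced = k < p.forced_recent_exacerbations
        end = int(round(p.episode_end_anchors[k]
                        + rng.normal(0.0, p.anchor_jitter_sd)))
        end = min(end, 0)
        if forced and end < -(p.recent_window - 1):
            end = -(p.recent_window - 1)
        if episodes:  # keep episodes disjoint, most recent first
            end = min(end, episodes[-1][0] - 1)
        dur = max(1, int(round(rng.lognormal(mu, p.duration_sigma))))
        start = end - dur
        if forced:
            start = max(start, -p.recent_window)
        start = max(start, -window)
        if start >= end:
            continue
        is_exac = forced or (rng.random() < p.exacerbation_prob)
        episodes.append((start, end, is_exac))
    return episodes


def generate_patient(archetype: int, params: ArchetypeParams,
                     rng: np.random.Generator, window_days: int = 365,
                     ambulatory: bool | None = None) -> list[tuple[str, int, int]]:
    """Generate one patient's pre-index event list (type, start_day, end_day).

    ``archetype`` is 1-based.  When ``ambulatory`` is None it is drawn from
    ``params.ambulatory_fraction``.  The returned list always contains the
    index event at day 0 and a therapy-marker point event, plus hospital
    episodes, nested ICU stays, oxygen start and Poisson point events.
    """
    if archetype not in (1, 2, 3, 4):
        raise ValueError(f"unknown archetype: {archetype!r}")
    window = int(window_days)
    if ambulatory is None:
        ambulatory = rng.random() < params.ambulatory_fraction

    events: list[tuple[str, int, int]] = [(INDEX_EVENT, 0, 1)]
    # Qualifying-therapy marker: one dispensing somewhere in the window.
    marker_day = -int(rng.integers(1, window + 1))
    events.append((COPD_MARKER, marker_day, marker_day + 1))

    if not ambulatory:
        for start, end, is_exac in _sample_episodes(rng, params, window):
            events.append((EXACERBATION if is_exac else CARDIO_RESP, start, end))
            if rng.random() < params.icu_prob:
                icu_days = min(end - start, 1 + int(rng.poisson(params.icu_days_lambda)))
                events.append((ICU, start, start + icu_days))

    if rng.random() < params.oxygen_prob:
        lead = 1 + int(rng.poisson(params.oxygen_lead_lambda))
        day = max(-window, -lead)
        events.append((OXYGEN_START, day, day + 1))

    for ev_type, rate in params.point_rates.items():
        n = int(rng.poisson(rate * window / 365.0))
        for day in rng.integers(-window, 0, size=n):
            events.append((ev_type, int(day), int(day) + 1))
    return events


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic cohort.

    Returns ``(events, covariates, truth)``:

    * ``events`` — long table with columns ``patient_id, event_type,
      start_day, end_day`` (half-open integer day intervals);
    * ``covariates`` — one row per patient: demographics, comorbidity
      flags, prescriber/setting of initiation, ``death_day`` (NaN if alive
      at end of follow-up) and ``followup_end_day``;
    * ``truth`` — ``patient_id, archetype`` ground-truth labels.

    Deterministic given ``config.rng_seed``; patients are generated from
    independent substreams, so the draw for patient *i* does not depend on
    how many patients precede it.
    """
    cum = np.cumsum(np.asarray(config.cluster_weights, dtype=float))
    event_rows: list[tuple[int, str, int, int]] = []
    cov_rows: list[dict] = []
    truth_rows: list[tuple[int, int]] = []

    for i in range(config.n_patients):
        pid = i + 1
        rng = _patient_rng(config.rng_seed, i)
        archetype = 1 + int(np.searchsorted(cum, rng.random(), side="right"))
        archetype = min(archetype, 4)  # guard float edge
        params = config.archetypes[archetype - 1]
        ambulatory = rng.random() < params.ambulatory_fraction

        for ev_type, s, e in generate_patient(archetype, params, rng,
                                              config.window_days, ambulatory):
            event_rows.append((pid, ev_type, s, e))

        cp = params.covariates
        age = float(np.clip(rng.normal(cp.age_mean, cp.age_sd),
                            config.min_age, config.max_age))
        flags = {k: int(rng.random() < cp.comorbidity_prevalence.get(k, 0.0))
                 for k in COMORBIDITY_FLAGS}
        u = rng.random()
        if u < cp.hospital_prescriber_prob:
            prescriber = "hospital_practitioner"
        elif u < cp.hospital_prescriber_prob + cp.private_pulmo_prescriber_prob:
            prescriber = "private_pulmonologist"
        else:
            prescriber = "other"
        followup_end = int(rng.integers(config.followup_min_days,
                                        config.followup_max_days + 1))
        scale_days = 365.0 / params.mortality_rate if params.mortality_rate > 0 else np.inf
        t_death = rng.exponential(scale_days) if np.isfinite(scale_days) else np.inf
        death_day = max(1, int(math.ceil(t_death))) if t_death <= followup_end else np.nan

        cov_rows.append({
            "patient_id": pid,
            "age": round(age, 1),
            "sex": "male" if rng.random() < cp.male_prob else "female",
            **flags,
            "prescriber": prescriber,
            "setting": "ambulatory" if ambulatory else "hospital",
            "death_day": death_day,
            "followup_end_day": followup_end,
        })
        truth_rows.append((pid, archetype))

    events = pd.DataFrame(event_rows, columns=list(EVENT_COLUMNS))
    covariates = pd.DataFrame(cov_rows)
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "archetype"])
    return events, covariates, truth
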