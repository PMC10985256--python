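"""Synthetic two-visit, two-placement actigraphy cohorts.

The generator emulates the free-living study design the pipeline targets:
an ambulatory Friedreich-ataxia (FRDA) group and an age-matched control
group wear waist and wrist sensors for 7 days during waking hours (16 h/day)
at a baseline and a 1-year follow-up visit, with 60-s count epochs.

The behavioural model is a minute-resolution first-order Markov chain over
activity states {sedentary, light, moderate, vigorous}; per-state vertical
counts are drawn from log-normals truncated to the state's cut-point band
(so generated intensity labels are exactly recoverable from the counts),
lateral axes are noisy scalings of the vertical axis, and steps are Poisson
in the light and moderate/vigorous states only.  Group x placement occupancy
targets, step-rate targets and clinical-score distributions are calibrated
to published cohort means for this design; an ataxia-severity covariate
(SARA) tilts the sedentary dwell and MVPA share through a logistic link so
clinical-digital correlations emerge, and a programmed annual decline shifts
FRDA profiles toward sedentary behaviour at follow-up while leaving controls
unchanged.  Day-level random effects give realistic (imperfect) odd/even
split-half reliability; explicit >= 90-min zero-count blocks are inserted so
non-wear detection has true positives.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so identical configurations reproduce bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr, ndtri

from .epochs import (
    DiaryLog,
    EpochSeries,
    SubjectRecord,
    write_clinical_table,
    write_diary_csv,
    write_epoch_csv,
)

__all__ = [
    "ActivityProfile",
    "CohortConfig",
    "SimulatedSeries",
    "SimulatedSubject",
    "Cohort",
    "sample_subject",
    "simulate_epoch_series",
    "simulate_cohort",
    "steps_calibration",
]

NONWEAR = -1
STATE_NAMES = ("sedentary", "light", "moderate", "vigorous")

#: Stationary occupancy targets over (sedentary, light, moderate, vigorous),
#: per group x placement, anchored to published cohort means for this design.
BASE_OCCUPANCY: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("FRDA", "waist"): (0.813, 0.160, 0.0245, 0.0025),
    ("CTR", "waist"): (0.677, 0.218, 0.0950, 0.0100),
    ("FRDA", "wrist"): (0.429, 0.258, 0.2850, 0.0280),
    ("CTR", "wrist"): (0.317, 0.249, 0.3950, 0.0390),
}

#: Mean steps/min targets used to calibrate per-state step rates.
STEP_TARGETS: dict[tuple[str, str], float] = {
    ("FRDA", "waist"): 7.7,
    ("CTR", "waist"): 16.0,
    ("FRDA", "wrist"): 14.0,
    ("CTR", "wrist"): 20.2,
}

#: Per-state truncated log-normal count parameters (median, sigma, low, high)
#: for the vertical axis, per placement.  Bands coincide with the default
#: cut-points; the sedentary band starts at 1 CPM because in this generator
#: true zero counts occur only during non-wear.
COUNT_PARAMS: dict[str, list[tuple[float, float, int, int]]] = {
    "waist": [
        (25.0, 1.00, 1, 99),
        (450.0, 0.80, 100, 1951),
        (2400.0, 0.35, 1952, 5724),
        (6500.0, 0.25, 5725, 20000),
    ],
    "wrist": [
        (60.0, 0.90, 1, 99),
        (900.0, 0.70, 100, 1951),
        (3400.0, 0.35, 1952, 5724),
        (7000.0, 0.25, 5725, 20000),
    ],
}


@dataclass
class ActivityProfile:
    """Per-subject x placement x visit generating process.

    ``occupancy`` is the stationary distribution of the minute-state chain;
    the transition matrix is the persistence mixture
    ``kappa * I + (1 - kappa) * 1 pi^T``, whose stationary law is exactly
    ``pi`` for any persistence ``kappa`` in [0, 1).
    """

    occupancy: np.ndarray
    placement: str
    persistence: float = 0.85
    count_median: np.ndarray = None
    count_sigma: np.ndarray = None
    count_low: np.ndarray = None
    count_high: np.ndarray = None
    lateral_ratios: tuple[float, float] = (0.55, 0.40)
    lateral_sigma: float = 0.25
    step_rates: np.ndarray = None  # steps/min per state; 0 for sedentary

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (4,) or np.any(self.occupancy < 0):
            raise ValueError("occupancy must be 4 non-negative probabilities")
        if not np.isclose(self.occupancy.sum(), 1.0):
            raise ValueError("occupancy must sum to 1")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must be in [0, 1)")
        if self.count_median is None:
            params = COUNT_PARAMS[self.placement]
            self.count_median = np.array([p[0] for p in params])
            self.count_sigma = np.array([p[1] for p in params])
            self.count_low = np.array([p[2] for p in params])
            self.count_high = np.array([p[3] for p in params])
        if self.step_rates is None:
            self.step_rates = np.zeros(4)
        self.step_rates = np.asarray(self.step_rates, dtype=float)
        if np.any(self.step_rates < 0):
            raise ValueError("step rates must be non-negative")

    @property
    def transition_matrix(self) -> np.ndarray:
        k = self.persistence
        return k * np.eye(4) + (1.0 - k) * np.outer(np.ones(4), self.occupancy)

    @property
    def stationary(self) -> np.ndarray:
        return self.occupancy.copy()


@dataclass
class CohortConfig:
    """Study-design and calibration parameters of the synthetic cohort.

    Defaults encode the emulated protocol: 26 FRDA / 13 controls, 7 days of
    waking-hour wear (06:00-22:00), two visits 52 weeks apart, SARA severity
    17.2 +/- 6.0 in FRDA and a mean 1-year SARA worsening of +1.5 +/- 1.5
    points with an accompanying shift of activity toward sedentary states.
    """

    n_frda: int = 26
    n_ctr: int = 13
    days: int = 7
    seed: int = 0
    start_date: str = "2022-03-07"  # a Monday, so odd/even weekdays balance
    followup_lag_weeks: int = 52
    waking_start_hour: int = 6
    waking_hours: int = 16

    sara_mean: float = 17.2
    sara_sd: float = 6.0
    sara_decline_mean: float = 1.5
    sara_decline_sd: float = 1.5

    # logistic-link coefficients (logit scale)
    sev_slope_sed: float = 0.45
    sev_slope_mvpa: float = -0.35
    subject_sd_sed: float = 0.28
    subject_sd_mvpa: float = 0.25
    day_sd_sed: float = 0.40
    visit_sd_sed: float = 0.08
    decline_sed_shift: float = 0.10
    decline_mvpa_shift: float = -0.10
    annual_decline: float = 1.0  # scales both SARA worsening and activity shift

    persistence: float = 0.85
    step_rate_ratio: float = 3.0
    nonwear_prob_per_day: float = 0.35
    nonwear_len_range: tuple[int, int] = (90, 150)

    def __post_init__(self) -> None:
        if min(self.n_frda, self.n_ctr) < 2:
            raise ValueError("need at least 2 subjects per group")
        for name in ("sara_sd", "subject_sd_sed", "subject_sd_mvpa", "day_sd_sed", "visit_sd_sed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def steps_calibration(
    p_light: float,
    p_mvpa: float,
    target_steps_per_min: float,
    ratio: float = 3.0,
) -> tuple[float, float]:
    """Solve per-state step rates from state occupancies and a steps/min target.

    With the MVPA rate constrained to ``ratio`` times the light rate, the
    identity ``rate_light * p_light + rate_mvpa * p_mvpa = target`` gives
    ``rate_light = target / (p_light + ratio * p_mvpa)``.  Zero MVPA
    occupancy puts all steps in the light state; an infeasible (negative)
    solution is an error.
    """
    if target_steps_per_min < 0:
        raise ValueError("steps/min target must be non-negative")
    if p_light < 0 or p_mvpa < 0:
        raise ValueError("occupancies must be non-negative")
    denom = p_light + ratio * p_mvpa
    if denom <= 0:
        if target_steps_per_min == 0:
            return 0.0, 0.0
        raise ValueError("no walking-capable occupancy: step target unreachable")
    rate_light = target_steps_per_min / denom
    return rate_light, ratio * rate_light


from functools import lru_cache

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@lru_cache(maxsize=256)
def _logit_mean_intercept(p0: float, sigma: float) -> float:
    """Intercept c such that E[expit(logit(p0) + c + sigma*Z)] = p0, Z ~ N(0,1).

    A symmetric logit-scale perturbation shrinks the mean of a probability
    toward 1/2 (Jensen's inequality); this correction keeps the *expected*
    occupancy of a noisy profile on its calibration target.
    """
    if sigma == 0.0:
        return 0.0
    a = float(logit(p0))

    def mean_at(c: float) -> float:
        return float(np.dot(_GH_WEIGHTS, expit(a + c + sigma * _GH_NODES)))

    from scipy.optimize import brentq

    return float(brentq(lambda c: mean_at(c) - p0, -3.0, 3.0, xtol=1e-10))


def _tilt_occupancy(base: np.ndarray, d_sed: float, d_mvpa: float) -> np.ndarray:
    """Shift a 4-state occupancy on the logit scale: ``d_sed`` moves the
    sedentary probability, ``d_mvpa`` moves MVPA's share of non-sedentary
    time; the moderate:vigorous split is preserved."""
    base = np.asarray(base, dtype=float)
    if base[0] >= 1.0 or base[0] <= 0.0:  # degenerate: nothing to tilt
        return base.copy()
    p_sed = float(expit(logit(base[0]) + d_sed))
    mvpa_base = base[2] + base[3]
    if mvpa_base > 0.0:
        mv_share = float(expit(logit(mvpa_base / (1.0 - base[0])) + d_mvpa))
        v_frac = base[3] / mvpa_base
    else:
        mv_share = 0.0
        v_frac = 0.0
    rest = 1.0 - p_sed
    p_mvpa = rest * mv_share
    return np.array(
        [p_sed, rest - p_mvpa, p_mvpa * (1.0 - v_frac), p_mvpa * v_frac]
    )


@dataclass
class SimulatedSeries:
    """An epoch series plus its generating ground truth."""

    series: EpochSeries
    states: np.ndarray  # per-epoch state code; -1 = non-wear (incl. night)
    nonwear_blocks: list[tuple[int, int]]  # inserted daytime blocks [start, end)
    day_effects: np.ndarray

    @property
    def true_wear(self) -> np.ndarray:
        return self.states >= 0

    def occupancy_realized(self) -> np.ndarray:
        worn = self.states[self.states >= 0]
        return np.bincount(worn, minlength=4) / max(worn.size, 1)


@dataclass
class SimulatedSubject:
    baseline: SubjectRecord
    followup: SubjectRecord
    profiles: dict[tuple[str, str], ActivityProfile]  # (placement, visit) -> profile
    z_baseline: float
    z_followup: float


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float, low: int, high: int, size: int
) -> np.ndarray:
    mu = np.log(median)
    a = (np.log(low) - mu) / sigma
    b = (np.log(high) - mu) / sigma
    u = rng.uniform(ndtr(a), ndtr(b), size)
    x = np.exp(mu + sigma * ndtri(u))
    return np.clip(np.rint(x), low, high).astype(np.int64)


def _clinical_frda(rng: np.random.Generator, sid: str, cfg: CohortConfig) -> dict:
    sara = float(np.clip(rng.normal(cfg.sara_mean, cfg.sara_sd), 6.0, 36.0))
    gait = float(np.clip(np.rint(sara * 7.0 / 40.0 + rng.normal(0, 0.8)), 0, 7))
    onset = float(np.clip(rng.normal(15.4, 4.9), 7.0, 24.0))
    duration = float(np.clip(rng.normal(11.7, 6.9), 1.0, 28.0))
    age = float(np.clip(onset + duration, 18.0, 45.0))
    t8_missing = rng.random() < expit((sara - cfg.sara_mean) / 3.0)
    return dict(
        subject_id=sid,
        group="FRDA",
        sex="M" if rng.random() < 16 / 26 else "F",
        age=round(age, 1),
        bmi=round(float(rng.normal(23.0, 3.0)), 1),
        sara=round(sara, 1),
        sara_gait=gait,
        mfars=round(float(np.clip(2.28 * sara + 11.3 + rng.normal(0, 4.0), 0, 93)), 1),
        fars_e=round(float(np.clip(0.80 * sara + rng.normal(0, 2.0), 0, 36)), 1),
        adl=round(float(np.clip(0.90 * sara - 3.2 + rng.normal(0, 2.0), 0, 36)), 1),
        ccfs=round(float(1225.0 + 15.5 * (sara - cfg.sara_mean) + rng.normal(0, 60.0)), 0),
        t8mwt=np.nan if t8_missing else round(float(4.0 + 0.27 * sara + rng.normal(0, 1.0)), 1),
        gaa1=float(np.rint(np.clip(rng.normal(700, 180), 120, 1300))),
        gaa2=float(np.rint(np.clip(rng.normal(900, 220), 300, 1700))),
        age_at_onset=round(onset, 1),
        disease_duration=round(duration, 1),
    )


def _clinical_ctr(rng: np.random.Generator, sid: str) -> dict:
    return dict(
        subject_id=sid,
        group="CTR",
        sex="F" if rng.random() < 7 / 13 else "M",
        age=round(float(np.clip(rng.normal(25.9, 3.1), 21.0, 31.0)), 1),
        bmi=round(float(rng.normal(22.0, 2.5)), 1),
        sara=float(rng.binomial(1, 0.3)),
        sara_gait=0.0,
        mfars=float(rng.binomial(1, 0.3)),
        fars_e=0.0,
        adl=0.0,
        ccfs=round(float(rng.normal(947.0, 150.0)), 0),
        t8mwt=round(float(rng.normal(4.2, 0.6)), 1),
        gaa1=np.nan,
        gaa2=np.nan,
        age_at_onset=np.nan,
        disease_duration=np.nan,
    )


def sample_subject(
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str = "SYN01",
) -> SimulatedSubject:
    """Draw one subject: clinical records for both visits plus an activity
    profile per placement x visit.

    Severity (SARA, FRDA only) tilts the sedentary dwell up and the MVPA
    share down through the configured logistic link; a shared subject-level
    random effect keeps waist and wrist measures of the same subject
    correlated.  The follow-up FRDA profile carries the programmed annual
    decline (controls are unshifted apart from visit noise).
    """
    if group not in ("FRDA", "CTR"):
        raise ValueError(f"unknown group {group!r}")
    dec = config.annual_decline
    if group == "FRDA":
        base_clin = _clinical_frda(rng, subject_id, config)
        sara_b = base_clin["sara"]
        sara_delta = float(rng.normal(config.sara_decline_mean * dec, config.sara_decline_sd))
        sara_f = float(np.clip(sara_b + sara_delta, 0.0, 40.0))
        z_b = (sara_b - config.sara_mean) / config.sara_sd
        z_f = (sara_f - config.sara_mean) / config.sara_sd
        fu_clin = dict(
            base_clin,
            sara=round(sara_f, 1),
            sara_gait=float(np.clip(np.rint(sara_f * 7.0 / 40.0 + rng.normal(0, 0.8)), 0, 7)),
            mfars=round(float(np.clip(base_clin["mfars"] + rng.normal(0.8 * dec, 4.6), 0, 93)), 1),
            adl=round(float(np.clip(base_clin["adl"] + rng.normal(1.0 * dec, 2.4), 0, 36)), 1),
            ccfs=round(base_clin["ccfs"] + float(rng.normal(6.0 * dec, 50.0)), 0),
            age=round(base_clin["age"] + 1.0, 1),
        )
    else:
        base_clin = _clinical_ctr(rng, subject_id)
        z_b = z_f = 0.0
        fu_clin = dict(
            base_clin,
            ccfs=round(base_clin["ccfs"] + float(rng.normal(0.0, 40.0)), 0),
            age=round(base_clin["age"] + 1.0, 1),
        )

    u_sed = float(rng.normal(0.0, config.subject_sd_sed))
    u_mv = float(rng.normal(0.0, config.subject_sd_mvpa))
    visit_eff = {v: float(rng.normal(0.0, config.visit_sd_sed)) for v in ("baseline", "followup")}

    # variance of the subject-level logit perturbations, for the mean-
    # preserving Jensen correction (day-level noise is corrected separately
    # at simulation time)
    sev_var = 1.0 if group == "FRDA" else 0.0
    sigma_sed = float(
        np.sqrt(sev_var * config.sev_slope_sed**2 + config.subject_sd_sed**2 + config.visit_sd_sed**2)
    )
    sigma_mv = float(np.sqrt(sev_var * config.sev_slope_mvpa**2 + config.subject_sd_mvpa**2))

    profiles: dict[tuple[str, str], ActivityProfile] = {}
    for placement in ("waist", "wrist"):
        base = np.array(BASE_OCCUPANCY[(group, placement)])
        rate_l, rate_m = steps_calibration(
            base[1], base[2] + base[3], STEP_TARGETS[(group, placement)], config.step_rate_ratio
        )
        c_sed = _logit_mean_intercept(base[0], sigma_sed)
        c_mv = _logit_mean_intercept(float((base[2] + base[3]) / (1.0 - base[0])), sigma_mv)
        for visit, z in (("baseline", z_b), ("followup", z_f)):
            declining = dec if (group == "FRDA" and visit == "followup") else 0.0
            d_sed = (
                config.sev_slope_sed * z
                + u_sed
                + visit_eff[visit]
                + c_sed
                + config.decline_sed_shift * declining
            )
            d_mv = config.sev_slope_mvpa * z + u_mv + c_mv + config.decline_mvpa_shift * declining
            profiles[(placement, visit)] = ActivityProfile(
                occupancy=_tilt_occupancy(base, d_sed, d_mv),
                placement=placement,
                persistence=config.persistence,
                step_rates=np.array([0.0, rate_l, rate_m, rate_m]),
            )

    mk = lambda clin, visit: SubjectRecord(visit=visit, **clin)
    return SimulatedSubject(
        baseline=mk(base_clin, "baseline"),
        followup=mk(fu_clin, "followup"),
        profiles=profiles,
        z_baseline=z_b,
        z_followup=z_f,
    )


def simulate_epoch_series(
    profile: ActivityProfile,
    days: int,
    rng: np.random.Generator,
    subject_id: str = "SYN01",
    visit: str = "baseline",
    start_date: str = "2022-03-07",
    day_effects: np.ndarray | None = None,
    waking_start_hour: int = 6,
    waking_hours: int = 16,
    nonwear_prob_per_day: float = 0.35,
    nonwear_len_range: tuple[int, int] = (90, 150),
    day_bias_sd: float = 0.0,
) -> SimulatedSeries:
    """Simulate a contiguous multi-day 60-s epoch series from a profile.

    Each calendar day holds a minute-state Markov chain over the waking
    window; outside the window the device is off (zero counts).  With
    probability ``nonwear_prob_per_day`` a daytime non-wear block of
    90-150 min of true zeros is inserted, giving the non-wear detector
    ground-truth positives.  ``day_effects`` (logit shifts of the sedentary
    dwell, one per day) lets a caller share day-to-day behavioural
    variability across placements.
    """
    n_day = 1440
    n = days * n_day
    if day_effects is None:
        day_effects = np.zeros(days)
    day_effects = np.asarray(day_effects, dtype=float)
    if day_effects.size != days:
        raise ValueError("day_effects must have one entry per day")

    states = np.full(n, NONWEAR, dtype=np.int64)
    w0 = waking_start_hour * 60
    w_len = waking_hours * 60
    kappa = profile.persistence
    nonwear_blocks: list[tuple[int, int]] = []

    # mean-preserving correction for the day-level logit noise, so the
    # realized occupancy matches the profile's stationary law on average
    c_day = _logit_mean_intercept(float(profile.occupancy[0]), float(day_bias_sd))

    for d in range(days):
        pi_day = _tilt_occupancy(profile.occupancy, day_effects[d] + c_day, 0.0)
        redraw = rng.random(w_len) < (1.0 - kappa)
        redraw[0] = True
        draws = rng.choice(4, size=w_len, p=pi_day)
        idx = np.where(redraw, np.arange(w_len), 0)
        np.maximum.accumulate(idx, out=idx)
        day_states = draws[idx]

        if rng.random() < nonwear_prob_per_day:
            lo, hi = nonwear_len_range
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, w_len - length + 1))
            day_states[start : start + length] = NONWEAR
            g0 = d * n_day + w0 + start
            nonwear_blocks.append((g0, g0 + length))
        states[d * n_day + w0 : d * n_day + w0 + w_len] = day_states

    axis1 = np.zeros(n, dtype=np.int64)
    axis2 = np.zeros(n, dtype=np.int64)
    axis3 = np.zeros(n, dtype=np.int64)
    steps = np.zeros(n, dtype=np.int64)
    r2, r3 = profile.lateral_ratios
    for s in range(4):
        where = np.flatnonzero(states == s)
        if not where.size:
            continue
        a1 = _truncated_lognormal(
            rng,
            profile.count_median[s],
            profile.count_sigma[s],
            int(profile.count_low[s]),
            int(profile.count_high[s]),
            where.size,
        )
        axis1[where] = a1
        axis2[where] = np.rint(a1 * r2 * np.exp(rng.normal(0, profile.lateral_sigma, where.size)))
        axis3[where] = np.rint(a1 * r3 * np.exp(rng.normal(0, profile.lateral_sigma, where.size)))
        if profile.step_rates[s] > 0:
            steps[where] = rng.poisson(profile.step_rates[s], where.size)

    series = EpochSeries(
        subject_id=subject_id,
        placement=profile.placement,
        visit=visit,
        start_time=pd.Timestamp(start_date),
        axis1=axis1,
        axis2=axis2,
        axis3=axis3,
        steps=steps,
        epoch_length=60,
    )
    return SimulatedSeries(series, states, nonwear_blocks, day_effects)


@dataclass
class Cohort:
    """A simulated cohort: subjects x 2 placements x 2 visits."""

    config: CohortConfig
    subjects: list[SimulatedSubject]
    series: dict[tuple[str, str, str], SimulatedSeries]  # (sid, placement, visit)

    @property
    def clinical_records(self) -> list[SubjectRecord]:
        out = []
        for s in self.subjects:
            out.extend([s.baseline, s.followup])
        return out

    def diaries(self) -> dict[str, DiaryLog]:
        """Diary logs reporting the waking window worn each recording day."""
        cfg = self.config
        out: dict[str, DiaryLog] = {}
        for s in self.subjects:
            sid = s.baseline.subject_id
            intervals = []
            for visit in ("baseline", "followup"):
                sim = self.series[(sid, "waist", visit)]
                day0 = sim.series.start_time.normalize()
                for d in range(cfg.days):
                    on = day0 + pd.Timedelta(days=d, hours=cfg.waking_start_hour)
                    intervals.append((on, on + pd.Timedelta(hours=cfg.waking_hours)))
            out[sid] = DiaryLog(sid, intervals)
        return out

    def ground_truth(self) -> dict:
        truth: dict = {"subjects": {}}
        for s in self.subjects:
            sid = s.baseline.subject_id
            entry = {
                "group": s.baseline.group,
                "sara_baseline": s.baseline.sara,
                "sara_followup": s.followup.sara,
                "series": {},
            }
            for (sid2, placement, visit), sim in self.series.items():
                if sid2 != sid:
                    continue
                entry["series"][f"{placement}_{visit}"] = {
                    "occupancy": sim.occupancy_realized().tolist(),
                    "nonwear_blocks": [list(b) for b in sim.nonwear_blocks],
                }
            truth["subjects"][sid] = entry
        return truth

    def write(self, out_dir) -> None:
        """Write the cohort through the public file interfaces: one epoch CSV
        per series, a diary CSV, a clinical CSV, and a ground-truth JSON."""
        out = Path(out_dir)
        (out / "epochs").mkdir(parents=True, exist_ok=True)
        for (sid, placement, visit), sim in self.series.items():
            write_epoch_csv(sim.series, out / "epochs" / f"{sid}_{placement}_{visit}.csv")
        write_diary_csv(list(self.diaries().values()), out / "diary.csv")
        write_clinical_table(self.clinical_records, out / "clinical.csv")
        (out / "truth.json").write_text(json.dumps(self.ground_truth(), indent=1))


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full cohort described by ``config`` (seed included).

    Baseline and follow-up recordings start 52 weeks apart on the same
    weekday; day-level behavioural effects are shared between the waist and
    wrist devices of a visit, since both are worn simultaneously.
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_frda + config.n_ctr
    children = ss.spawn(n_total)

    base_start = pd.Timestamp(config.start_date)
    fu_start = base_start + pd.Timedelta(weeks=config.followup_lag_weeks)

    subjects: list[SimulatedSubject] = []
    series: dict[tuple[str, str, str], SimulatedSeries] = {}
    labels = [("FRDA", f"FRDA{i + 1:02d}") for i in range(config.n_frda)] + [
        ("CTR", f"CTR{i + 1:02d}") for i in range(config.n_ctr)
    ]
    for (group, sid), child in zip(labels, children):
        rng = np.random.default_rng(child)
        subj = sample_subject(group, config, rng, subject_id=sid)
        subjects.append(subj)
        for visit, start in (("baseline", base_start), ("followup", fu_start)):
            day_effects = rng.normal(0.0, config.day_sd_sed, config.days)
            for placement in ("waist", "wrist"):
                sim = simulate_epoch_series(
                    subj.profiles[(placement, visit)],
                    config.days,
                    rng,
                    subject_id=sid,
                    visit=visit,
                    start_date=str(start.date()),
                    day_effects=day_effects,
                    waking_start_hour=config.waking_start_hour,
                    waking_hours=config.waking_hours,
                    nonwear_prob_per_day=config.nonwear_prob_per_day,
                    nonwear_len_range=config.nonwear_len_range,
                    day_bias_sd=config.day_sd_sed,
                )
                series[(sid, placement, visit)] = sim
    return Cohort(config, subjects, series)
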