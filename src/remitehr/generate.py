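"""Synthetic longitudinal EHR generator.

Emulates the statistical structure the downstream analysis assumes: an
exposure window (first positive SARS-CoV-2 swab for exposed patients, a
latent anchor date for unexposed ones), background care processes (outpatient
visits, routine glucose and HbA1c testing), incident diabetes emitted as
computable-phenotype-satisfiable event patterns, and latent remitters whose
post-detection HbA1c trajectories drop below the diagnostic threshold off
glucose-lowering medication.  A configurable multiplicative effect of
exposure on the remission probability (``true_remission_rr``) is the ground
truth that parameter-recovery tests target.

Design notes
------------
* All stochastic draws come from one ``numpy`` Generator; a fixed seed gives
  byte-identical tables.
* Event counts are Poisson with per-patient rates; laboratory values are
  Gaussian around state-dependent means (non-diabetic, diabetic, remitted),
  truncated to the type invariants.
* Post-index laboratory intensity of exposed patients is scaled by
  ``surveillance_ratio`` (optionally only for hospitalized exposed patients),
  which is the mechanism behind surveillance-bias experiments: each glucose
  test of a patient without diabetes has a small probability of a transient
  hyperglycemic spike, so more testing means more false incident-diabetes
  detections, and those patients overwhelmingly look like remitters.
* Unexposed patients' laboratory dates inside the exposure window are
  concentrated at or before their anchor month so that frequency-matched
  index assignment mostly lands on or before the anchor; assignments that
  land after a patient's diabetes onset are excluded downstream as prevalent
  disease, mirroring the real-data mechanism.
* A ground-truth sidecar table (latent flags, planned detection date) is
  written for tests only; the analysis pipeline never reads it.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .config import ConfigurationError, GeneratorConfig
from .dataset import EhrDataset, LAB_KINDS

EPOCH = dt.date(1970, 1, 1)

#: predominant-variant eras (calendar month ranges, closed on both ends)
ERAS = (
    ("wild_type", dt.date(2020, 3, 1), dt.date(2021, 4, 30)),
    ("alpha", dt.date(2021, 5, 1), dt.date(2021, 7, 31)),
    ("delta", dt.date(2021, 8, 1), dt.date(2021, 12, 31)),
    ("omicron", dt.date(2022, 1, 1), dt.date(2022, 6, 30)),
)

#: share of index dates per era among exposed patients (wild-type-heavy wave
#: structure of the study window)
ERA_WEIGHTS = np.array([0.659, 0.064, 0.244, 0.033])

BACKGROUND_ICD = np.array(["I10", "J06.9", "M54.5", "K21.9"])
DIABETES_ICD = np.array(["E10.9", "E11.9", "E13.9"])
DIABETES_ICD_W = np.array([0.10, 0.85, 0.05])


def _day(d: dt.date) -> int:
    return (d - EPOCH).days


def _to_ts(days: np.ndarray) -> pd.Series:
    return pd.to_datetime(np.asarray(days, dtype="int64"), unit="D")


def _month_end(days: np.ndarray) -> np.ndarray:
    """Last day of the month containing each epoch-day."""
    d64 = np.asarray(days, dtype="int64").astype("datetime64[D]")
    nxt = (d64.astype("datetime64[M]") + 1).astype("datetime64[D]")
    return nxt.astype("int64") - 1


def _month_start(days: np.ndarray) -> np.ndarray:
    d64 = np.asarray(days, dtype="int64").astype("datetime64[D]")
    return d64.astype("datetime64[M]").astype("datetime64[D]").astype("int64")


def _poisson_times(
    rng: np.random.Generator,
    start: np.ndarray,
    stop: np.ndarray,
    rate_per_year: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson event days per patient on [start, stop).

    Returns (patient_index, day) arrays.
    """
    span = np.maximum(stop - start, 0)
    lam = span / 365.25 * rate_per_year
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(len(span)), counts)
    u = rng.random(counts.sum())
    days = (np.repeat(start, counts) + u * np.repeat(span, counts)).astype(np.int64)
    return idx, days


def _trunc_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, n), lo, hi)


class _State:
    """Latent per-patient quantities shared across emission steps."""

    def __init__(self, n: int):
        self.n = n
        self.exposed = np.zeros(n, bool)
        self.anchor = np.zeros(n, np.int64)  # t0: swab day / latent anchor day
        self.hospitalized = np.zeros(n, bool)
        self.prevalent = np.zeros(n, bool)
        self.incident = np.zeros(n, bool)
        self.remitter = np.zeros(n, bool)
        self.observable = np.zeros(n, bool)
        self.d1 = np.full(n, -1, np.int64)  # first abnormal lab day
        self.det = np.full(n, -1, np.int64)  # planned detection day (2nd abnormal)
        self.onset = np.full(n, 10**9, np.int64)  # remission onset day
        self.t1 = np.full(n, -1, np.int64)
        self.t2 = np.full(n, -1, np.int64)
        self.lab_based = np.zeros(n, bool)  # detection pattern uses two HbA1c


def _a1c_values(
    rng: np.random.Generator, st: _State, idx: np.ndarray, days: np.ndarray
) -> np.ndarray:
    """HbA1c along each patient's latent glycemic trajectory, percent."""
    v = _trunc_normal(rng, len(idx), 5.5, 0.3, 4.0, 6.4)  # healthy baseline
    inc = st.incident[idx]
    pre = inc & (days < st.d1[idx])
    v[pre] = _trunc_normal(rng, int(pre.sum()), 6.0, 0.25, 4.5, 6.4)
    dia = inc & (days >= st.d1[idx]) & (days < st.onset[idx])
    v[dia] = _trunc_normal(rng, int(dia.sum()), 7.3, 0.6, 6.5, 13.0)
    rem = inc & st.remitter[idx] & (days >= st.onset[idx])
    v[rem] = _trunc_normal(rng, int(rem.sum()), 5.9, 0.3, 4.5, 6.4)
    prev = st.prevalent[idx]
    v[prev] = _trunc_normal(rng, int(prev.sum()), 7.5, 1.0, 6.5, 14.0)
    return np.round(v, 1)


def _glucose_values(
    rng: np.random.Generator,
    st: _State,
    idx: np.ndarray,
    days: np.ndarray,
    kinds: np.ndarray,
    spike_prob: float,
) -> np.ndarray:
    """Glucose values (mg/dL) along the latent trajectory.

    Patients in a non-diabetic regime occasionally show a transient
    hyperglycemic spike; remitted patients are stable by construction.
    """
    fasting = kinds == "fasting_glucose"
    v = np.where(
        fasting,
        _trunc_normal(rng, len(idx), 95, 10, 70, 125),
        _trunc_normal(rng, len(idx), 100, 15, 70, 199),
    )
    inc = st.incident[idx]
    dia = (inc & (days >= st.d1[idx]) & (days < st.onset[idx])) | st.prevalent[idx]
    v[dia] = _trunc_normal(rng, int(dia.sum()), 165, 40, 80, 400)
    rem = inc & st.remitter[idx] & (days >= st.onset[idx])
    v[rem] = _trunc_normal(rng, int(rem.sum()), 100, 12, 70, 125)
    spiky = ~dia & ~rem
    spike = spiky & (rng.random(len(idx)) < spike_prob)
    v[spike] = _trunc_normal(rng, int(spike.sum()), 230, 20, 200, 320)
    return np.round(v, 0)


def generate_dataset(config: GeneratorConfig) -> EhrDataset:
    """Generate all event tables plus the ground-truth sidecar.

    Deterministic for a fixed ``config.seed``.
    """
    if config.p_prevalent_diabetes + config.p_incident_diabetes > 1.0:
        raise ConfigurationError(
            "p_prevalent_diabetes + p_incident_diabetes must not exceed 1"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    st = _State(n)
    w_lo, w_hi = _day(config.calendar_window[0]), _day(config.calendar_window[1])
    horizon = _day(config.data_horizon)

    # ---- latent structure -------------------------------------------------
    st.exposed = rng.random(n) < config.p_exposed

    era_lo = np.array([max(_day(a), w_lo) for _, a, _ in ERAS])
    era_hi = np.array([min(_day(b), w_hi) for _, b, _ in ERAS])
    valid = era_hi >= era_lo
    weights = ERA_WEIGHTS * valid
    weights = weights / weights.sum()
    era_idx = rng.choice(len(ERAS), size=n, p=weights)
    u = rng.random(n)
    anchor_raw = (era_lo[era_idx] + u * (era_hi[era_idx] - era_lo[era_idx] + 1)).astype(
        np.int64
    )
    # unexposed anchors sit at the end of their month so that frequency-matched
    # index days (uniform within the month) precede all detection events
    st.anchor = np.where(st.exposed, anchor_raw, _month_end(anchor_raw))
    st.anchor = np.clip(st.anchor, w_lo, w_hi)

    st.hospitalized = rng.random(n) < np.where(
        st.exposed,
        config.p_hospitalized_given_exposed,
        config.p_hospitalized_given_unexposed,
    )

    state_u = rng.random(n)
    st.prevalent = state_u < config.p_prevalent_diabetes
    st.incident = (~st.prevalent) & (
        state_u < config.p_prevalent_diabetes + config.p_incident_diabetes
    )

    st.d1 = st.anchor + rng.integers(20, 61, n)
    st.det = st.d1 + rng.integers(30, 91, n)
    st.lab_based = st.incident & (rng.random(n) < 0.6)

    p_rem = config.p_remission_base * np.where(st.exposed, config.true_remission_rr, 1.0)
    st.remitter = st.incident & (rng.random(n) < p_rem)

    # squeeze the qualifying pair inside the data horizon where possible:
    # onset >= det + 90 (latency), t2 - t1 >= 90, both <= horizon
    slack = horizon - (st.det + 180)
    st.observable = st.remitter & (slack >= 0)
    o_extra = np.floor(
        rng.random(n) * (np.minimum(np.maximum(slack, 0), 50) + 1)
    ).astype(np.int64)
    st.onset = np.where(st.observable, st.det + 90 + o_extra, 10**9)
    g_extra = np.floor(
        rng.random(n) * (np.minimum(np.maximum(slack - o_extra, 0), 40) + 1)
    ).astype(np.int64)
    st.t1 = np.where(st.observable, st.onset, -1)
    st.t2 = np.where(st.observable, st.t1 + 90 + g_extra, -1)

    surv_mult = np.where(
        st.exposed & (st.hospitalized | ~config.surveillance_hospitalized_only),
        config.surveillance_ratio,
        1.0,
    )

    # ---- patients ---------------------------------------------------------
    pid = np.array([f"P{i:07d}" for i in range(n)])
    age = _trunc_normal(rng, n, 60.5, 13.0, 22.0, 95.0)
    birth = st.anchor - np.round(age * 365.25).astype(np.int64)
    female = rng.random(n) < 0.11
    race_black = rng.random(n) < 0.22
    race_latinx = rng.random(n) < 0.08
    race_white = rng.random(n) < 0.68
    race_other = rng.random(n) < 0.04
    region = rng.choice(
        np.array(["Midwest", "Southeast", "South", "West", "Other"]),
        size=n,
        p=[0.25, 0.25, 0.20, 0.20, 0.10],
    )
    smoking = rng.choice(
        np.array(["never", "former", "current"]), size=n, p=[0.32, 0.35, 0.33]
    ).astype(object)
    smoking[rng.random(n) < 0.08] = None  # unrecorded; downstream default: never
    charlson = rng.poisson(1.0, n)
    bmi = np.round(_trunc_normal(rng, n, 33.6, 6.6, 12.0, 80.0), 1)
    bmi = np.where(rng.random(n) < config.bmi_missing_rate, np.nan, bmi)
    no_prior_visits = rng.random(n) < 0.03

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "birth_date": _to_ts(birth),
            "sex_at_birth": np.where(female, "female", "male"),
            "race_black": race_black,
            "race_latinx": race_latinx,
            "race_white": race_white,
            "race_other": race_other,
            "region": region,
            "smoking": smoking,
            "charlson": charlson.astype(np.int64),
            "bmi_true": bmi,
        }
    )

    # ---- labs -------------------------------------------------------------
    lab_idx: list[np.ndarray] = []
    lab_day: list[np.ndarray] = []
    lab_kind: list[np.ndarray] = []
    lab_val: list[np.ndarray] = []

    def emit_a1c(idx: np.ndarray, days: np.ndarray, values: np.ndarray | None = None):
        lab_idx.append(idx)
        lab_day.append(days)
        lab_kind.append(np.full(len(idx), "hba1c", dtype=object))
        lab_val.append(_a1c_values(rng, st, idx, days) if values is None else values)

    def emit_glucose(idx: np.ndarray, days: np.ndarray, kinds: np.ndarray):
        lab_idx.append(idx)
        lab_day.append(days)
        lab_kind.append(kinds.astype(object))
        lab_val.append(
            _glucose_values(rng, st, idx, days, kinds, config.glucose_spike_prob)
        )

    # pre-anchor baseline: 1 + Poisson(1.5) normal-range labs per patient
    pre_counts = 1 + rng.poisson(1.5, n)
    pre_idx = np.repeat(np.arange(n), pre_counts)
    pre_days = (st.anchor[pre_idx] - rng.integers(1, 730, len(pre_idx))).astype(
        np.int64
    )
    is_a1c = rng.random(len(pre_idx)) < 0.5
    emit_a1c(pre_idx[is_a1c], pre_days[is_a1c])
    g_kinds = rng.choice(
        np.array(["random_glucose", "fasting_glucose"]), size=int((~is_a1c).sum()),
        p=[0.7, 0.3],
    )
    emit_glucose(pre_idx[~is_a1c], pre_days[~is_a1c], g_kinds)

    # prevalent diabetes: one diabetic-range HbA1c well before the anchor
    pv = np.flatnonzero(st.prevalent)
    pv_days = st.anchor[pv] - rng.integers(30, 401, len(pv))
    emit_a1c(pv, pv_days)

    # unexposed routine lab inside the anchor month (guarantees window lab and
    # index-month candidacy)
    ux = np.flatnonzero(~st.exposed)
    ms = _month_start(st.anchor[ux])
    rx_days = ms + np.floor(
        rng.random(len(ux)) * (st.anchor[ux] - ms + 1)
    ).astype(np.int64)
    is_a1c = rng.random(len(ux)) < 0.5
    emit_a1c(ux[is_a1c], rx_days[is_a1c])
    g_kinds = rng.choice(
        np.array(["random_glucose", "fasting_glucose"]), size=int((~is_a1c).sum()),
        p=[0.7, 0.3],
    )
    emit_glucose(ux[~is_a1c], rx_days[~is_a1c], g_kinds)

    # incident detection pattern: lab-based patients get two abnormal HbA1c at
    # d1/det; the rest two abnormal glucose values (one may fall inside the
    # 30-day post-index exclusion) plus a diagnosis code
    lb = np.flatnonzero(st.lab_based)
    for dcol in (st.d1, st.det):
        vals = np.round(_trunc_normal(rng, len(lb), 7.1, 0.5, 6.5, 12.0), 1)
        emit_a1c(lb, dcol[lb], vals)
    mx = np.flatnonzero(st.incident & ~st.lab_based)
    vals = np.round(_trunc_normal(rng, len(mx), 150, 15, 126, 300), 0)
    lab_idx.append(mx)
    lab_day.append(st.d1[mx])
    lab_kind.append(np.full(len(mx), "fasting_glucose", dtype=object))
    lab_val.append(vals)
    vals = np.round(_trunc_normal(rng, len(mx), 235, 25, 200, 400), 0)
    lab_idx.append(mx)
    lab_day.append(st.det[mx])
    lab_kind.append(np.full(len(mx), "random_glucose", dtype=object))
    lab_val.append(vals)

    # post-detection monitoring HbA1c (routine diabetes care): two guaranteed
    # draws inside the horizon, values follow the trajectory
    inc = np.flatnonzero(st.incident)
    for lo, hi in ((40, 151), (160, 301)):
        md = st.det[inc] + rng.integers(lo, hi, len(inc))
        keep = md <= horizon
        emit_a1c(inc[keep], md[keep])

    # remission qualifying pair
    ob = np.flatnonzero(st.observable)
    for dcol in (st.t1, st.t2):
        vals = np.round(_trunc_normal(rng, len(ob), 5.9, 0.25, 4.5, 6.4), 1)
        emit_a1c(ob, dcol[ob], vals)

    # background post-index testing, scaled by surveillance
    idx, days = _poisson_times(
        rng, st.anchor, np.full(n, horizon + 1), config.a1c_rate_post * surv_mult
    )
    emit_a1c(idx, days)
    idx, days = _poisson_times(
        rng, st.anchor, np.full(n, horizon + 1), config.glucose_rate_post * surv_mult
    )
    g_kinds = rng.choice(
        np.array(["random_glucose", "fasting_glucose"]), size=len(idx), p=[0.7, 0.3]
    )
    emit_glucose(idx, days, g_kinds)
    # background pre-index glucose testing (not surveillance-scaled)
    idx, days = _poisson_times(
        rng, st.anchor - 730, st.anchor, config.glucose_rate_pre
    )
    g_kinds = rng.choice(
        np.array(["random_glucose", "fasting_glucose"]), size=len(idx), p=[0.7, 0.3]
    )
    emit_glucose(idx, days, g_kinds)

    li = np.concatenate(lab_idx)
    ld = np.concatenate(lab_day)
    lk = np.concatenate(lab_kind)
    lv = np.concatenate(lab_val).astype(float)
    kcode = pd.Categorical(lk, categories=list(LAB_KINDS)).codes
    order = np.lexsort((lv, kcode, ld, li))
    labs = pd.DataFrame(
        {
            "patient_id": pid[li[order]],
            "date": _to_ts(ld[order]),
            "kind": lk[order],
            "value": lv[order],
        }
    )

    # ---- diagnoses ----------------------------------------------------------
    dg_idx: list[np.ndarray] = []
    dg_day: list[np.ndarray] = []
    dg_code: list[np.ndarray] = []
    coded = np.flatnonzero(st.incident & (rng.random(n) < 0.85))
    dg_idx.append(coded)
    dg_day.append(st.det[coded] + rng.integers(0, 11, len(coded)))
    dg_code.append(rng.choice(DIABETES_ICD, size=len(coded), p=DIABETES_ICD_W))
    pv_coded = np.flatnonzero(st.prevalent & (rng.random(n) < 0.8))
    dg_idx.append(pv_coded)
    dg_day.append(st.anchor[pv_coded] - rng.integers(30, 501, len(pv_coded)))
    dg_code.append(rng.choice(DIABETES_ICD, size=len(pv_coded), p=DIABETES_ICD_W))
    idx, days = _poisson_times(
        rng, st.anchor - 730, np.full(n, horizon + 1), 0.8
    )
    dg_idx.append(idx)
    dg_day.append(days)
    dg_code.append(rng.choice(BACKGROUND_ICD, size=len(idx)))
    di = np.concatenate(dg_idx)
    dd_day = np.concatenate(dg_day)
    dc = np.concatenate(dg_code).astype(object)
    ccode = pd.factorize(dc, sort=True)[0]
    order = np.lexsort((ccode, dd_day, di))
    diagnoses = pd.DataFrame(
        {
            "patient_id": pid[di[order]],
            "date": _to_ts(dd_day[order]),
            "icd10_code": dc[order],
        }
    )

    # ---- dispenses ----------------------------------------------------------
    dp_idx: list[np.ndarray] = []
    dp_rx: list[np.ndarray] = []
    dp_day: list[np.ndarray] = []
    dp_supply: list[np.ndarray] = []
    dp_refills: list[np.ndarray] = []
    dp_gl: list[np.ndarray] = []

    # remitters on medication: exactly an initial fill and one refill, supply
    # exhausted with no remaining refills well before the qualifying pair
    rx_rem = np.flatnonzero(st.remitter & (rng.random(n) < 0.25))
    f1 = st.det[rx_rem] + rng.integers(3, 16, len(rx_rem))
    for k, (dday, refills) in enumerate(((f1, 1), (f1 + 30, 0))):
        dp_idx.append(rx_rem)
        dp_rx.append(np.array([f"{pid[i]}-RX0" for i in rx_rem], dtype=object))
        dp_day.append(dday)
        dp_supply.append(np.full(len(rx_rem), 30, np.int64))
        dp_refills.append(np.full(len(rx_rem), refills, np.int64))
        dp_gl.append(np.ones(len(rx_rem), bool))

    # treated non-remitting diabetics: ongoing refill chains
    rx_non = np.flatnonzero(st.incident & ~st.remitter & (rng.random(n) < 0.55))
    n_fills = rng.integers(2, 7, len(rx_non))
    total = int(n_fills.sum())
    fill_pt = np.repeat(np.arange(len(rx_non)), n_fills)
    fill_no = np.concatenate([np.arange(k) for k in n_fills]) if total else np.array([], int)
    start = st.det[rx_non] + rng.integers(3, 31, len(rx_non))
    dday = start[fill_pt] + fill_no * 30 + rng.integers(0, 6, total)
    dp_idx.append(rx_non[fill_pt])
    dp_rx.append(np.array([f"{pid[i]}-RX0" for i in rx_non[fill_pt]], dtype=object))
    dp_day.append(dday)
    dp_supply.append(np.full(total, 30, np.int64))
    dp_refills.append((n_fills[fill_pt] - 1 - fill_no + 1).astype(np.int64))
    dp_gl.append(np.ones(total, bool))

    # non-glucose-lowering background dispenses
    other = np.flatnonzero(rng.random(n) < 0.30)
    k_fills = rng.integers(1, 4, len(other))
    total = int(k_fills.sum())
    fill_pt = np.repeat(np.arange(len(other)), k_fills)
    fill_no = np.concatenate([np.arange(k) for k in k_fills]) if total else np.array([], int)
    start = st.anchor[other] - rng.integers(0, 301, len(other))
    dp_idx.append(other[fill_pt])
    dp_rx.append(np.array([f"{pid[i]}-RX9" for i in other[fill_pt]], dtype=object))
    dp_day.append(start[fill_pt] + fill_no * 90)
    dp_supply.append(np.full(total, 90, np.int64))
    dp_refills.append((k_fills[fill_pt] - 1 - fill_no).astype(np.int64))
    dp_gl.append(np.zeros(total, bool))

    pi_ = np.concatenate(dp_idx)
    rx_ = np.concatenate(dp_rx)
    dy_ = np.concatenate(dp_day)
    rx_is9 = np.array([r.endswith("RX9") for r in rx_])
    order = np.lexsort((dy_, rx_is9, pi_))
    dispenses = pd.DataFrame(
        {
            "patient_id": pid[pi_[order]],
            "prescription_id": rx_[order],
            "dispense_date": _to_ts(dy_[order]),
            "days_supply": np.concatenate(dp_supply)[order],
            "refills_remaining_after": np.concatenate(dp_refills)[order],
            "is_glucose_lowering": np.concatenate(dp_gl)[order],
        }
    )

    # ---- encounters ---------------------------------------------------------
    # visits are emitted through index+30 only: downstream rules read visits
    # from the prior year, while follow-up is carried by the lab stream
    visit_start = np.where(no_prior_visits, st.anchor, st.anchor - 365)
    idx, days = _poisson_times(
        rng, visit_start, np.minimum(st.anchor + 30, horizon + 1), config.visit_rate
    )
    hz = np.flatnonzero(st.hospitalized)
    adm = st.anchor[hz] + rng.integers(-7, 15, len(hz))
    stay = rng.integers(2, 11, len(hz))
    e_idx = np.concatenate([idx, hz])
    e_day = np.concatenate([days, adm])
    e_adm = np.concatenate([np.zeros(len(idx), bool), np.ones(len(hz), bool)])
    e_dc = np.concatenate([np.full(len(idx), -1, np.int64), adm + stay])
    order = np.lexsort((e_adm, e_day, e_idx))
    dc_days = e_dc[order].astype(float)
    dc = pd.to_datetime(
        pd.Series(np.where(dc_days < 0, np.nan, dc_days)), unit="D"
    )
    encounters = pd.DataFrame(
        {
            "patient_id": pid[e_idx[order]],
            "date": _to_ts(e_day[order]),
            "type": np.where(e_adm[order], "admission", "outpatient"),
            "discharge_date": dc,
        }
    )

    # ---- swabs --------------------------------------------------------------
    sw_idx: list[np.ndarray] = []
    sw_day: list[np.ndarray] = []
    sw_res: list[np.ndarray] = []
    ex = np.flatnonzero(st.exposed)
    sw_idx.append(ex)
    sw_day.append(st.anchor[ex])
    sw_res.append(np.full(len(ex), "positive", dtype=object))
    extra = np.flatnonzero(st.exposed & (rng.random(n) < 0.15))
    d_extra = np.minimum(st.anchor[extra] + rng.integers(30, 301, len(extra)), w_hi)
    sw_idx.append(extra)
    sw_day.append(d_extra)
    sw_res.append(np.full(len(extra), "positive", dtype=object))
    neg_ex = np.flatnonzero(st.exposed & (rng.random(n) < 0.3))
    nd = np.maximum(st.anchor[neg_ex] - rng.integers(5, 201, len(neg_ex)), w_lo)
    sw_idx.append(neg_ex)
    sw_day.append(nd)
    sw_res.append(np.full(len(neg_ex), "negative", dtype=object))
    neg_ux = np.flatnonzero(~st.exposed & (rng.random(n) < 0.7))
    ms = _month_start(st.anchor[neg_ux])
    nd = ms + np.floor(
        rng.random(len(neg_ux)) * (st.anchor[neg_ux] - ms + 1)
    ).astype(np.int64)
    sw_idx.append(neg_ux)
    sw_day.append(nd)
    sw_res.append(np.full(len(neg_ux), "negative", dtype=object))
    si = np.concatenate(sw_idx)
    sd = np.concatenate(sw_day)
    sr = np.concatenate(sw_res)
    order = np.lexsort((sr == "positive", sd, si))
    swabs = pd.DataFrame(
        {
            "patient_id": pid[si[order]],
            "result_date": _to_ts(sd[order]),
            "result": sr[order],
        }
    )

    # ---- vaccinations -------------------------------------------------------
    vax_start = max(w_lo, _day(dt.date(2020, 12, 15)))
    n_doses = rng.choice(np.array([0, 1, 2, 3]), size=n, p=[0.55, 0.06, 0.25, 0.14])
    total = int(n_doses.sum())
    vx_pt = np.repeat(np.arange(n), n_doses)
    raw = vax_start + rng.random(total) * (horizon - vax_start)
    vx = pd.DataFrame({"pi": vx_pt, "day": raw.astype(np.int64)})
    vx = vx.sort_values(["pi", "day"]).reset_index(drop=True)
    vx["dose_number"] = vx.groupby("pi").cumcount() + 1
    # enforce strictly increasing dates within patient
    vx["day"] = vx["day"] + vx["dose_number"] - 1
    vaccinations = pd.DataFrame(
        {
            "patient_id": pid[vx["pi"].to_numpy()],
            "date": _to_ts(vx["day"].to_numpy()),
            "dose_number": vx["dose_number"].astype(np.int64).to_numpy(),
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "latent_exposed": st.exposed,
            "latent_diabetic": st.incident,
            "latent_remitter": st.remitter,
            "remission_observable": st.observable,
            "hospitalized": st.hospitalized,
            "anchor_date": _to_ts(st.anchor),
            "detection_planned": _to_ts(
                np.where(st.incident, st.det, np.datetime64("NaT").astype(np.int64))
            ).where(st.incident),
        }
    )

    return EhrDataset(
        patients=patients,
        labs=labs,
        diagnoses=diagnoses,
        dispenses=dispenses,
        encounters=encounters,
        swabs=swabs,
        vaccinations=vaccinations,
        truth=truth,
    )
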