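"""Derivation of analysis covariates from raw events.

Every adjustment variable of the relative-risk models is computed here:
age and BMI categories (half-open bins matching the published table labels,
so "24-29" means [24, 30)), hospitalization in the closed window from 7 days
before to 30 days after the index date, prior-year utilization counts over
[index - 365 d, index), vaccine-dose category from doses strictly before the
index date, the pandemic-era partition of the index month, and the first
HbA1c in the 30 days after the index date.  Patients with no recorded
smoking status are classified as never smokers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DiagnosticThresholds
from .dataset import EhrDataset, GLUCOSE_KINDS
from .phenotype import _days, _month_start_day

AGE_BINS = ((-np.inf, 40, "<40"), (40, 50, "40-49"), (50, 60, "50-59"),
            (60, 70, "60-69"), (70, 80, "70-79"), (80, np.inf, ">=80"))
BMI_BINS = ((-np.inf, 24, "<24"), (24, 30, "24-29"), (30, 35, "30-34"),
            (35, 40, "35-39"), (40, np.inf, ">=40"))
A1C_BINS = ((-np.inf, 7.0, "<7.0"), (7.0, 8.0, "7.0-7.9"),
            (8.0, 9.0, "8.0-8.9"), (9.0, np.inf, ">=9.0"))

#: pandemic eras by index month (closed month ranges); a partition of the
#: study window with no gaps or overlaps
ERA_MONTHS = (
    ("wild_type", "2020-03", "2021-04"),
    ("alpha", "2021-05", "2021-07"),
    ("delta", "2021-08", "2021-12"),
    ("omicron", "2022-01", "2022-06"),
)


def _bin_value(x: float, bins) -> str:
    for lo, hi, label in bins:
        if lo <= x < hi:
            return label
    raise ValueError(f"value {x} outside all bins")


def age_category(age_years: float) -> str:
    """Map an age in years to the table's category labels."""
    return _bin_value(age_years, AGE_BINS)


def bmi_category(bmi: float | None) -> str:
    """Map BMI (kg/m^2) to the table's category labels; NaN -> 'missing'."""
    if bmi is None or (isinstance(bmi, float) and np.isnan(bmi)):
        return "missing"
    return _bin_value(bmi, BMI_BINS)


def early_a1c_category(value: float | None) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "absent"
    return _bin_value(value, A1C_BINS)


def pandemic_era(index_date) -> str:
    """Era of an index date, by calendar month."""
    m = pd.Period(pd.Timestamp(index_date), freq="M")
    for label, lo, hi in ERA_MONTHS:
        if pd.Period(lo, "M") <= m <= pd.Period(hi, "M"):
            return label
    raise ValueError(f"index month {m} outside the pandemic-era partition")


def _categorize(values: np.ndarray, bins, missing_label: str | None = None) -> np.ndarray:
    out = np.full(len(values), missing_label or "", dtype=object)
    finite = ~pd.isna(values)
    v = np.asarray(values, dtype=float)
    for lo, hi, label in bins:
        m = finite & (v >= lo) & (v < hi)
        out[m] = label
    return out


def derive_rows(
    ds: EhrDataset,
    cohort: pd.DataFrame,
    remission: pd.DataFrame,
    th: DiagnosticThresholds | None = None,
) -> pd.DataFrame:
    """Build the analysis table: one row per included cohort patient."""
    th = th or DiagnosticThresholds()
    rows = cohort.merge(
        remission[["patient_id", "remission"]], on="patient_id", how="left"
    )
    rows = rows.merge(ds.patients, on="patient_id", how="left")
    n = len(rows)
    pid = rows["patient_id"].to_numpy()
    pindex = pd.Index(pid)
    idx_day = _days(rows["index_date"])
    birth_day = _days(rows["birth_date"])

    age = (idx_day - birth_day) / 365.25
    rows["age_years"] = age
    rows["age_cat"] = _categorize(age, AGE_BINS)
    rows["female"] = rows["sex_at_birth"] == "female"
    rows["smoking"] = rows["smoking"].fillna("never")
    rows["bmi"] = rows["bmi_true"].astype(float)
    rows["bmi_cat"] = _categorize(rows["bmi"].to_numpy(), BMI_BINS, "missing")

    def window_count(ev_pid, ev_day, lo_off, hi_off) -> np.ndarray:
        """Count events per patient with day in [idx+lo_off, idx+hi_off)."""
        ix = pindex.get_indexer(ev_pid)
        sel = ix >= 0
        rowix = ix[sel]
        d = ev_day[sel]
        base = idx_day[rowix]
        cnt = np.zeros(n, np.int64)
        inside = (d >= base + lo_off) & (d < base + hi_off)
        np.add.at(cnt, rowix[inside], 1)
        return cnt

    enc_pid = ds.encounters["patient_id"].to_numpy()
    enc_day = _days(ds.encounters["date"])
    outpt = (ds.encounters["type"] == "outpatient").to_numpy()
    rows["n_visits_prior_year"] = window_count(enc_pid[outpt], enc_day[outpt], -365, 0)
    # vitals are recorded at encounters; the prior-year vitals count is the
    # prior-year encounter count
    rows["n_vitals_prior_year"] = window_count(enc_pid, enc_day, -365, 0)

    lab_pid = ds.labs["patient_id"].to_numpy()
    lab_day = _days(ds.labs["date"])
    is_glu = ds.labs["kind"].isin(GLUCOSE_KINDS).to_numpy()
    is_a1c = (ds.labs["kind"] == "hba1c").to_numpy()
    rows["n_glucose_prior_year"] = window_count(lab_pid[is_glu], lab_day[is_glu], -365, 0)
    rows["n_a1c_prior_year"] = window_count(lab_pid[is_a1c], lab_day[is_a1c], -365, 0)

    # hospitalization: admission date between 7 days before and 30 days after
    # the index date (closed on both ends)
    adm = (ds.encounters["type"] == "admission").to_numpy()
    lo, hi = th.hosp_window
    hosp_cnt = window_count(enc_pid[adm], enc_day[adm], lo, hi + 1)
    rows["hospitalized"] = hosp_cnt > 0

    # vaccine doses strictly before index
    vax_pid = ds.vaccinations["patient_id"].to_numpy()
    vax_day = _days(ds.vaccinations["date"])
    vax_n = window_count(vax_pid, vax_day, -(10**6), 0)
    rows["vaccine_cat"] = np.select(
        [vax_n == 0, vax_n == 1], ["0", "1"], default=">=2"
    )

    # pandemic era by index month
    idx_month = pd.PeriodIndex(rows["index_date"], freq="M")
    era = np.full(n, "", dtype=object)
    for label, lo_m, hi_m in ERA_MONTHS:
        m = (idx_month >= pd.Period(lo_m, "M")) & (idx_month <= pd.Period(hi_m, "M"))
        era[m] = label
    rows["era"] = era

    # first HbA1c in the 30 days after the index date
    lab_ix = pindex.get_indexer(lab_pid)
    sel = is_a1c & (lab_ix >= 0)
    rowix = lab_ix[sel]
    d = lab_day[sel]
    v = ds.labs["value"].to_numpy(dtype=float)[sel]
    base = idx_day[rowix]
    inside = (d >= base) & (d <= base + 30)
    early = np.full(n, np.nan)
    order = np.lexsort((d[inside], rowix[inside]))[::-1]  # reversed: first wins last
    early[rowix[inside][order]] = v[inside][order]
    rows["early_a1c"] = early
    rows["early_a1c_cat"] = _categorize(early, A1C_BINS, "absent")

    # follow-up: last event of any kind minus index, floored at 0
    last = np.full(n, -np.inf)
    for ev_pid, ev_day in (
        (lab_pid, lab_day),
        (enc_pid, enc_day),
        (ds.diagnoses["patient_id"].to_numpy(), _days(ds.diagnoses["date"])),
        (ds.dispenses["patient_id"].to_numpy(), _days(ds.dispenses["dispense_date"])),
        (ds.swabs["patient_id"].to_numpy(), _days(ds.swabs["result_date"])),
        (ds.vaccinations["patient_id"].to_numpy(), _days(ds.vaccinations["date"])),
    ):
        ix = pindex.get_indexer(ev_pid)
        sel = ix >= 0
        np.maximum.at(last, ix[sel], ev_day[sel])
    rows["follow_up_days"] = np.maximum(last - idx_day, 0).astype(np.int64)

    keep = [
        "patient_id", "exposed", "index_date", "detection_date", "criterion",
        "age_years", "age_cat", "female", "race_black", "race_latinx",
        "race_white", "race_other", "region", "smoking", "charlson", "bmi",
        "bmi_cat", "hospitalized", "n_visits_prior_year", "n_vitals_prior_year",
        "n_glucose_prior_year", "n_a1c_prior_year", "vaccine_cat", "era",
        "early_a1c", "early_a1c_cat", "remission", "follow_up_days",
    ]
    out = rows[keep].copy()
    out["remission"] = out["remission"].fillna(False).astype(bool)
    return out
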