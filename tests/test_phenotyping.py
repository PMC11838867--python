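"""Index assignment, eligibility and incident-diabetes detection rules."""

import numpy as np
import pandas as pd
import pytest

from remitehr import (
    EhrDataset,
    IndexAssignment,
    MatchingError,
    assign_index_dates,
    build_cohort,
    check_eligibility,
    detect_cohort1,
    detect_cohort2,
    has_prior_diabetes_evidence,
)
from remitehr.phenotype import _lab_abnormal

from conftest import empty_frame, lab_frame
from _oracle import (
    brute_force_cohort1,
    brute_force_cohort2,
)

IDX = pd.Timestamp("2020-06-15")
D = lambda days: IDX + pd.Timedelta(days=days)


def labf(records):
    """Lab rows with dates relative to IDX: (pid, day_offset, kind, value)."""
    return pd.DataFrame(
        [
            {"patient_id": p, "date": D(d), "kind": k, "value": float(v)}
            for p, d, k, v in records
        ],
        columns=["patient_id", "date", "kind", "value"],
    )


def _mini_ds(patients, labs=None, swabs=None, encounters=None):
    ds = EhrDataset.empty()
    ds.patients = pd.DataFrame({"patient_id": patients})
    if labs is not None:
        ds.labs = labs
    if swabs is not None:
        ds.swabs = swabs
    if encounters is not None:
        ds.encounters = encounters
    return ds


# ---------------------------------------------------------------------------
# index assignment
# ---------------------------------------------------------------------------

def test_index_is_first_positive_swab():
    swabs = pd.DataFrame(
        {
            "patient_id": ["a", "a"],
            "result_date": [pd.Timestamp("2020-05-01"), pd.Timestamp("2021-01-01")],
            "result": ["positive", "positive"],
        }
    )
    ds = _mini_ds(["a"], swabs=swabs)
    out = assign_index_dates(ds, seed=0)
    assert out.loc[0, "index_date"] == pd.Timestamp("2020-05-01")
    assert bool(out.loc[0, "exposed"])


def test_single_month_target_assigns_everyone_to_that_month():
    swabs = pd.DataFrame(
        {
            "patient_id": [f"e{i}" for i in range(5)],
            "result_date": pd.Timestamp("2020-06-10"),
            "result": "positive",
        }
    )
    labs = lab_frame([(f"u{i}", 5, "hba1c", 5.5) for i in range(20)])
    ds = _mini_ds([f"e{i}" for i in range(5)] + [f"u{i}" for i in range(20)],
                  labs=labs, swabs=swabs)
    out = assign_index_dates(ds, seed=1)
    un = out[~out["exposed"]]
    assert len(un) == 20
    assert (un["index_date"].dt.to_period("M") == pd.Period("2020-06")).all()


def test_no_exposed_patients_is_an_error(small_ds):
    ds = EhrDataset.empty()
    ds.patients = pd.DataFrame({"patient_id": ["a"]})
    ds.labs = lab_frame([("a", 0, "hba1c", 5.5)])
    with pytest.raises(MatchingError):
        assign_index_dates(ds, seed=0)


def test_frequency_matching_reproduces_70_30_split():
    """10,000 unexposed with uniform two-month candidacy against a 70/30
    exposed distribution are assigned within 2 percentage points of 70/30."""
    n_exp, n_un = 1000, 10_000
    swabs = pd.DataFrame(
        {
            "patient_id": [f"e{i}" for i in range(n_exp)],
            "result_date": [
                pd.Timestamp("2020-06-10") if i < 700 else pd.Timestamp("2020-07-10")
                for i in range(n_exp)
            ],
            "result": "positive",
        }
    )
    labs = lab_frame(
        [(f"u{i}", 5, "hba1c", 5.5) for i in range(n_un)]
        + [(f"u{i}", 35, "hba1c", 5.5) for i in range(n_un)]
    )
    ds = _mini_ds(
        [f"e{i}" for i in range(n_exp)] + [f"u{i}" for i in range(n_un)],
        labs=labs, swabs=swabs,
    )
    out = assign_index_dates(ds, seed=9)
    un = out[~out["exposed"]]
    share_june = (un["index_date"].dt.to_period("M") == pd.Period("2020-06")).mean()
    assert abs(share_june - 0.70) < 0.02


def test_index_month_distributions_match_on_generated_data(medium_ds):
    """Total-variation distance between exposed and assigned unexposed
    index-month distributions is < 0.03 at n = 10,000."""
    out = assign_index_dates(medium_ds, seed=4)
    m = out.assign(month=out["index_date"].dt.to_period("M"))
    pe = m.loc[m["exposed"], "month"].value_counts(normalize=True)
    pu = m.loc[~m["exposed"], "month"].value_counts(normalize=True)
    months = pe.index.union(pu.index)
    tv = 0.5 * float(
        (pe.reindex(months, fill_value=0) - pu.reindex(months, fill_value=0))
        .abs().sum()
    )
    assert tv < 0.03


def test_unexposed_index_in_candidate_month(small_ds):
    out = assign_index_dates(small_ds, seed=2)
    labs = small_ds.labs.assign(month=small_ds.labs["date"].dt.to_period("M"))
    by_pid = labs.groupby("patient_id")["month"].agg(set)
    un = out[~out["exposed"]]
    for pid, idx in zip(un["patient_id"], un["index_date"]):
        assert pd.Period(idx, "M") in by_pid[pid]


def test_negative_swab_flavor_uses_negative_swab_months(small_ds):
    out = assign_index_dates(small_ds, flavor="negative_swab", seed=2)
    neg = small_ds.swabs[small_ds.swabs["result"] == "negative"]
    months = neg.assign(month=neg["result_date"].dt.to_period("M")).groupby(
        "patient_id"
    )["month"].agg(set)
    un = out[~out["exposed"]]
    assert len(un) > 0
    for pid, idx in zip(un["patient_id"], un["index_date"]):
        assert pd.Period(idx, "M") in months[pid]


# ---------------------------------------------------------------------------
# per-patient gates
# ---------------------------------------------------------------------------

def test_prior_evidence_boundaries(th):
    dx = empty_frame("patient_id", "date", "icd10_code")
    labs = labf([("p", -1, "fasting_glucose", 126.0)])
    assert has_prior_diabetes_evidence(labs, dx, IDX, th)  # boundary: >= 126
    labs = labf([("p", -10, "hba1c", 6.4)])
    assert not has_prior_diabetes_evidence(labs, dx, IDX, th)
    dx = pd.DataFrame(
        {"patient_id": ["p"], "date": [D(-30)], "icd10_code": ["E11.9"]}
    )
    assert has_prior_diabetes_evidence(lab_frame([]), dx, IDX, th)
    dx14 = pd.DataFrame(
        {"patient_id": ["p"], "date": [D(-30)], "icd10_code": ["E14.0"]}
    )
    assert not has_prior_diabetes_evidence(lab_frame([]), dx14, IDX, th)


def _assignment(exposed=False):
    return IndexAssignment("p", exposed, IDX)


def test_eligibility_prior_diabetes(th):
    labs = labf([("p", -100, "hba1c", 7.0)])
    res = check_eligibility(labs, empty_frame("patient_id", "date", "icd10_code"),
                            empty_frame("patient_id", "date", "type"),
                            _assignment(), th)
    assert not res.eligible
    assert res.exclusion_reasons[0] == "prior_diabetes"


def test_eligibility_all_gates_pass(th):
    labs = labf([("p", -700, "random_glucose", 100.0)])
    enc = pd.DataFrame(
        {"patient_id": ["p"], "date": [D(-200)], "type": ["outpatient"]}
    )
    res = check_eligibility(labs, empty_frame("patient_id", "date", "icd10_code"),
                            enc, _assignment(), th)
    assert res.eligible and res.exclusion_reasons == ()


def test_eligibility_stale_lab_outside_730_days(th):
    labs = labf([("p", -800, "random_glucose", 100.0)])
    enc = pd.DataFrame(
        {"patient_id": ["p"], "date": [D(-200)], "type": ["outpatient"]}
    )
    res = check_eligibility(labs, empty_frame("patient_id", "date", "icd10_code"),
                            enc, _assignment(), th)
    assert res.exclusion_reasons == ("no_normal_lab_2y",)


def test_visit_window_is_anchored_to_index_month(th):
    # index 2020-06-15 -> window [2019-06-02, 2020-06-01)
    labs = labf([("p", -100, "random_glucose", 100.0)])
    dx = empty_frame("patient_id", "date", "icd10_code")
    enc = pd.DataFrame(
        {"patient_id": ["p"], "date": [pd.Timestamp("2020-06-05")],
         "type": ["outpatient"]}
    )
    res = check_eligibility(labs, dx, enc, _assignment(), th)
    assert "no_visit_1y" in res.exclusion_reasons  # visit inside index month
    enc2 = pd.DataFrame(
        {"patient_id": ["p"], "date": [pd.Timestamp("2020-05-20")],
         "type": ["outpatient"]}
    )
    res2 = check_eligibility(labs, dx, enc2, _assignment(), th)
    assert res2.eligible


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

EMPTY_DX = empty_frame("patient_id", "date", "icd10_code")
EMPTY_RX = empty_frame(
    "patient_id", "prescription_id", "dispense_date", "days_supply",
    "refills_remaining_after", "is_glucose_lowering",
)


def test_cohort1_glucose_exclusion_window(th):
    labs = labf(
        [("p", 10, "random_glucose", 250.0), ("p", 40, "random_glucose", 250.0)]
    )
    res = detect_cohort1(labs, EMPTY_DX, EMPTY_RX, IDX, th)
    assert not res.detected  # first value falls in [index, index+30]


def test_cohort1_hba1c_not_subject_to_glucose_window(th):
    labs = labf([("p", 10, "hba1c", 6.7), ("p", 50, "hba1c", 6.8)])
    res = detect_cohort1(labs, EMPTY_DX, EMPTY_RX, IDX, th)
    assert res.detected and res.criterion == "two_labs"
    assert res.detection_date == D(50)


def test_cohort1_med_refill_beats_later_code(th):
    rx = pd.DataFrame(
        {
            "patient_id": ["p", "p"],
            "prescription_id": ["r1", "r1"],
            "dispense_date": [D(20), D(55)],
            "days_supply": [30, 30],
            "refills_remaining_after": [2, 1],
            "is_glucose_lowering": [True, True],
        }
    )
    dx = pd.DataFrame({"patient_id": ["p"], "date": [D(90)], "icd10_code": ["E11"]})
    res = detect_cohort1(lab_frame([]), dx, rx, IDX, th)
    assert res.detected and res.criterion == "med_refill"
    assert res.detection_date == D(55)


def test_cohort1_refill_requires_same_prescription(th):
    rx = pd.DataFrame(
        {
            "patient_id": ["p", "p"],
            "prescription_id": ["r1", "r2"],
            "dispense_date": [D(20), D(55)],
            "days_supply": [30, 30],
            "refills_remaining_after": [0, 0],
            "is_glucose_lowering": [True, True],
        }
    )
    res = detect_cohort1(lab_frame([]), EMPTY_DX, rx, IDX, th)
    assert not res.detected


def test_cohort2_boundary_and_counts(th):
    labs = labf([("p", 30, "hba1c", 6.5), ("p", 120, "hba1c", 6.5)])
    res = detect_cohort2(labs, IDX, th)
    assert res.detected and res.detection_date == D(120)
    assert not detect_cohort2(labf([("p", 30, "hba1c", 9.0)]), IDX, th).detected
    many_low = labf([("p", 30 * k, "hba1c", 6.4) for k in range(1, 6)])
    assert not detect_cohort2(many_low, IDX, th).detected


# ---------------------------------------------------------------------------
# build_cohort against the per-patient oracle
# ---------------------------------------------------------------------------

def _day(ts):
    return int(np.datetime64(pd.Timestamp(ts), "D").astype("int64"))


@pytest.mark.parametrize("cohort_id", [1, 2])
def test_build_cohort_matches_brute_force(small_ds, th, cohort_id):
    """Every emitted record's detection matches an independent re-evaluation
    over the raw events."""
    build = build_cohort(small_ds, cohort_id=cohort_id, seed=6)
    assign = assign_index_dates(small_ds, seed=6)
    idx_map = dict(zip(assign["patient_id"], assign["index_date"]))
    labs_by = dict(tuple(small_ds.labs.groupby("patient_id")))
    dx_by = dict(tuple(small_ds.diagnoses.groupby("patient_id")))
    rx_by = dict(tuple(small_ds.dispenses.groupby("patient_id")))
    assert len(build.cohort) > 10
    for _, row in build.cohort.iterrows():
        pid = row["patient_id"]
        idx_day = _day(idx_map[pid])
        labs = [
            (_day(r.date), r.kind, r.value)
            for r in labs_by.get(pid, lab_frame([])).itertuples()
        ]
        if cohort_id == 1:
            codes = [
                (_day(r.date), r.icd10_code)
                for r in dx_by.get(pid, EMPTY_DX).itertuples()
            ]
            rx = [
                (r.prescription_id, _day(r.dispense_date), r.days_supply,
                 r.refills_remaining_after)
                for r in rx_by.get(pid, EMPTY_RX).itertuples()
                if r.is_glucose_lowering
            ]
            det, day, crit = brute_force_cohort1(labs, codes, rx, idx_day)
        else:
            det, day = brute_force_cohort2(labs, idx_day)
            crit = "two_a1c"
        assert det
        assert _day(row["detection_date"]) == day
        assert row["criterion"] == crit


def test_gate_counts_are_additive(small_ds):
    build = build_cohort(small_ds, cohort_id=1, seed=6)
    gc = build.gate_counts
    total_excluded = sum(
        gc[k] for k in gc if k not in ("n_input", "n_output")
    )
    assert gc["n_input"] == gc["n_output"] + total_excluded
    assert len(build.exclusions) == total_excluded


def test_no_included_patient_has_prior_diabetes_evidence(small_ds, th):
    build = build_cohort(small_ds, cohort_id=1, seed=6)
    assign = assign_index_dates(small_ds, seed=6)
    idx_map = dict(zip(assign["patient_id"], assign["index_date"]))
    for pid in build.cohort["patient_id"]:
        labs = small_ds.labs[small_ds.labs["patient_id"] == pid]
        pre = labs[labs["date"] < idx_map[pid]]
        assert not (len(pre) and _lab_abnormal(pre, th).any())
        dx = small_ds.diagnoses[small_ds.diagnoses["patient_id"] == pid]
        pre_dx = dx[dx["date"] < idx_map[pid]]
        assert not any(th.icd10_is_diabetes(c) for c in pre_dx["icd10_code"])


def test_cohort2_members_have_two_post_index_diabetic_a1c(small_ds, th):
    build = build_cohort(small_ds, cohort_id=2, seed=6)
    assign = assign_index_dates(small_ds, seed=6)
    idx_map = dict(zip(assign["patient_id"], assign["index_date"]))
    for pid in build.cohort["patient_id"]:
        labs = small_ds.labs[small_ds.labs["patient_id"] == pid]
        hits = labs[
            (labs["kind"] == "hba1c")
            & (labs["value"] >= th.hba1c_dm)
            & (labs["date"] >= idx_map[pid])
        ]
        assert len(hits) >= 2
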