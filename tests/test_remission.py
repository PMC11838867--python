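"""Remission classifier: boundaries, medication-supply logic, oracle parity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from remitehr import (
    DiagnosticThresholds,
    SupplyTimeline,
    build_supply_timeline,
    classify_remission,
    follow_up_days,
)
from remitehr.remission import _classify_days

from _oracle import brute_force_remission

DET = pd.Timestamp("2020-06-01")
DET_DAY = int(np.datetime64(DET, "D").astype("int64"))
D = lambda days: DET + pd.Timedelta(days=days)


def a1cf(records):
    return pd.DataFrame(
        [
            {"patient_id": "p", "date": D(d), "kind": "hba1c", "value": float(v)}
            for d, v in records
        ],
        columns=["patient_id", "date", "kind", "value"],
    )


def rxf(records):
    """(rx_id, day, days_supply, refills_remaining_after)."""
    return pd.DataFrame(
        [
            {"patient_id": "p", "prescription_id": r, "dispense_date": D(d),
             "days_supply": s, "refills_remaining_after": f,
             "is_glucose_lowering": True}
            for r, d, s, f in records
        ],
        columns=["patient_id", "prescription_id", "dispense_date", "days_supply",
                 "refills_remaining_after", "is_glucose_lowering"],
    )


NO_MEDS = SupplyTimeline()


# ---------------------------------------------------------------------------
# supply timeline
# ---------------------------------------------------------------------------

def test_empty_timeline():
    tl = build_supply_timeline(rxf([]))
    assert tl.covered_intervals == () and tl.open_refills_after is None
    assert not tl.blocked(DET_DAY)


def test_contiguous_fills_merge_and_free_after():
    tl = build_supply_timeline(rxf([("r", 0, 30, 1), ("r", 30, 30, 0)]))
    assert tl.covered_intervals == ((DET_DAY, DET_DAY + 60),)
    assert tl.blocked(DET_DAY + 45)
    assert not tl.blocked(DET_DAY + 61)


def test_open_refills_disqualify_beyond_supply():
    tl = build_supply_timeline(rxf([("r", 0, 30, 2)]))
    assert tl.blocked(DET_DAY + 35)  # supply exhausted but refills remain
    assert tl.open_refills_after == DET_DAY


def test_non_glucose_lowering_dispenses_ignored():
    rx = rxf([("r", 0, 30, 2)])
    rx["is_glucose_lowering"] = False
    assert build_supply_timeline(rx).covered_intervals == ()


# ---------------------------------------------------------------------------
# classifier boundaries
# ---------------------------------------------------------------------------

def test_basic_remission_pair(th):
    a1cs = a1cf([(100, 6.0), (200, 6.1)])
    r = classify_remission(a1cs, a1cs, NO_MEDS, DET, th)
    assert r.remission
    assert r.qualifying_dates == (D(100), D(200))


def test_latency_gate(th):
    a1cs = a1cf([(50, 6.0), (150, 6.1)])
    r = classify_remission(a1cs, a1cs, NO_MEDS, DET, th)
    assert not r.remission and r.failure_reason == "insufficient_latency"


def test_gap_boundary_90_days(th):
    near = a1cf([(100, 6.0), (185, 6.1)])
    assert not classify_remission(near, near, NO_MEDS, DET, th).remission
    exact = a1cf([(100, 6.0), (190, 6.1)])
    assert classify_remission(exact, exact, NO_MEDS, DET, th).remission


def test_threshold_is_strict(th):
    at = a1cf([(100, 6.5), (200, 6.4)])
    r = classify_remission(at, at, NO_MEDS, DET, th)
    assert not r.remission  # 6.5 does not qualify; single 6.4 has no partner


def test_later_diabetic_lab_voids_remission(th):
    a1cs = a1cf([(100, 6.0), (200, 6.1)])
    labs = pd.concat(
        [a1cs, pd.DataFrame([{"patient_id": "p", "date": D(300),
                              "kind": "random_glucose", "value": 220.0}])],
        ignore_index=True,
    )
    r = classify_remission(a1cs, labs, NO_MEDS, DET, th)
    assert not r.remission and r.failure_reason == "later_diabetes_lab"


def test_medication_coverage_voids_pair(th):
    a1cs = a1cf([(100, 6.0), (200, 6.1)])
    supply = build_supply_timeline(rxf([("r", 90, 30, 0)]))  # covers day 100
    r = classify_remission(a1cs, a1cs, supply, DET, th)
    assert not r.remission and r.failure_reason == "medication_covered"


def test_earliest_pair_reported(th):
    a1cs = a1cf([(100, 6.0), (195, 6.2), (300, 6.1)])
    r = classify_remission(a1cs, a1cs, NO_MEDS, DET, th)
    assert r.qualifying_dates == (D(100), D(195))


def test_missing_detection_date_is_an_error(th):
    with pytest.raises(ValueError):
        classify_remission(a1cf([(100, 6.0)]), a1cf([]), NO_MEDS, None, th)


def test_sensitivity_threshold_5_7(th):
    a1cs = a1cf([(100, 5.9), (200, 5.6), (300, 5.5)])
    strict = th.with_remission_threshold(5.7)
    r = classify_remission(a1cs, a1cs, NO_MEDS, DET, strict)
    assert r.remission and r.qualifying_dates == (D(200), D(300))
    assert r.threshold_used == 5.7


def test_follow_up_days():
    assert follow_up_days(pd.Series([DET]), DET) == 0
    assert follow_up_days(pd.Series([D(10), D(700)]), DET) == 700
    assert follow_up_days(pd.Series([D(-30)]), DET) == 0
    assert follow_up_days(pd.Series([], dtype="datetime64[ns]"), DET) == 0


# ---------------------------------------------------------------------------
# property tests against the brute-force oracle
# ---------------------------------------------------------------------------

event_streams = st.tuples(
    st.lists(  # HbA1c: (day, value)
        st.tuples(st.integers(0, 500), st.floats(5.0, 8.0)),
        max_size=10,
    ),
    st.lists(  # glucose labs: (day, kind idx, value)
        st.tuples(st.integers(0, 600), st.integers(0, 2), st.floats(80, 260)),
        max_size=4,
    ),
    st.lists(  # dispenses: (rx, start day, supply, refills)
        st.tuples(st.integers(0, 1), st.integers(0, 400), st.integers(7, 90),
                  st.integers(0, 3)),
        max_size=4,
    ),
)

GLUCOSE_KINDS = ["random_glucose", "fasting_glucose", "ogtt_2h_glucose"]


def _run_both(a1cs, glu, rx, threshold=6.5):
    th = DiagnosticThresholds(remission_hba1c=threshold)
    a1c_rows = a1cf([(d, round(v, 1)) for d, v in a1cs])
    glu_rows = pd.DataFrame(
        [
            {"patient_id": "p", "date": D(d), "kind": GLUCOSE_KINDS[k],
             "value": round(v, 0)}
            for d, k, v in glu
        ],
        columns=["patient_id", "date", "kind", "value"],
    )
    frames = [f for f in (a1c_rows, glu_rows) if len(f)]
    all_labs = pd.concat(frames, ignore_index=True) if frames else a1c_rows
    rx_rows = rxf([(f"rx{r}", d, s, f) for r, d, s, f in rx])
    supply = build_supply_timeline(rx_rows)
    got = classify_remission(a1c_rows, all_labs, supply, DET, th)

    a1c_list = [(DET_DAY + d, round(v, 1)) for d, v in a1cs]
    lab_list = [(t, "hba1c", v) for t, v in a1c_list] + [
        (DET_DAY + d, GLUCOSE_KINDS[k], round(v, 0)) for d, k, v in glu
    ]
    rx_list = [(f"rx{r}", DET_DAY + d, s, f) for r, d, s, f in rx]
    want, pair = brute_force_remission(
        a1c_list, lab_list, rx_list, DET_DAY, threshold
    )
    return got, want, pair


@settings(max_examples=300, deadline=None, derandomize=True)
@given(event_streams)
def test_classifier_equals_brute_force_oracle(stream):
    a1cs, glu, rx = stream
    got, want, pair = _run_both(a1cs, glu, rx)
    assert got.remission == want
    if want:
        got_pair = tuple(
            int(np.datetime64(t, "D").astype("int64")) for t in got.qualifying_dates
        )
        assert got_pair == pair


@settings(max_examples=150, deadline=None, derandomize=True)
@given(event_streams)
def test_threshold_monotonicity(stream):
    """Remission at 5.7% implies remission at 6.5% on the same events."""
    a1cs, glu, rx = stream
    strict, _, _ = _run_both(a1cs, glu, rx, threshold=5.7)
    loose, _, _ = _run_both(a1cs, glu, rx, threshold=6.5)
    if strict.remission:
        assert loose.remission


@settings(max_examples=150, deadline=None, derandomize=True)
@given(event_streams, st.integers(0, 400), st.integers(7, 90), st.integers(0, 2))
def test_adding_a_dispense_never_creates_remission(stream, day, supply, refills):
    a1cs, glu, rx = stream
    base, _, _ = _run_both(a1cs, glu, rx)
    more, _, _ = _run_both(a1cs, glu, rx + [(0, day, supply, refills)])
    if not base.remission:
        assert not more.remission
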