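"""EHR-defined diabetes remission off glucose-lowering medication.

Remission requires two HbA1c measurements below threshold (default 6.5%,
strict), 90 or more days apart, the first at least 90 days after diabetes
detection, with neither measurement inside a medication-covered interval nor
on/before a date at which some glucose-lowering prescription still had
refills remaining, and no glucose or HbA1c value meeting a diabetes
diagnostic threshold on or after the first qualifying measurement.  The
lexicographically earliest qualifying (t1, t2) pair is reported.

The last condition follows the stricter reading of the outcome definition
(no diabetes-range lab *following* the qualifying measurements, which
implies none between them); ``between_only=True`` exposes the weaker
variant that only forbids diabetes-range labs between t1 and t2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DiagnosticThresholds
from .dataset import EhrDataset
from .phenotype import _days, _lab_abnormal

FAILURE_REASONS = (
    "no_pair",
    "insufficient_latency",
    "medication_covered",
    "later_diabetes_lab",
)


@dataclass(frozen=True)
class SupplyTimeline:
    """Medication state for one patient's glucose-lowering prescriptions.

    ``covered_intervals`` are half-open ``[start, end)`` day pairs (epoch
    days), sorted and non-overlapping.  ``refill_open_intervals`` are the
    periods during which some prescription still had refills remaining:
    refill state is observable only at dispense events, so a prescription is
    open from any fill with ``refills_remaining_after > 0`` until its next
    fill, indefinitely if no later fill closes it (end = None).
    ``open_refills_after`` is the latest dispense day whose
    ``refills_remaining_after`` was positive, or None.
    """

    covered_intervals: tuple[tuple[int, int], ...] = ()
    refill_open_intervals: tuple[tuple[int, int | None], ...] = ()
    open_refills_after: int | None = None

    def covers(self, day: int) -> bool:
        return any(a <= day < b for a, b in self.covered_intervals)

    def refills_open(self, day: int) -> bool:
        return any(
            a <= day and (b is None or day < b) for a, b in self.refill_open_intervals
        )

    def blocked(self, day: int) -> bool:
        """A measurement at ``day`` is disqualified by medication supply."""
        return self.covers(day) or self.refills_open(day)


@dataclass(frozen=True)
class RemissionResult:
    patient_id: str
    remission: bool
    qualifying_dates: tuple[pd.Timestamp, pd.Timestamp] | None = None
    threshold_used: float = 6.5
    failure_reason: str | None = None


def _timeline_from_arrays(
    days: np.ndarray,
    supply: np.ndarray,
    refills: np.ndarray,
    rx: np.ndarray | None = None,
) -> SupplyTimeline:
    if len(days) == 0:
        return SupplyTimeline()
    order = np.argsort(days, kind="mergesort")
    starts, ends = days[order], days[order] + supply[order]
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    # refill state per prescription: open from a positive-refill fill until
    # the next fill of the same prescription
    open_iv: list[tuple[int, int | None]] = []
    if rx is None:
        rx = np.zeros(len(days), dtype=np.int64)
    for r in pd.unique(rx):
        sel = rx == r
        d, f = days[sel], refills[sel]
        o = np.argsort(d, kind="mergesort")
        d, f = d[o], f[o]
        for i in range(len(d)):
            if f[i] > 0:
                nxt = int(d[i + 1]) if i + 1 < len(d) else None
                open_iv.append((int(d[i]), nxt))
    open_after = days[refills > 0].max() if (refills > 0).any() else None
    return SupplyTimeline(
        covered_intervals=tuple((a, b) for a, b in merged),
        refill_open_intervals=tuple(sorted(open_iv, key=lambda t: t[0])),
        open_refills_after=int(open_after) if open_after is not None else None,
    )


def build_supply_timeline(dispenses: pd.DataFrame) -> SupplyTimeline:
    """Merge one patient's glucose-lowering dispenses into coverage intervals.

    Each dispense covers ``[dispense_date, dispense_date + days_supply)``;
    refill state is tracked per prescription (a fill leaving refills
    outstanding keeps the prescription open until its next fill).
    """
    gl = dispenses
    if "is_glucose_lowering" in gl.columns:
        gl = gl[gl["is_glucose_lowering"].astype(bool)]
    if not len(gl):
        return SupplyTimeline()
    rx = pd.factorize(gl["prescription_id"].to_numpy())[0] if "prescription_id" in gl \
        else None
    return _timeline_from_arrays(
        _days(gl["dispense_date"]),
        gl["days_supply"].to_numpy(dtype=np.int64),
        gl["refills_remaining_after"].to_numpy(dtype=np.int64),
        rx,
    )


def _classify_days(
    a1c_days: np.ndarray,
    a1c_vals: np.ndarray,
    diabetic_lab_days: np.ndarray,
    supply: SupplyTimeline,
    det_day: int,
    th: DiagnosticThresholds,
    between_only: bool = False,
) -> tuple[bool, tuple[int, int] | None, str | None]:
    """Core classifier on integer-day arrays; returns (remission, pair, reason)."""
    sub = a1c_vals < th.remission_hba1c  # strict: equality does not qualify
    days = np.sort(a1c_days[sub])
    if len(days) < 2 or days[-1] - days[0] < th.remission_gap:
        return False, None, "no_pair"
    latency_ok = days >= det_day + th.remission_latency
    t1s = days[latency_ok]
    if len(t1s) == 0 or days[-1] - t1s[0] < th.remission_gap:
        return False, None, "insufficient_latency"
    med_ok = np.array([not supply.blocked(int(d)) for d in days])
    stage = "medication_covered"
    dmax = diabetic_lab_days.max() if len(diabetic_lab_days) else None
    found_med_pair = False
    dia = np.sort(diabetic_lab_days)
    for i in np.flatnonzero(latency_ok & med_ok):
        t1 = int(days[i])
        later = days[(days >= t1 + th.remission_gap) & med_ok]
        if len(later) == 0:
            continue
        found_med_pair = True
        if between_only:
            for t2 in later:
                if not np.any((dia >= t1) & (dia <= int(t2))):
                    return True, (t1, int(t2)), None
            continue
        if dmax is not None and dmax >= t1:
            continue
        return True, (t1, int(later[0])), None
    if found_med_pair:
        return False, None, "later_diabetes_lab"
    return False, None, stage


def classify_remission(
    a1cs: pd.DataFrame,
    all_labs: pd.DataFrame,
    supply: SupplyTimeline,
    detection_date,
    th: DiagnosticThresholds | None = None,
    between_only: bool = False,
) -> RemissionResult:
    """Classify one patient's remission status.

    ``a1cs`` holds the patient's HbA1c rows (date, value); ``all_labs`` all
    glucose and HbA1c rows, used for the no-subsequent-diabetes-lab rule.
    """
    th = th or DiagnosticThresholds()
    if detection_date is None or pd.isna(detection_date):
        raise ValueError("classify_remission requires a detection_date")
    det_day = int(np.datetime64(pd.Timestamp(detection_date), "D").astype("int64"))
    a1c_days = _days(a1cs["date"]) if len(a1cs) else np.array([], np.int64)
    a1c_vals = a1cs["value"].to_numpy(dtype=float) if len(a1cs) else np.array([])
    if len(all_labs):
        dia = _lab_abnormal(all_labs, th)
        dia_days = _days(all_labs["date"])[dia]
    else:
        dia_days = np.array([], np.int64)
    ok, pair, reason = _classify_days(
        a1c_days, a1c_vals, dia_days, supply, det_day, th, between_only=between_only
    )
    pid = str(a1cs["patient_id"].iloc[0]) if len(a1cs) else ""
    return RemissionResult(
        patient_id=pid,
        remission=ok,
        qualifying_dates=(
            (pd.Timestamp(np.datetime64(pair[0], "D")),
             pd.Timestamp(np.datetime64(pair[1], "D")))
            if pair
            else None
        ),
        threshold_used=th.remission_hba1c,
        failure_reason=reason,
    )


def follow_up_days(event_dates: pd.Series | np.ndarray, index_date) -> int:
    """Days from index to the last recorded event of any kind, floored at 0."""
    idx = int(np.datetime64(pd.Timestamp(index_date), "D").astype("int64"))
    arr = np.asarray(pd.to_datetime(pd.Series(event_dates)).to_numpy())
    if len(arr) == 0:
        return 0
    last = int(arr.astype("datetime64[D]").astype("int64").max())
    return max(last - idx, 0)


# ---------------------------------------------------------------------------
# batch classification over a cohort
# ---------------------------------------------------------------------------

def classify_cohort(
    ds: EhrDataset,
    cohort: pd.DataFrame,
    th: DiagnosticThresholds | None = None,
) -> pd.DataFrame:
    """Run the remission classifier for every cohort row.

    Returns a DataFrame with columns ``patient_id, remission, t1, t2,
    threshold, failure_reason``.
    """
    th = th or DiagnosticThresholds()
    pindex = pd.Index(cohort["patient_id"].to_numpy())
    lab_ix = pindex.get_indexer(ds.labs["patient_id"].to_numpy())
    labs = ds.labs.loc[lab_ix >= 0]
    lab_pid = lab_ix[lab_ix >= 0]
    lab_day = _days(labs["date"])
    lab_val = labs["value"].to_numpy(dtype=float)
    lab_a1c = (labs["kind"] == "hba1c").to_numpy()
    lab_dia = _lab_abnormal(labs, th)
    order = np.argsort(lab_pid, kind="mergesort")
    lab_pid, lab_day, lab_val = lab_pid[order], lab_day[order], lab_val[order]
    lab_a1c, lab_dia = lab_a1c[order], lab_dia[order]
    rows_ix = np.arange(len(cohort))
    bounds = np.searchsorted(lab_pid, rows_ix, side="left")
    bounds_hi = np.searchsorted(lab_pid, rows_ix, side="right")

    gl_ix = pindex.get_indexer(ds.dispenses["patient_id"].to_numpy())
    gl_sel = (gl_ix >= 0) & ds.dispenses["is_glucose_lowering"].to_numpy(dtype=bool)
    gl_pid = gl_ix[gl_sel]
    gl_day = _days(ds.dispenses.loc[gl_sel, "dispense_date"])
    gl_supply = ds.dispenses.loc[gl_sel, "days_supply"].to_numpy(np.int64)
    gl_refills = ds.dispenses.loc[gl_sel, "refills_remaining_after"].to_numpy(np.int64)
    gl_rx = pd.factorize(ds.dispenses.loc[gl_sel, "prescription_id"].to_numpy())[0]
    g_order = np.lexsort((gl_day, gl_pid))
    gl_pid, gl_day = gl_pid[g_order], gl_day[g_order]
    gl_supply, gl_refills = gl_supply[g_order], gl_refills[g_order]
    gl_rx = gl_rx[g_order]
    g_lo = np.searchsorted(gl_pid, rows_ix, side="left")
    g_hi = np.searchsorted(gl_pid, rows_ix, side="right")
    empty_supply = SupplyTimeline()

    def supply_for(k: int) -> SupplyTimeline:
        a, b = g_lo[k], g_hi[k]
        if a == b:
            return empty_supply
        return _timeline_from_arrays(
            gl_day[a:b], gl_supply[a:b], gl_refills[a:b], gl_rx[a:b]
        )

    det_days = _days(cohort["detection_date"])
    rows = []
    for k, (p, det) in enumerate(zip(cohort["patient_id"].to_numpy(), det_days)):
        lo, hi = bounds[k], bounds_hi[k]
        a1c_sel = lab_a1c[lo:hi]
        ok, pair, reason = _classify_days(
            lab_day[lo:hi][a1c_sel],
            lab_val[lo:hi][a1c_sel],
            lab_day[lo:hi][lab_dia[lo:hi]],
            supply_for(k),
            int(det),
            th,
        )
        rows.append((p, ok, pair[0] if pair else None, pair[1] if pair else None,
                     th.remission_hba1c, reason))
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "remission", "t1", "t2", "threshold", "failure_reason"],
    )
    for c in ("t1", "t2"):
        out[c] = pd.to_datetime(out[c], unit="D")
    return out
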