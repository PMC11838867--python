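"""Index-date assignment, eligibility exclusions and incident-diabetes detection.

Exposed patients are indexed at their first positive SARS-CoV-2 swab.
Unexposed patients receive a random date during a month in which they had a
qualifying event (any laboratory test, or a negative swab under the
negative-swab comparator), with the index-month distribution frequency
matched to the exposed distribution by largest-remainder quotas.

Two incident-diabetes definitions are implemented:

* cohort 1 — computable phenotype: two or more abnormal post-index lab
  values (glucose values in the 30 days after the index date are excluded to
  avoid corticosteroid-related transient hyperglycemia), or a diabetes ICD-10
  code (E08-E13), or an initial plus one refill dispense of a
  glucose-lowering prescription;
* cohort 2 — restrictive: two post-index HbA1c results at or above the
  diagnostic threshold.

Per-patient functions (:func:`has_prior_diabetes_evidence`,
:func:`check_eligibility`, :func:`detect_cohort1`, :func:`detect_cohort2`)
define the rules on one patient's event frame; :func:`build_cohort` applies
the same rules vectorized across a dataset and logs counts excluded at each
gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ComparatorFlavor, DiagnosticThresholds
from .dataset import EhrDataset, GLUCOSE_KINDS

logger = logging.getLogger("remitehr")

EXCLUSION_ORDER = (
    "prior_diabetes",
    "no_normal_lab_2y",
    "no_visit_1y",
    "no_incident_diabetes",
    "fewer_than_2_post_detection_a1c",
)


class MatchingError(ValueError):
    """Frequency matching has no target distribution (no exposed patients)."""


@dataclass(frozen=True)
class IndexAssignment:
    patient_id: str
    exposed: bool
    index_date: pd.Timestamp
    comparator_flavor: ComparatorFlavor = "any_lab"


@dataclass(frozen=True)
class EligibilityResult:
    patient_id: str
    eligible: bool
    exclusion_reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class DetectionResult:
    patient_id: str
    cohort: int
    detected: bool
    detection_date: pd.Timestamp | None = None
    criterion: str | None = None


def _days(s: pd.Series) -> np.ndarray:
    return s.to_numpy().astype("datetime64[D]").astype("int64")


def _day(ts) -> int:
    return int(np.datetime64(pd.Timestamp(ts), "D").astype("int64"))


def _ts(day: int) -> pd.Timestamp:
    return pd.Timestamp(np.datetime64(int(day), "D"))


def _month_start_day(day: np.ndarray | int):
    d64 = np.asarray(day, dtype="int64").astype("datetime64[D]")
    return d64.astype("datetime64[M]").astype("datetime64[D]").astype("int64")


def _lab_abnormal(labs: pd.DataFrame, th: DiagnosticThresholds) -> np.ndarray:
    """Boolean mask of lab rows meeting a diabetes diagnostic threshold."""
    kind = labs["kind"].to_numpy()
    value = labs["value"].to_numpy(dtype=float)
    cut = np.select(
        [
            kind == "hba1c",
            kind == "random_glucose",
            kind == "fasting_glucose",
            kind == "ogtt_2h_glucose",
        ],
        [th.hba1c_dm, th.random_glucose_dm, th.fasting_glucose_dm, th.ogtt_glucose_dm],
        default=np.inf,
    )
    return value >= cut


# ---------------------------------------------------------------------------
# index-date assignment with frequency matching
# ---------------------------------------------------------------------------

def _largest_remainder_quotas(counts: pd.Series, total: int) -> pd.Series:
    """Integer quotas proportional to ``counts`` summing to ``total``."""
    p = counts / counts.sum()
    raw = p * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    remainder = raw - base
    # deterministic tie-break: larger remainder first, then month order
    order = np.lexsort((np.arange(len(counts)), -remainder.to_numpy()))
    base = base.to_numpy()
    base[order[:short]] += 1
    return pd.Series(base, index=counts.index)


def assign_index_dates(
    ds: EhrDataset,
    flavor: ComparatorFlavor = "any_lab",
    seed: int = 0,
    window: tuple | None = None,
) -> pd.DataFrame:
    """Assign exposure flags and index dates to every assignable patient.

    Returns a DataFrame with columns ``patient_id, exposed, index_date,
    comparator_flavor``.  Unexposed patients with no candidate month are
    dropped (logged).  Raises :class:`MatchingError` when there are no
    exposed patients to define the matching target.
    """
    rng = np.random.default_rng(seed)
    pos = ds.swabs[ds.swabs["result"] == "positive"]
    first_pos = pos.groupby("patient_id")["result_date"].min()
    known = pd.Index(ds.patients["patient_id"])
    first_pos = first_pos[known.get_indexer(first_pos.index) >= 0]
    if first_pos.empty:
        raise MatchingError(
            "no exposed patients: the index-month matching target is undefined"
        )

    exposed_df = pd.DataFrame(
        {
            "patient_id": first_pos.index,
            "exposed": True,
            "index_date": first_pos.to_numpy(),
        }
    )
    # months as integer codes (months since 1970) for speed
    exp_months = (
        exposed_df["index_date"].to_numpy().astype("datetime64[M]").astype("int64")
    )
    month_counts = pd.Series(exp_months).value_counts().sort_index()

    if window is None:
        w_lo = exposed_df["index_date"].min().normalize().replace(day=1)
        w_hi = exposed_df["index_date"].max() + pd.offsets.MonthEnd(0)
    else:
        w_lo, w_hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])

    if flavor == "any_lab":
        ev = ds.labs[["patient_id", "date"]]
    else:
        neg = ds.swabs[ds.swabs["result"] == "negative"]
        ev = neg.rename(columns={"result_date": "date"})[["patient_id", "date"]]
    pos_idx = pd.Index(first_pos.index)
    keep = (
        (pos_idx.get_indexer(ev["patient_id"].to_numpy()) < 0)
        & (known.get_indexer(ev["patient_id"].to_numpy()) >= 0)
        & (ev["date"] >= w_lo).to_numpy()
        & (ev["date"] <= w_hi).to_numpy()
    )
    ev = ev.loc[keep]
    cand = pd.DataFrame(
        {
            "patient_id": ev["patient_id"].to_numpy(),
            "month": ev["date"].to_numpy().astype("datetime64[M]").astype("int64"),
        }
    ).drop_duplicates()
    # candidate months must be months in which exposed index dates occur
    cand = cand[cand["month"].isin(month_counts.index)]

    n_unexposed_all = int(
        (pos_idx.get_indexer(ds.patients["patient_id"].to_numpy()) < 0).sum()
    )
    assignable = cand["patient_id"].unique()
    dropped = n_unexposed_all - len(assignable)
    if dropped:
        logger.info(
            "index assignment: dropped %d unexposed patients with no candidate "
            "month (%s flavor)", dropped, flavor,
        )
    if len(assignable) == 0:
        unexposed_df = exposed_df.iloc[:0].copy()
    else:
        quotas = _largest_remainder_quotas(month_counts, len(assignable))
        cand = cand.sort_values(["month", "patient_id"], kind="mergesort")
        by_month = {m: g["patient_id"].to_numpy() for m, g in cand.groupby("month")}
        n_cand = {m: len(v) for m, v in by_month.items()}
        # scarce months first so their quotas can still be filled
        month_order = sorted(
            quotas.index,
            key=lambda m: (n_cand.get(m, 0) / max(quotas[m], 1), m),
        )
        assigned: dict[str, int] = {}
        for m in month_order:
            pool = by_month.get(m, ())
            avail = np.array([p for p in pool if p not in assigned], dtype=object)
            take = min(quotas[m], len(avail))
            if take > 0:
                chosen = rng.choice(avail, size=take, replace=False)
                for p in chosen:
                    assigned[p] = m
        leftovers = [p for p in assignable if p not in assigned]
        if leftovers:
            cand_by_pid = cand.groupby("patient_id")["month"].agg(list)
            for p in sorted(leftovers):
                months = cand_by_pid[p]
                w = np.array([month_counts.get(m, 0) for m in months], dtype=float)
                w = w / w.sum() if w.sum() > 0 else np.full(len(months), 1 / len(months))
                assigned[p] = months[int(rng.choice(len(months), p=w))]
        pids = np.array(sorted(assigned), dtype=object)
        mcode = np.array([assigned[p] for p in pids], dtype="int64")
        starts = mcode.astype("datetime64[M]").astype("datetime64[D]").astype("int64")
        ndays = (
            (mcode + 1).astype("datetime64[M]").astype("datetime64[D]").astype("int64")
            - starts
        )
        day = starts + np.floor(rng.random(len(pids)) * ndays).astype("int64")
        unexposed_df = pd.DataFrame(
            {
                "patient_id": pids,
                "exposed": False,
                "index_date": pd.to_datetime(day, unit="D"),
            }
        )

    out = pd.concat([exposed_df, unexposed_df], ignore_index=True)
    out["comparator_flavor"] = flavor
    out["index_date"] = pd.to_datetime(out["index_date"])
    return out.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-patient rules
# ---------------------------------------------------------------------------

def has_prior_diabetes_evidence(
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    index_date,
    th: DiagnosticThresholds,
) -> bool:
    """Any pre-index diabetes-range lab or diabetes ICD-10 code.

    The entire available pre-index history is searched (no lookback limit).
    """
    idx = pd.Timestamp(index_date)
    if len(labs):
        pre = labs[labs["date"] < idx]
        if len(pre) and _lab_abnormal(pre, th).any():
            return True
    if len(diagnoses):
        pre = diagnoses[diagnoses["date"] < idx]
        if any(th.icd10_is_diabetes(c) for c in pre["icd10_code"]):
            return True
    return False


def check_eligibility(
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    encounters: pd.DataFrame,
    assignment: IndexAssignment,
    th: DiagnosticThresholds,
) -> EligibilityResult:
    """Apply the pre-index exclusion gates, recording every failed reason."""
    idx = pd.Timestamp(assignment.index_date)
    reasons: list[str] = []
    if has_prior_diabetes_evidence(labs, diagnoses, idx, th):
        reasons.append("prior_diabetes")
    lo = idx - pd.Timedelta(days=th.pre_index_lab_lookback)
    pre = labs[(labs["date"] >= lo) & (labs["date"] < idx)]
    if not (len(pre) and (~_lab_abnormal(pre, th)).any()):
        reasons.append("no_normal_lab_2y")
    month_start = idx.normalize().replace(day=1)
    v_lo = month_start - pd.Timedelta(days=th.visit_lookback)
    visits = encounters[
        (encounters["type"] == "outpatient")
        & (encounters["date"] >= v_lo)
        & (encounters["date"] < month_start)
    ]
    if not len(visits):
        reasons.append("no_visit_1y")
    return EligibilityResult(
        patient_id=assignment.patient_id,
        eligible=not reasons,
        exclusion_reasons=tuple(reasons),
    )


def detect_cohort1(
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    dispenses: pd.DataFrame,
    index_date,
    th: DiagnosticThresholds,
) -> DetectionResult:
    """Computable-phenotype detection on post-index events.

    Glucose (not HbA1c) values dated in [index, index + 30 days] are ignored.
    Criterion dates: second qualifying abnormal lab; first in-range code;
    second fill (first refill) of a glucose-lowering prescription whose
    initial fill is on or after the index date.  The earliest satisfied
    criterion wins; ties break in that order.
    """
    idx = pd.Timestamp(index_date)
    pid = _pid_of(labs, diagnoses, dispenses)
    candidates: list[tuple[pd.Timestamp, str]] = []

    post = labs[labs["date"] >= idx]
    if len(post):
        in_window = (
            post["kind"].isin(GLUCOSE_KINDS)
            & (post["date"] <= idx + pd.Timedelta(days=th.steroid_exclusion_window))
        )
        ab = post[_lab_abnormal(post, th) & ~in_window.to_numpy()]
        if len(ab) >= 2:
            candidates.append((ab["date"].nsmallest(2).iloc[1], "two_labs"))
    post_dx = diagnoses[diagnoses["date"] >= idx]
    in_range = [d for d, c in zip(post_dx["date"], post_dx["icd10_code"])
                if th.icd10_is_diabetes(c)]
    if in_range:
        candidates.append((min(in_range), "icd_code"))
    gl = dispenses[dispenses["is_glucose_lowering"].astype(bool)]
    for _, rx in gl.groupby("prescription_id"):
        dates = rx["dispense_date"].sort_values()
        if len(dates) >= 2 and dates.iloc[0] >= idx:
            candidates.append((dates.iloc[1], "med_refill"))
    if not candidates:
        return DetectionResult(pid, 1, False)
    order = {"two_labs": 0, "icd_code": 1, "med_refill": 2}
    date, crit = min(candidates, key=lambda t: (t[0], order[t[1]]))
    return DetectionResult(pid, 1, True, date, crit)


def detect_cohort2(
    labs: pd.DataFrame, index_date, th: DiagnosticThresholds
) -> DetectionResult:
    """Detection by two post-index HbA1c results at or above threshold."""
    idx = pd.Timestamp(index_date)
    pid = _pid_of(labs)
    a1c = labs[
        (labs["kind"] == "hba1c")
        & (labs["date"] >= idx)
        & (labs["value"] >= th.hba1c_dm)
    ]
    if len(a1c) < 2:
        return DetectionResult(pid, 2, False)
    return DetectionResult(pid, 2, True, a1c["date"].nsmallest(2).iloc[1], "two_a1c")


def _pid_of(*frames: pd.DataFrame) -> str:
    for f in frames:
        if len(f):
            return str(f["patient_id"].iloc[0])
    return ""


# ---------------------------------------------------------------------------
# vectorized cohort construction
# ---------------------------------------------------------------------------

@dataclass
class CohortBuild:
    """Included patients plus the per-gate exclusion audit."""

    cohort: pd.DataFrame  # patient_id, exposed, index_date, detection_date, criterion
    exclusions: pd.DataFrame  # patient_id, gate (first failed), reasons (all failed)
    gate_counts: dict = field(default_factory=dict)


def build_cohort(
    ds: EhrDataset,
    cohort_id: int = 1,
    flavor: ComparatorFlavor = "any_lab",
    th: DiagnosticThresholds | None = None,
    seed: int = 0,
) -> CohortBuild:
    """Compose assignment, eligibility, detection and the post-detection
    HbA1c restriction over a full dataset."""
    th = th or DiagnosticThresholds()
    assign = assign_index_dates(ds, flavor=flavor, seed=seed)
    pid = assign["patient_id"].to_numpy()
    idx_day = _days(assign["index_date"])
    pindex = pd.Index(pid)  # hash-based row lookup

    lab_ix = pindex.get_indexer(ds.labs["patient_id"].to_numpy())
    labs = ds.labs.loc[lab_ix >= 0]
    lab_pid = lab_ix[lab_ix >= 0]
    lab_day = _days(labs["date"])
    lab_idx_day = idx_day[lab_pid]
    lab_abn = _lab_abnormal(labs, th)
    lab_is_glucose = labs["kind"].isin(GLUCOSE_KINDS).to_numpy()
    lab_is_a1c = (labs["kind"] == "hba1c").to_numpy()
    lab_val = labs["value"].to_numpy(dtype=float)

    dx_ix = pindex.get_indexer(ds.diagnoses["patient_id"].to_numpy())
    dx = ds.diagnoses.loc[dx_ix >= 0]
    dx_pid = dx_ix[dx_ix >= 0]
    dx_day = _days(dx["date"])
    dx_dm = np.array([th.icd10_is_diabetes(c) for c in dx["icd10_code"]], dtype=bool)
    dx_idx_day = idx_day[dx_pid]

    n = len(pid)

    def any_by_pid(rows: np.ndarray, mask: np.ndarray) -> np.ndarray:
        out = np.zeros(n, bool)
        np.logical_or.at(out, rows[mask], True)
        return out

    # gate 1: prior diabetes evidence over all pre-index history
    prior = any_by_pid(lab_pid, lab_abn & (lab_day < lab_idx_day))
    prior |= any_by_pid(dx_pid, dx_dm & (dx_day < dx_idx_day))

    # gate 2: a normal (sub-threshold) glucose/HbA1c lab in the 2 years prior
    in_lookback = (
        (lab_day >= lab_idx_day - th.pre_index_lab_lookback)
        & (lab_day < lab_idx_day)
    )
    normal_lab = any_by_pid(lab_pid, ~lab_abn & in_lookback)

    # gate 3: outpatient visit in the year before the index month
    enc_ix = pindex.get_indexer(ds.encounters["patient_id"].to_numpy())
    enc_sel = (enc_ix >= 0) & (ds.encounters["type"] == "outpatient").to_numpy()
    enc = ds.encounters.loc[enc_sel]
    enc_pid = enc_ix[enc_sel]
    enc_day = _days(enc["date"])
    month_start = _month_start_day(idx_day)
    es = month_start[enc_pid]
    visit = any_by_pid(
        enc_pid, (enc_day >= es - th.visit_lookback) & (enc_day < es)
    )

    # detection
    def second_smallest(rows: np.ndarray, days: np.ndarray) -> np.ndarray:
        out = np.full(n, np.iinfo(np.int64).max, np.int64)
        if len(rows) == 0:
            return out
        order = np.lexsort((days, rows))
        r, d = rows[order], days[order]
        first_pos_mask = np.ones(len(r), bool)
        first_pos_mask[1:] = r[1:] != r[:-1]
        starts = np.flatnonzero(first_pos_mask)
        counts = np.diff(np.append(starts, len(r)))
        has2 = counts >= 2
        out[r[starts[has2]]] = d[starts[has2] + 1]
        return out

    def min_by_pid(rows: np.ndarray, days: np.ndarray) -> np.ndarray:
        out = np.full(n, np.iinfo(np.int64).max, np.int64)
        np.minimum.at(out, rows, days)
        return out

    BIG = np.iinfo(np.int64).max
    if cohort_id == 1:
        excluded_glu = (
            lab_is_glucose
            & (lab_day >= lab_idx_day)
            & (lab_day <= lab_idx_day + th.steroid_exclusion_window)
        )
        ab_post = lab_abn & (lab_day >= lab_idx_day) & ~excluded_glu
        d_labs = second_smallest(lab_pid[ab_post], lab_day[ab_post])
        dxm = dx_dm & (dx_day >= dx_idx_day)
        d_code = min_by_pid(dx_pid[dxm], dx_day[dxm])
        disp_ix = pindex.get_indexer(ds.dispenses["patient_id"].to_numpy())
        disp_sel = (disp_ix >= 0) & ds.dispenses["is_glucose_lowering"].to_numpy(
            dtype=bool
        )
        disp = ds.dispenses.loc[disp_sel]
        if len(disp):
            dd = disp.assign(
                _pid=disp_ix[disp_sel],
                _day=_days(disp["dispense_date"]),
            ).sort_values(["_pid", "prescription_id", "_day"], kind="mergesort")
            p_arr = dd["_pid"].to_numpy()
            rx_arr = dd["prescription_id"].to_numpy()
            dy_arr = dd["_day"].to_numpy()
            new = np.ones(len(p_arr), bool)
            new[1:] = (p_arr[1:] != p_arr[:-1]) | (rx_arr[1:] != rx_arr[:-1])
            starts = np.flatnonzero(new)
            sizes = np.diff(np.append(starts, len(p_arr)))
            has2 = sizes >= 2
            gp = p_arr[starts[has2]]
            first_fill = dy_arr[starts[has2]]
            second_fill = dy_arr[starts[has2] + 1]
            keep = first_fill >= idx_day[gp]
            d_med = min_by_pid(gp[keep], second_fill[keep])
        else:
            d_med = np.full(n, BIG, np.int64)
        stacked = np.stack([d_labs, d_code, d_med])
        det_day = stacked.min(axis=0)
        crit_idx = stacked.argmin(axis=0)
        criterion = np.array(["two_labs", "icd_code", "med_refill"])[crit_idx]
        detected = det_day < BIG
    else:
        a1c_dm = lab_is_a1c & (lab_val >= th.hba1c_dm) & (lab_day >= lab_idx_day)
        det_day = second_smallest(lab_pid[a1c_dm], lab_day[a1c_dm])
        detected = det_day < BIG
        criterion = np.full(n, "two_a1c", dtype=object)

    # restriction: >= 2 HbA1c results captured after diabetes detection
    det_for_lab = det_day[lab_pid]
    post_det_a1c = lab_is_a1c & (lab_day > det_for_lab)
    cnt = np.zeros(n, np.int64)
    np.add.at(cnt, lab_pid[post_det_a1c], 1)
    enough_a1c = cnt >= 2

    # additive gates, in order
    gates = [
        ("prior_diabetes", prior),
        ("no_normal_lab_2y", ~normal_lab),
        ("no_visit_1y", ~visit),
        ("no_incident_diabetes", ~detected),
        ("fewer_than_2_post_detection_a1c", ~enough_a1c),
    ]
    first_fail = np.full(n, "", dtype=object)
    excluded = np.zeros(n, bool)
    gate_counts = {"n_input": n}
    for name, fail in gates:
        newly = fail & ~excluded
        first_fail[newly] = name
        gate_counts[name] = int(newly.sum())
        excluded |= fail
    include = ~excluded
    gate_counts["n_output"] = int(include.sum())

    reasons = [
        ";".join(name for name, fail in gates if fail[i]) for i in np.flatnonzero(excluded)
    ]
    exclusions = pd.DataFrame(
        {
            "patient_id": pid[excluded],
            "gate": first_fail[excluded],
            "reasons": reasons,
        }
    )
    cohort = pd.DataFrame(
        {
            "patient_id": pid[include],
            "exposed": assign["exposed"].to_numpy()[include],
            "index_date": assign["index_date"].to_numpy()[include],
            "detection_date": pd.to_datetime(det_day[include], unit="D"),
            "criterion": criterion[include],
        }
    )
    logger.info("cohort %d (%s): %s", cohort_id, flavor, gate_counts)
    return CohortBuild(cohort=cohort, exclusions=exclusions, gate_counts=gate_counts)
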