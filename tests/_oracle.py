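"""Independent brute-force oracles used only by tests.

These re-implement the remission and detection rules by exhaustive
enumeration over raw event lists, deliberately sharing no code with the
package's classifiers.
"""

from __future__ import annotations

GAP = 90
LATENCY = 90

THRESHOLDS = {
    "random_glucose": 200.0,
    "fasting_glucose": 126.0,
    "ogtt_2h_glucose": 200.0,
    "hba1c": 6.5,
}


def lab_is_diabetic(kind: str, value: float) -> bool:
    return value >= THRESHOLDS[kind]


def med_blocked(day: int, dispenses: list[tuple[str, int, int, int]]) -> bool:
    """dispenses: (rx_id, day, days_supply, refills_remaining_after)."""
    for _, d, supply, _ in dispenses:
        if d <= day < d + supply:
            return True
    rx_ids = {r for r, *_ in dispenses}
    for rx in rx_ids:
        fills = sorted(t for t in dispenses if t[0] == rx)
        last_on_or_before = None
        for t in fills:
            if t[1] <= day:
                last_on_or_before = t
        if last_on_or_before is not None and last_on_or_before[3] > 0:
            return True
    return False


def brute_force_remission(
    a1cs: list[tuple[int, float]],
    labs: list[tuple[int, str, float]],
    dispenses: list[tuple[str, int, int, int]],
    det_day: int,
    threshold: float = 6.5,
) -> tuple[bool, tuple[int, int] | None]:
    """Enumerate all HbA1c pairs; return (remission, earliest qualifying pair)."""
    diabetic_days = [d for d, k, v in labs if lab_is_diabetic(k, v)]
    pairs = []
    for i, (t1, v1) in enumerate(a1cs):
        for t2, v2 in a1cs:
            if not (v1 < threshold and v2 < threshold):
                continue
            if t2 - t1 < GAP:
                continue
            if t1 < det_day + LATENCY:
                continue
            if med_blocked(t1, dispenses) or med_blocked(t2, dispenses):
                continue
            if any(d >= t1 for d in diabetic_days):
                continue
            pairs.append((t1, t2))
    if not pairs:
        return False, None
    return True, min(pairs)


def brute_force_cohort1(
    labs: list[tuple[int, str, float]],
    codes: list[tuple[int, str]],
    dispenses: list[tuple[str, int, int, int]],
    index_day: int,
) -> tuple[bool, int | None, str | None]:
    """Exhaustively evaluate the computable phenotype on one event stream."""
    sat: list[tuple[int, int, str]] = []  # (day, tie_rank, criterion)
    usable = sorted(
        d for d, k, v in labs
        if lab_is_diabetic(k, v) and d >= index_day
        and not (k != "hba1c" and index_day <= d <= index_day + 30)
    )
    if len(usable) >= 2:
        sat.append((usable[1], 0, "two_labs"))
    dm_codes = sorted(
        d for d, c in codes
        if d >= index_day and c[:3] in {"E08", "E09", "E10", "E11", "E12", "E13"}
    )
    if dm_codes:
        sat.append((dm_codes[0], 1, "icd_code"))
    for rx in {r for r, *_ in dispenses}:
        fills = sorted(t[1] for t in dispenses if t[0] == rx)
        if len(fills) >= 2 and fills[0] >= index_day:
            sat.append((fills[1], 2, "med_refill"))
    if not sat:
        return False, None, None
    day, _, crit = min(sat)
    return True, day, crit


def brute_force_cohort2(
    labs: list[tuple[int, str, float]], index_day: int
) -> tuple[bool, int | None]:
    hits = sorted(
        d for d, k, v in labs if k == "hba1c" and v >= 6.5 and d >= index_day
    )
    if len(hits) < 2:
        return False, None
    return True, hits[1]
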