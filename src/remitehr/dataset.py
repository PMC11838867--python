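"""The longitudinal EHR event tables and their delimited-text round trip.

An :class:`EhrDataset` bundles one patient table and six event tables
(laboratory results, diagnosis events, medication dispenses, encounters,
SARS-CoV-2 swabs, vaccinations), plus an optional ground-truth sidecar written
by the synthetic generator and consumed only by tests.  Tables are plain
pandas DataFrames with ISO dates serialized as ``YYYY-MM-DD``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

LAB_KINDS = ("random_glucose", "fasting_glucose", "ogtt_2h_glucose", "hba1c")
GLUCOSE_KINDS = ("random_glucose", "fasting_glucose", "ogtt_2h_glucose")

#: table name -> (file name, date columns, column order)
TABLE_SPECS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "patients": (
        "patients.csv",
        ("birth_date",),
        (
            "patient_id", "birth_date", "sex_at_birth", "race_black",
            "race_latinx", "race_white", "race_other", "region", "smoking",
            "charlson", "bmi_true",
        ),
    ),
    "labs": ("labs.csv", ("date",), ("patient_id", "date", "kind", "value")),
    "diagnoses": ("diagnoses.csv", ("date",), ("patient_id", "date", "icd10_code")),
    "dispenses": (
        "dispenses.csv",
        ("dispense_date",),
        (
            "patient_id", "prescription_id", "dispense_date", "days_supply",
            "refills_remaining_after", "is_glucose_lowering",
        ),
    ),
    "encounters": (
        "encounters.csv",
        ("date", "discharge_date"),
        ("patient_id", "date", "type", "discharge_date"),
    ),
    "swabs": ("swabs.csv", ("result_date",), ("patient_id", "result_date", "result")),
    "vaccinations": (
        "vaccinations.csv",
        ("date",),
        ("patient_id", "date", "dose_number"),
    ),
    "truth": (
        "truth.csv",
        ("anchor_date", "detection_planned"),
        (
            "patient_id", "latent_exposed", "latent_diabetic", "latent_remitter",
            "remission_observable", "hospitalized", "anchor_date",
            "detection_planned",
        ),
    ),
}


#: explicit column dtypes for the CSV round trip
INT_COLUMNS = {"charlson", "days_supply", "refills_remaining_after", "dose_number"}
FLOAT_COLUMNS = {"value", "bmi_true"}
BOOL_COLUMNS = {
    "race_black", "race_latinx", "race_white", "race_other", "is_glucose_lowering",
    "latent_exposed", "latent_diabetic", "latent_remitter",
    "remission_observable", "hospitalized",
}


class ParseError(ValueError):
    """A malformed value in a dataset file; names file, line and field."""

    def __init__(self, file: str, line: int | None, field: str, message: str):
        self.file, self.line, self.field = file, line, field
        where = f"{file}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{where}, field {field!r}: {message}")


@dataclass
class EhrDataset:
    """All event tables of one synthetic or on-disk EHR extract."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    dispenses: pd.DataFrame
    encounters: pd.DataFrame
    swabs: pd.DataFrame
    vaccinations: pd.DataFrame
    truth: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for f in dc_fields(self):
            df = getattr(self, f.name)
            if df is not None:
                out[f.name] = df
        return out

    def equals(self, other: "EhrDataset") -> bool:
        a, b = self.tables(), other.tables()
        if set(a) != set(b):
            return False
        return all(a[k].reset_index(drop=True).equals(b[k].reset_index(drop=True))
                   for k in a)

    @staticmethod
    def empty(with_truth: bool = False) -> "EhrDataset":
        kw = {}
        for name, (_, date_cols, cols) in TABLE_SPECS.items():
            if name == "truth" and not with_truth:
                kw["truth"] = None
                continue
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            for c in date_cols:
                df[c] = pd.Series(dtype="datetime64[ns]")
            kw[name] = df
        return EhrDataset(**kw)


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], file: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(file, None, missing[0], "missing column")


def _first_bad(mask: pd.Series) -> int:
    # +2: header line plus 1-based numbering
    return int(np.flatnonzero(mask.to_numpy())[0]) + 2


def _validate(name: str, df: pd.DataFrame, file: str) -> None:
    """Check table invariants, raising ParseError at the first offending row."""
    if name == "labs":
        bad = ~df["kind"].isin(LAB_KINDS)
        if bad.any():
            raise ParseError(file, _first_bad(bad), "kind", "unknown lab kind")
        v = pd.to_numeric(df["value"], errors="coerce")
        bad = v.isna() | (v <= 0)
        if bad.any():
            raise ParseError(file, _first_bad(bad), "value", "value must be > 0")
        is_a1c = df["kind"] == "hba1c"
        bad = is_a1c & ((v < 3) | (v > 20))
        if bad.any():
            raise ParseError(file, _first_bad(bad), "value",
                             "hba1c out of range [3, 20] percent")
        bad = ~is_a1c & ((v < 30) | (v > 1000))
        if bad.any():
            raise ParseError(file, _first_bad(bad), "value",
                             "glucose out of range [30, 1000] mg/dL")
    elif name == "dispenses":
        v = pd.to_numeric(df["days_supply"], errors="coerce")
        bad = v.isna() | (v < 1)
        if bad.any():
            raise ParseError(file, _first_bad(bad), "days_supply",
                             "days_supply must be >= 1")
        v = pd.to_numeric(df["refills_remaining_after"], errors="coerce")
        bad = v.isna() | (v < 0)
        if bad.any():
            raise ParseError(file, _first_bad(bad), "refills_remaining_after",
                             "must be a non-negative integer")
    elif name == "encounters":
        bad = ~df["type"].isin(("outpatient", "admission"))
        if bad.any():
            raise ParseError(file, _first_bad(bad), "type", "unknown encounter type")
        has_dc = df["discharge_date"].notna()
        bad = has_dc & (df["discharge_date"] < df["date"])
        if bad.any():
            raise ParseError(file, _first_bad(bad), "discharge_date",
                             "discharge before admission")
    elif name == "swabs":
        bad = ~df["result"].isin(("positive", "negative"))
        if bad.any():
            raise ParseError(file, _first_bad(bad), "result", "unknown swab result")
    elif name == "diagnoses":
        ok = df["icd10_code"].astype(str).str.match(r"^[A-Z]\d\d(\.\d+)?$")
        bad = ~ok
        if bad.any():
            raise ParseError(file, _first_bad(bad), "icd10_code",
                             "code must look like letter+digits(+subcode)")
    elif name == "vaccinations":
        v = pd.to_numeric(df["dose_number"], errors="coerce")
        bad = v.isna() | (v < 1)
        if bad.any():
            raise ParseError(file, _first_bad(bad), "dose_number",
                             "dose_number must be a positive integer")


def write_dataset(ds: EhrDataset, directory: Path | str) -> list[Path]:
    """Write every table as UTF-8 CSV with a header row; returns file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in ds.tables().items():
        file, date_cols, cols = TABLE_SPECS[name]
        out = df.copy()
        for c in date_cols:
            if c in out.columns:
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        out = out[[c for c in cols if c in out.columns]]
        path = directory / file
        out.to_csv(path, index=False)
        written.append(path)
    return written


def read_dataset(directory: Path | str) -> EhrDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises :class:`ParseError` naming the file, line and field on malformed
    input.  The truth sidecar is optional.
    """
    directory = Path(directory)
    kw: dict[str, pd.DataFrame | None] = {}
    for name, (file, date_cols, cols) in TABLE_SPECS.items():
        path = directory / file
        if name == "truth" and not path.exists():
            kw[name] = None
            continue
        if not path.exists():
            raise ParseError(file, None, "-", "required table file missing")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _require_columns(df, cols, file)
        df = df[list(cols)]
        df = df.replace({"": None})
        for c in date_cols:
            try:
                df[c] = pd.to_datetime(df[c], format="%Y-%m-%d")
            except (ValueError, TypeError):
                parsed = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
                bad = parsed.isna() & df[c].notna()
                raise ParseError(file, _first_bad(bad), c, "unparseable ISO date")
        for c in df.columns:
            if c in date_cols:
                continue
            if c in INT_COLUMNS:
                converted = pd.to_numeric(df[c], errors="coerce")
                bad = converted.isna()
                if bad.any():
                    raise ParseError(file, _first_bad(bad), c, "expected an integer")
                df[c] = converted.astype(np.int64)
            elif c in FLOAT_COLUMNS:
                converted = pd.to_numeric(
                    df[c].where(df[c].notna(), np.nan), errors="coerce"
                )
                bad = converted.isna() & df[c].notna()
                if bad.any():
                    raise ParseError(file, _first_bad(bad), c, "expected a number")
                df[c] = converted.astype(float)
            elif c in BOOL_COLUMNS:
                converted = df[c].map({"True": True, "False": False})
                bad = converted.isna()
                if bad.any():
                    raise ParseError(file, _first_bad(bad), c, "expected True/False")
                df[c] = converted.astype(bool)
        _validate(name, df, file)
        kw[name] = df
    return EhrDataset(**kw)  # type: ignore[arg-type]
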