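"""Case ascertainment from a hospital admission line-listing.

A survey line-listing holds one row per hip-fracture admission.  The case
definition keeps first low-energy hip fractures (ICD-10 S72.0/S72.1/S72.2)
in citizens at or above a minimum age, admitted inside the survey window;
high-trauma and pathological fractures are excluded, and repeat admissions
for the same fracture site are dropped so each fracture is counted once.

Rejection reasons are assigned under a fixed precedence so that the report
is reproducible: window → citizenship → age → ICD → trauma → pathological
(→ duplicate, applied by :func:`deduplicate` after filtering).  Each record
is counted once, under its first failing rule.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import pandas as pd

from .incidence import AgeBand, default_bands

logger = logging.getLogger(__name__)

COLUMNS = [
    "patient_id", "age", "sex", "admission_date", "icd10",
    "mechanism", "pathological", "citizen", "hospital_id",
]

MECHANISMS = {"low_energy", "road_traffic", "other_major_trauma"}

#: Rejection reasons in precedence order.
REASONS = [
    "outside-window", "non-citizen", "under-age",
    "ineligible-icd", "high-trauma", "pathological",
]


@dataclass(frozen=True)
class FractureRecord:
    """One hospital admission with the attributes eligibility depends on."""

    patient_id: str
    age: int
    sex: str
    admission_date: dt.date
    icd10: str
    mechanism: str
    pathological: bool
    citizen: bool
    hospital_id: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if not self.icd10:
            raise ValueError("icd10 must be non-empty")
        if self.sex not in {"male", "female"}:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class CaseDefinition:
    """Eligibility rules for a first low-energy hip fracture."""

    eligible_icd10: frozenset[str] = frozenset({"S72.0", "S72.1", "S72.2"})
    min_age: int = 45
    survey_start: dt.date = dt.date(2017, 1, 1)
    survey_end: dt.date = dt.date(2018, 12, 31)
    require_citizen: bool = True

    def __post_init__(self) -> None:
        if self.min_age < 0:
            raise ValueError("min_age must be non-negative")
        if self.survey_start >= self.survey_end:
            raise ValueError("survey_start must precede survey_end")


def read_linelisting(path) -> pd.DataFrame:
    """Read an admission line-listing CSV.

    Expects the header ``patient_id,age,sex,admission_date,icd10,mechanism,
    pathological,citizen,hospital_id`` with ISO-8601 dates and 0/1 booleans.
    Unparseable rows are dropped with a logged row number; parsing continues.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"line-listing missing columns: {missing}")
    rows, bad = [], 0
    for i, row in raw.iterrows():
        try:
            parsed = {
                "patient_id": row["patient_id"],
                "age": int(row["age"]),
                "sex": row["sex"],
                "admission_date": dt.date.fromisoformat(row["admission_date"]),
                "icd10": row["icd10"],
                "mechanism": row["mechanism"],
                "pathological": bool(int(row["pathological"])),
                "citizen": bool(int(row["citizen"])),
                "hospital_id": row["hospital_id"],
            }
            if parsed["age"] < 0 or not parsed["icd10"]:
                raise ValueError("invalid field value")
            rows.append(parsed)
        except (ValueError, KeyError) as exc:
            bad += 1
            logger.warning("row %d unparseable (%s); skipped", i + 2, exc)
    df = pd.DataFrame(rows, columns=COLUMNS)
    if bad:
        logger.warning("%d unparseable rows skipped", bad)
    return df


def write_linelisting(df: pd.DataFrame, path) -> None:
    out = df[COLUMNS].copy()
    out["pathological"] = out["pathological"].astype(int)
    out["citizen"] = out["citizen"].astype(int)
    out.to_csv(path, index=False)


def _site_class(icd10: pd.Series) -> pd.Series:
    """Fracture-site class used for deduplication: the 4-character ICD-10
    stem (S72.0 / S72.1 / S72.2)."""
    return icd10.str[:5]


def filter_eligible(
    records: pd.DataFrame, rules: CaseDefinition | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the case definition; return (retained, rejection counts).

    Each rejected record is counted once under the first failing rule in the
    fixed precedence order, so ``len(records) == len(retained) +
    rejections.sum()``.
    """
    rules = rules or CaseDefinition()
    if records.empty:
        return records.copy(), pd.Series(0, index=REASONS, name="count")
    df = records
    dates = pd.to_datetime(df["admission_date"]).dt.date
    prefixes = tuple(rules.eligible_icd10)
    fails = {
        "outside-window": (dates < rules.survey_start) | (dates > rules.survey_end),
        "non-citizen": (~df["citizen"].astype(bool)) if rules.require_citizen
        else pd.Series(False, index=df.index),
        "under-age": df["age"].astype(int) < rules.min_age,
        "ineligible-icd": ~df["icd10"].str.startswith(prefixes),
        "high-trauma": df["mechanism"] != "low_energy",
        "pathological": df["pathological"].astype(bool),
    }
    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    for name in REASONS:
        reason = reason.mask(reason.isna() & fails[name], name)
    retained = df[reason.isna()].copy()
    counts = reason.value_counts().reindex(REASONS, fill_value=0).rename("count")
    return retained, counts


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep the earliest admission per (patient, fracture-site class).

    Output is sorted by (admission_date, patient_id) so the result does not
    depend on input row order.
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    df["_site"] = _site_class(df["icd10"])
    df = df.sort_values(["admission_date", "patient_id"], kind="mergesort")
    df = df.drop_duplicates(subset=["patient_id", "_site"], keep="first")
    return df.drop(columns="_site").reset_index(drop=True)


def tabulate_counts(
    records: pd.DataFrame, bands: list[AgeBand] | None = None
) -> pd.DataFrame:
    """Count records per (sex, band).  Ages beyond the last band start fall
    into the open-ended terminal band."""
    bands = bands or default_bands()
    rows = []
    for sex in ("male", "female"):
        sub = records[records["sex"] == sex] if not records.empty else records
        for band in bands:
            if records.empty:
                n = 0
            elif band.open_ended:
                n = int((sub["age"] >= band.start).sum())
            else:
                n = int(sub["age"].between(band.start, band.end).sum())
            rows.append((sex, band.start, band.end, n))
    out = pd.DataFrame(rows, columns=["sex", "band_start", "band_end", "events"])
    if not records.empty:
        in_scope = int((records["age"] >= bands[0].start).sum())
        if out["events"].sum() != in_scope:
            raise AssertionError("band assignment lost records")
        over = int((records["age"] > bands[-1].end).sum())
        if over:
            logger.info(
                "%d records older than %d assigned to the open-ended %s band",
                over, bands[-1].end, bands[-1].label,
            )
    return out
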