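"""Booking-record I/O, cleaning rules, patient profiles and entity summaries.

The raw input is an administrative booking table: one row per booking event,
carrying the patient (id, gender, age at prescription), the appointment
(date, facility, health-service provision) and the referral (prescription
date, status).  Records are held in a :class:`pandas.DataFrame` with the
column schema in :data:`BOOKING_COLUMNS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column schema of a booking table.  ``practitioner_id`` and
#: ``district_id`` are optional at read time.
BOOKING_COLUMNS = [
    "patient_id",
    "gender",
    "age_at_prescription",
    "practitioner_id",
    "prescription_date",
    "appointment_date",
    "status",
    "facility_id",
    "provision_id",
]

REQUIRED_COLUMNS = [
    "patient_id",
    "gender",
    "age_at_prescription",
    "prescription_date",
    "appointment_date",
    "status",
    "facility_id",
    "provision_id",
]

#: Identifier values treated as encoding errors by cleaning rule 1.
UNKNOWN_TOKENS = frozenset({"", "UNKNOWN", "NA"})

#: Order of the five cleaning rules; each removed record is attributed to the
#: first rule that removes it.
CLEANING_RULES = (
    "unknown_identifier",
    "not_valid_status",
    "below_min_appointments",
    "zero_appointment",
    "negative_wait",
)


@dataclass
class CleaningReport:
    """Audit of the five-rule cleaning pass."""

    counts_removed_per_rule: dict[str, int]
    records_in: int
    records_out: int
    patients_in: int
    patients_out: int

    def to_dict(self) -> dict:
        return {
            "counts_removed_per_rule": dict(self.counts_removed_per_rule),
            "records_in": self.records_in,
            "records_out": self.records_out,
            "patients_in": self.patients_in,
            "patients_out": self.patients_out,
        }


@dataclass
class EntitySummary:
    """Descriptive counts and frequency tables of a booking table."""

    unique_counts: dict[str, int]
    provision_frequencies: pd.Series  # descending relative frequencies
    cumulative_top_n: dict[int, float] = field(default_factory=dict)
    monthly_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


def read_bookings(
    path,
    sep: str = ",",
    column_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Read a delimited booking file.

    Parameters
    ----------
    path : str or file-like
        CSV file with a header row declaring the required columns
        (ISO-8601 dates).
    sep : str
        Field delimiter.
    column_map : dict, optional
        Mapping from file column names to canonical names in
        :data:`BOOKING_COLUMNS`.

    Returns
    -------
    (records, n_malformed)
        ``records`` is a DataFrame in canonical schema, row order preserved;
        rows whose dates do not parse are dropped and counted in
        ``n_malformed``.

    Raises
    ------
    ValueError
        If a required column is missing from the header.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    for opt in ("practitioner_id", "district_id"):
        if opt not in df.columns:
            df[opt] = ""

    presc = pd.to_datetime(df["prescription_date"], format="%Y-%m-%d", errors="coerce")
    appt = pd.to_datetime(df["appointment_date"], format="%Y-%m-%d", errors="coerce")
    age = pd.to_numeric(df["age_at_prescription"], errors="coerce")
    gender = pd.to_numeric(df["gender"], errors="coerce")

    # blank appointment dates are legal (cleaning rule 4 removes them later);
    # a non-blank date that fails to parse marks the row malformed
    appt_ok = appt.notna() | (df["appointment_date"].str.strip() == "")
    ok = (
        presc.notna()
        & appt_ok
        & age.notna()
        & (age >= 0)
        & gender.isin([0, 1])
    )
    n_malformed = int((~ok).sum())
    if n_malformed:
        logger.warning("read_bookings: %d malformed row(s) skipped", n_malformed)

    out = df.loc[ok, ["patient_id", "practitioner_id", "status", "facility_id",
                      "provision_id", "district_id"]].copy()
    out["gender"] = gender[ok].astype(np.int8)
    out["age_at_prescription"] = age[ok].astype(np.int16)
    out["prescription_date"] = presc[ok]
    out["appointment_date"] = appt[ok]
    return out.reset_index(drop=True), n_malformed


def write_bookings(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a booking table back to CSV with the canonical schema."""
    out = df.copy()
    for c in ("prescription_date", "appointment_date"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d").fillna("")
    out.to_csv(path, sep=sep, index=False, columns=BOOKING_COLUMNS)


def clean_records(
    records: pd.DataFrame,
    min_appointments: int = 5,
    unknown_tokens: frozenset[str] = UNKNOWN_TOKENS,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the five cleaning rules in order and audit the removals.

    Rules, applied sequentially (a record is attributed to the first rule
    that removes it):

    1. drop records with unknown/blank patient, provision or facility
       identifiers (encoding errors);
    2. keep only ``status == "Valid"``;
    3. keep only patients with at least ``min_appointments`` remaining
       records;
    4. drop records with no appointment date (zero-appointment records);
    5. drop records whose appointment precedes the prescription
       (negative days of waiting).
    """
    if records.empty:
        raise ValueError("clean_records requires a non-empty record table")

    counts: dict[str, int] = {r: 0 for r in CLEANING_RULES}
    patients_in = records["patient_id"].nunique()
    n_in = len(records)
    df = records

    id_cols = ["patient_id", "provision_id", "facility_id"]
    bad = np.zeros(len(df), dtype=bool)
    for c in id_cols:
        bad |= df[c].astype(str).str.strip().str.upper().isin(
            {t.upper() for t in unknown_tokens}
        ).to_numpy()
    counts["unknown_identifier"] = int(bad.sum())
    df = df.loc[~bad]

    keep = df["status"] == "Valid"
    counts["not_valid_status"] = int((~keep).sum())
    df = df.loc[keep]

    sizes = df.groupby("patient_id")["patient_id"].transform("size")
    keep = sizes >= min_appointments
    counts["below_min_appointments"] = int((~keep).sum())
    df = df.loc[keep]

    keep = df["appointment_date"].notna()
    counts["zero_appointment"] = int((~keep).sum())
    df = df.loc[keep]

    wait = (df["appointment_date"] - df["prescription_date"]).dt.days
    keep = wait >= 0
    counts["negative_wait"] = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)

    report = CleaningReport(
        counts_removed_per_rule=counts,
        records_in=n_in,
        records_out=len(df),
        patients_in=patients_in,
        patients_out=df["patient_id"].nunique() if len(df) else 0,
    )
    return df, report


def build_profiles(records: pd.DataFrame) -> pd.DataFrame:
    """One profile per patient: gender and estimated birth year.

    Birth year is the minimum over the patient's records of
    (prescription year - age at prescription).  Conflicting gender codes
    resolve to the mode, ties to 0.
    """
    df = records.copy()
    df["_by"] = df["prescription_date"].dt.year - df["age_at_prescription"]

    def _gender_mode(s: pd.Series) -> int:
        counts = s.value_counts()
        if len(counts) > 1:
            logger.warning("conflicting gender codes for a patient; taking mode")
            top = counts.max()
            return int(min(counts[counts == top].index))
        return int(counts.index[0])

    prof = df.groupby("patient_id").agg(
        gender=("gender", _gender_mode),
        birth_year=("_by", "min"),
    )
    return prof.reset_index()


def summarize_entities(
    records: pd.DataFrame,
    top_n: tuple[int, ...] = (50, 100, 150, 200),
) -> EntitySummary:
    """Unique-entity counts, provision frequency table, top-n cumulative
    frequencies and monthly appointment counts."""
    if records.empty:
        return EntitySummary(
            unique_counts={k: 0 for k in
                           ("appointments", "patients", "provisions",
                            "appointment_dates", "facilities")},
            provision_frequencies=pd.Series(dtype=float),
        )
    unique_counts = {
        "appointments": len(records),
        "patients": records["patient_id"].nunique(),
        "provisions": records["provision_id"].nunique(),
        "appointment_dates": records["appointment_date"].nunique(),
        "facilities": records["facility_id"].nunique(),
    }
    freq = records["provision_id"].value_counts(normalize=True)
    cum = {n: float(freq.iloc[:n].sum()) for n in top_n}
    monthly = (
        records.dropna(subset=["appointment_date"])
        .groupby(records["appointment_date"].dt.to_period("M"))
        .size()
    )
    return EntitySummary(
        unique_counts=unique_counts,
        provision_frequencies=freq,
        cumulative_top_n=cum,
        monthly_counts=monthly,
    )
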