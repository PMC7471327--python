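import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from attendcast.features import WeekCalendar, WeeklyHistory
from attendcast.records import BOOKING_COLUMNS


def make_bookings(rows):
    """Build a canonical booking frame from compact row tuples:
    (patient_id, gender, age, presc_date, appt_date, status, facility,
    provision)."""
    df = pd.DataFrame(
        [(pid, g, a, "", pr, ap, st, fac, prov)
         for pid, g, a, pr, ap, st, fac, prov in rows],
        columns=BOOKING_COLUMNS,
    )
    df["prescription_date"] = pd.to_datetime(df["prescription_date"])
    df["appointment_date"] = pd.to_datetime(
        df["appointment_date"], errors="coerce")
    df["gender"] = df["gender"].astype(np.int8)
    df["age_at_prescription"] = df["age_at_prescription"].astype(np.int16)
    df["district_id"] = ""
    return df


def make_history(active_weeks, T, counts=None):
    """WeeklyHistory with the given 1-based booking weeks on a single
    provision/facility column."""
    tot = np.zeros(T, dtype=np.int32)
    for i, w in enumerate(active_weeks):
        tot[w - 1] += counts[i] if counts is not None else 1
    P = sp.csr_matrix(tot[:, None])
    return WeeklyHistory("pat", P, P.copy())


@pytest.fixture
def calendar():
    return WeekCalendar("2014-01-01", "2016-12-31")


@pytest.fixture(scope="session")
def small_dataset():
    """Small end-to-end featurized dataset shared by model and experiment
    tests (generated once per session)."""
    from attendcast.features import build_window_dataset
    from attendcast.records import clean_records
    from attendcast.synth import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(n_patients=30, facility_loyalty=0.9,
                          revisit_burst=0.5, seed=42)
    bookings, _, facilities = generate_dataset(cfg)
    cleaned, _ = clean_records(bookings)
    cal = WeekCalendar(cfg.period_start, cfg.period_end)
    district_of = dict(zip(facilities["facility_id"],
                           facilities["district_id"]))
    return build_window_dataset(cleaned, cal, district_of, seed=1)
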