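"""Featurization: weekly count matrices, provision clusters, facility
regrouping, sliding-window extraction, scaling and labeling.

A patient's booking history is binned into calendar weeks, producing two
sparse count matrices per patient: ``P_full`` (weeks x provisions) and
``F_full`` (weeks x facilities).  Every 52-week window with bookings in at
least four distinct weeks and at least one booking in the following 9 weeks
becomes one training sample; provision columns are collapsed to k-means
clusters, facility columns to the top-10 facilities, their districts and a
rest-of-universe group; counts are squashed to [0, 1) by
``phi(x) = 1 - lambda**(-x)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

WINDOW_LEN = 52
HORIZON = 9
MIN_ACTIVE_WEEKS = 4
N_TOP_FACILITIES = 10


@dataclass(frozen=True)
class WeekCalendar:
    """Consecutive 7-day weeks anchored at ``period_start`` (1-based)."""

    period_start: pd.Timestamp
    period_end: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "period_start", pd.Timestamp(self.period_start))
        object.__setattr__(self, "period_end", pd.Timestamp(self.period_end))
        if self.period_end < self.period_start:
            raise ValueError("period_end precedes period_start")

    @property
    def n_weeks(self) -> int:
        days = (self.period_end - self.period_start).days + 1
        return math.ceil(days / 7)

    def week_index(self, dates) -> np.ndarray:
        """1-based week index of each date; raises if outside the period."""
        d = pd.to_datetime(pd.Series(dates))
        off = (d - self.period_start).dt.days.to_numpy()
        if (off < 0).any() or (off > (self.period_end - self.period_start).days).any():
            bad = d[(off < 0) | (off > (self.period_end - self.period_start).days)]
            raise ValueError(f"date(s) outside calendar period: {list(bad.head(3))}")
        return off // 7 + 1


@dataclass
class WeeklyHistory:
    """Per-patient weekly count matrices in sparse form."""

    patient_id: str
    P_full: sp.csr_matrix  # T x n_provisions
    F_full: sp.csr_matrix  # T x n_facilities


@dataclass
class ProvisionClustering:
    """k-means partition of the provision universe."""

    assignment: dict[str, int]  # provision_id -> cluster in 1..k
    k: int
    feature_matrix: pd.DataFrame | None = None


@dataclass
class FacilityCatalog:
    """Facility -> feature-column map: ranks 1..10, district groups, rest."""

    top_facilities: list[str]
    district_of: dict[str, str]
    column_of: dict[str, int]
    n_district_groups: int

    @property
    def n_columns(self) -> int:
        return N_TOP_FACILITIES + self.n_district_groups + 1


@dataclass(frozen=True)
class ScalingConfig:
    """Parameters of the count squashing and age normalization."""

    lam: float = math.e / 2
    age_min: float = 0.0
    age_max: float = 120.0

    def __post_init__(self):
        if self.lam <= 1:
            raise ValueError("lambda must exceed 1 for phi to increase into [0,1)")


@dataclass
class WindowDataset:
    """Materialized window samples ready for model training.

    ``P`` and ``F`` hold phi-scaled values; ``F_tilde`` holds raw forecast
    counts (it exists only to produce labels and diagnostics).
    """

    patient_id: np.ndarray  # (N,) str
    window_id: np.ndarray   # (N,) int, start week of the window
    gender: np.ndarray      # (N,) float
    age: np.ndarray         # (N,) float in [0,1]
    P: np.ndarray           # (N, 52, k)
    F: np.ndarray           # (N, 52, n_cols)
    F_tilde: np.ndarray     # (N, 9, n_cols) raw counts
    y: np.ndarray           # (N, n_top+1) binary

    def __len__(self) -> int:
        return len(self.window_id)

    def subset(self, idx) -> "WindowDataset":
        return WindowDataset(*(getattr(self, f)[idx] for f in
                               ("patient_id", "window_id", "gender", "age",
                                "P", "F", "F_tilde", "y")))

    def save(self, path) -> None:
        np.savez_compressed(
            path, patient_id=self.patient_id, window_id=self.window_id,
            gender=self.gender, age=self.age, P=self.P, F=self.F,
            F_tilde=self.F_tilde, y=self.y,
        )

    @classmethod
    def load(cls, path) -> "WindowDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(**{k: z[k] for k in
                          ("patient_id", "window_id", "gender", "age",
                           "P", "F", "F_tilde", "y")})


# ---------------------------------------------------------------------------
# weekly matrices

def build_weekly_matrices(
    records: pd.DataFrame,
    calendar: WeekCalendar,
    provisions: list[str] | None = None,
    facilities: list[str] | None = None,
) -> tuple[dict[str, WeeklyHistory], list[str], list[str]]:
    """Bin each patient's bookings into weekly provision/facility counts.

    Returns the per-patient histories plus the (sorted) provision and
    facility universes defining the column order.
    """
    if provisions is None:
        provisions = sorted(records["provision_id"].unique())
    if facilities is None:
        facilities = sorted(records["facility_id"].unique())
    p_idx = {p: i for i, p in enumerate(provisions)}
    f_idx = {f: i for i, f in enumerate(facilities)}

    weeks = calendar.week_index(records["appointment_date"]) - 1
    T = calendar.n_weeks
    histories: dict[str, WeeklyHistory] = {}
    prov_codes = records["provision_id"].map(p_idx).to_numpy()
    fac_codes = records["facility_id"].map(f_idx).to_numpy()
    for pid, grp_idx in records.groupby("patient_id").indices.items():
        w = weeks[grp_idx]
        ones = np.ones(len(grp_idx), dtype=np.int32)
        P = sp.coo_matrix((ones, (w, prov_codes[grp_idx])),
                          shape=(T, len(provisions))).tocsr()
        F = sp.coo_matrix((ones, (w, fac_codes[grp_idx])),
                          shape=(T, len(facilities))).tocsr()
        histories[pid] = WeeklyHistory(pid, P, F)
    return histories, provisions, facilities


# ---------------------------------------------------------------------------
# provision clustering

def provision_features(records: pd.DataFrame, calendar: WeekCalendar) -> pd.DataFrame:
    """Per-provision statistical feature vectors (standardized columns).

    Features: overall relative frequency, distinct patients, mean and
    standard deviation of patient age, mean weekly count, proportion of
    weeks with at least one booking, mean prescription-to-appointment wait.
    """
    T = calendar.n_weeks
    df = records.copy()
    df["_week"] = calendar.week_index(df["appointment_date"])
    df["_wait"] = (df["appointment_date"] - df["prescription_date"]).dt.days
    g = df.groupby("provision_id")
    feats = pd.DataFrame({
        "frequency": g.size() / len(df),
        "n_patients": g["patient_id"].nunique(),
        "age_mean": g["age_at_prescription"].mean(),
        "age_std": g["age_at_prescription"].std().fillna(0.0),
        "weekly_mean": g.size() / T,
        "week_coverage": g["_week"].nunique() / T,
        "wait_mean": g["_wait"].mean(),
    })
    scaled = StandardScaler().fit_transform(feats.to_numpy(dtype=float))
    return pd.DataFrame(scaled, index=feats.index, columns=feats.columns)


def cluster_provisions(
    feature_matrix: pd.DataFrame, k: int = 8, seed: int = 0
) -> ProvisionClustering:
    """k-means (k-means++ init, 10 restarts, seeded) over provision features."""
    if k > len(feature_matrix):
        raise ValueError(f"k={k} exceeds the {len(feature_matrix)} provisions")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(feature_matrix.to_numpy(dtype=float))
    assignment = {p: int(c) + 1 for p, c in zip(feature_matrix.index, labels)}
    return ProvisionClustering(assignment=assignment, k=k,
                               feature_matrix=feature_matrix)


def select_k_silhouette(
    feature_matrix: pd.DataFrame, k_range=range(2, 11), seed: int = 0
) -> int:
    """Silhouette-based k selection utility for synthetic-data sanity checks."""
    best_k, best_s = None, -np.inf
    X = feature_matrix.to_numpy(dtype=float)
    for k in k_range:
        if k >= len(X):
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        s = silhouette_score(X, km.labels_)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


# ---------------------------------------------------------------------------
# facility catalog

def rank_facilities(
    forecast_totals: pd.Series,
    district_of: dict[str, str],
    n_top: int = N_TOP_FACILITIES,
) -> FacilityCatalog:
    """Rank facilities by forecast-window appointment volume and regroup.

    The top ``n_top`` facilities (ties broken by lexicographic id) become
    columns 1..n_top; remaining facilities in one of the top facilities'
    districts map to that district's group column; everything else maps to
    the final rest-of-universe column.
    """
    order = sorted(forecast_totals.index, key=lambda f: (-forecast_totals[f], f))
    top = order[:n_top]
    top_districts: list[str] = []
    for f in top:
        d = district_of.get(f)
        if d is not None and d not in top_districts:
            top_districts.append(d)
    if len(top_districts) != 8:
        logger.info("top-%d facilities span %d districts (not 8); "
                    "column layout adapts", n_top, len(top_districts))
    dist_col = {d: n_top + 1 + i for i, d in enumerate(top_districts)}
    rest_col = n_top + len(top_districts) + 1

    column_of: dict[str, int] = {}
    for rank, f in enumerate(top, start=1):
        column_of[f] = rank
    for f in forecast_totals.index:
        if f in column_of:
            continue
        column_of[f] = dist_col.get(district_of.get(f), rest_col)
    return FacilityCatalog(
        top_facilities=list(top),
        district_of=dict(district_of),
        column_of=column_of,
        n_district_groups=len(top_districts),
    )


# ---------------------------------------------------------------------------
# windows

def extract_windows(
    history: WeeklyHistory,
    window_len: int = WINDOW_LEN,
    horizon: int = HORIZON,
    min_active_weeks: int = MIN_ACTIVE_WEEKS,
) -> list[int]:
    """Start weeks (1-based) of all admissible sliding windows.

    A window starting at week ``w`` is kept iff the ``window_len`` weeks
    from ``w`` contain bookings in at least ``min_active_weeks`` distinct
    weeks and the following ``horizon`` weeks contain at least one booking.
    """
    weekly_totals = np.asarray(history.P_full.sum(axis=1)).ravel()
    T = len(weekly_totals)
    n_starts = T - window_len - horizon + 1
    if n_starts <= 0:
        return []
    active = (weekly_totals > 0).astype(np.int64)
    c_active = np.concatenate([[0], np.cumsum(active)])
    c_total = np.concatenate([[0], np.cumsum(weekly_totals)])
    starts = []
    for w in range(1, n_starts + 1):
        a = c_active[w - 1 + window_len] - c_active[w - 1]
        fut = c_total[w - 1 + window_len + horizon] - c_total[w - 1 + window_len]
        if a >= min_active_weeks and fut >= 1:
            starts.append(w)
    return starts


def collapse_columns(
    P_raw: np.ndarray | sp.spmatrix,
    F_raw: np.ndarray | sp.spmatrix,
    F_tilde_raw: np.ndarray | sp.spmatrix,
    clustering: ProvisionClustering,
    catalog: FacilityCatalog,
    provisions: list[str],
    facilities: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum raw provision columns into clusters and facility columns into
    the catalog's ranked/district/rest columns.  Counts are conserved."""
    unmapped = [p for p in provisions if p not in clustering.assignment]
    if unmapped:
        raise KeyError(f"provision(s) missing from clustering: {unmapped[:3]}")
    unmapped = [f for f in facilities if f not in catalog.column_of]
    if unmapped:
        raise KeyError(f"facility(s) missing from catalog: {unmapped[:3]}")

    Mp = _group_indicator([clustering.assignment[p] - 1 for p in provisions],
                          clustering.k)
    Mf = _group_indicator([catalog.column_of[f] - 1 for f in facilities],
                          catalog.n_columns)
    P = _densify(P_raw @ Mp)
    F = _densify(F_raw @ Mf)
    Ft = _densify(F_tilde_raw @ Mf)
    return P, F, Ft


def _group_indicator(cols: list[int], n_groups: int) -> np.ndarray:
    M = np.zeros((len(cols), n_groups))
    M[np.arange(len(cols)), cols] = 1.0
    return M


def _densify(x) -> np.ndarray:
    return np.asarray(x.todense() if sp.issparse(x) else x, dtype=np.float64)


# ---------------------------------------------------------------------------
# scaling and labeling

def scale_phi(x, config: ScalingConfig = ScalingConfig()) -> np.ndarray:
    """phi(x) = 1 - lambda**(-x), mapping counts into [0, 1).

    Emphasizes differences among small counts: phi(0)=0, phi strictly
    increasing with strictly decreasing increments.
    """
    arr = np.asarray(x, dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("phi is defined on non-negative counts only")
    return 1.0 - config.lam ** (-arr)


def scale_age(age_years, config: ScalingConfig = ScalingConfig()) -> np.ndarray:
    """Min-max age normalization onto [0, 1] with clamping."""
    a = np.clip(np.asarray(age_years, dtype=np.float64),
                config.age_min, config.age_max)
    return (a - config.age_min) / (config.age_max - config.age_min)


def label_window(F_tilde: np.ndarray, n_top: int = N_TOP_FACILITIES) -> np.ndarray:
    """Binary label vector from the forecast count matrix.

    ``y_j = 1`` (j = 1..n_top) iff facility column j has any booking in the
    forecast period; the final label is 1 iff any non-top column does.
    """
    Ft = np.asarray(F_tilde)
    y = np.zeros(n_top + 1, dtype=np.int8)
    y[:n_top] = (Ft[:, :n_top] > 0).any(axis=0)
    y[n_top] = int((Ft[:, n_top:] > 0).any())
    return y


def rebalance_windows(
    y: np.ndarray, keep_fraction: float = 1.0 / 7.0, seed: int = 0
) -> np.ndarray:
    """Indices of the rebalanced window set.

    Windows with any top-facility label are all kept; the remaining
    (last-label-only) windows are down-sampled uniformly at random to
    ``round(count * keep_fraction)``.
    """
    y = np.asarray(y)
    has_top = y[:, :-1].any(axis=1)
    a_idx = np.flatnonzero(has_top)
    b_idx = np.flatnonzero(~has_top)
    rng = np.random.default_rng(seed)
    n_keep = int(round(len(b_idx) * keep_fraction))
    kept_b = rng.choice(b_idx, size=n_keep, replace=False) if n_keep else \
        np.empty(0, dtype=int)
    return np.sort(np.concatenate([a_idx, kept_b]))


# ---------------------------------------------------------------------------
# end-to-end dataset construction

@dataclass
class FeaturizationResult:
    dataset: WindowDataset
    clustering: ProvisionClustering
    catalog: FacilityCatalog
    calendar: WeekCalendar


def build_window_dataset(
    records: pd.DataFrame,
    calendar: WeekCalendar,
    district_of: dict[str, str],
    profiles: pd.DataFrame | None = None,
    k_clusters: int = 8,
    scaling: ScalingConfig = ScalingConfig(),
    seed: int = 0,
    window_len: int = WINDOW_LEN,
    horizon: int = HORIZON,
    min_active_weeks: int = MIN_ACTIVE_WEEKS,
) -> FeaturizationResult:
    """Run the full featurization chain on cleaned records.

    Weekly matrices -> window extraction -> facility ranking on forecast
    totals -> provision clustering -> per-window collapse, scaling and
    labeling.
    """
    from .records import build_profiles

    if profiles is None:
        profiles = build_profiles(records)
    profiles = profiles.set_index("patient_id")

    histories, provisions, facilities = build_weekly_matrices(records, calendar)
    feats = provision_features(records, calendar)
    clustering = cluster_provisions(feats, k=k_clusters, seed=seed)

    window_index: list[tuple[str, int]] = []
    fac_totals = np.zeros(len(facilities))
    for pid, hist in histories.items():
        for w in extract_windows(hist, window_len, horizon, min_active_weeks):
            window_index.append((pid, w))
            lo, hi = w - 1 + window_len, w - 1 + window_len + horizon
            fac_totals += np.asarray(hist.F_full[lo:hi].sum(axis=0)).ravel()
    catalog = rank_facilities(pd.Series(fac_totals, index=facilities), district_of)

    N = len(window_index)
    n_cols = catalog.n_columns
    P = np.zeros((N, window_len, k_clusters), dtype=np.float32)
    F = np.zeros((N, window_len, n_cols), dtype=np.float32)
    Ft = np.zeros((N, horizon, n_cols), dtype=np.int32)
    y = np.zeros((N, N_TOP_FACILITIES + 1), dtype=np.int8)
    gender = np.zeros(N, dtype=np.float32)
    age = np.zeros(N, dtype=np.float32)
    pids = np.empty(N, dtype=object)
    wids = np.zeros(N, dtype=np.int64)

    for i, (pid, w) in enumerate(window_index):
        hist = histories[pid]
        lo = w - 1
        Pc, Fc, Ftc = collapse_columns(
            hist.P_full[lo:lo + window_len],
            hist.F_full[lo:lo + window_len],
            hist.F_full[lo + window_len:lo + window_len + horizon],
            clustering, catalog, provisions, facilities,
        )
        P[i] = scale_phi(Pc, scaling)
        F[i] = scale_phi(Fc, scaling)
        Ft[i] = Ftc
        y[i] = label_window(Ftc)
        prof = profiles.loc[pid]
        gender[i] = float(prof["gender"])
        start_year = (calendar.period_start + pd.Timedelta(days=7 * (w - 1))).year
        age[i] = scale_age(start_year - prof["birth_year"], scaling)
        pids[i] = pid
        wids[i] = w

    dataset = WindowDataset(
        patient_id=pids.astype(str), window_id=wids, gender=gender, age=age,
        P=P, F=F, F_tilde=Ft, y=y,
    )
    return FeaturizationResult(dataset, clustering, catalog, calendar)
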