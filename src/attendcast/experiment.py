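"""End-to-end experiment orchestration: rebalance, split, train, calibrate,
evaluate — repeated over seeded runs with mean ± sd aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .features import WindowDataset, rebalance_windows
from .metrics import MetricsReport, evaluate_predictions
from .model import (MLPBaseline, NetworkConfig, RFBaseline, TCNNModel,
                    calibrate_thresholds, fit_baseline, flatten_inputs,
                    train_model)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a repeated-runs experiment.

    Split fractions follow the method: networks use
    train/validation/test = 0.72/0.18/0.10 (the validation part drives
    early stopping and threshold calibration); the random forest, which
    needs no validation set, uses 0.90/0.10.
    """

    method: str = "tcnn"  # "tcnn" | "rf" | "mlp"
    nn_split: tuple[float, float, float] = (0.72, 0.18, 0.10)
    rf_split: tuple[float, float] = (0.90, 0.10)
    keep_fraction: float = 1.0 / 7.0
    n_runs: int = 15
    base_seed: int = 0
    split_by_patient: bool = False
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        for fr in (self.nn_split, self.rf_split):
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"split fractions must sum to 1, got {fr}")


def split_indices(n: int, fractions: tuple[float, ...],
                  seed: int,
                  patient_ids: np.ndarray | None = None) -> list[np.ndarray]:
    """Shuffle and partition ``n`` windows into disjoint, exhaustive parts.

    With ``patient_ids`` given, whole patients are assigned to parts
    (avoiding cross-split leakage of one patient's overlapping windows);
    otherwise the split is at the window level.
    """
    rng = np.random.default_rng(seed)
    if patient_ids is None:
        perm = rng.permutation(n)
        bounds = np.cumsum([int(round(f * n)) for f in fractions[:-1]])
        return [np.sort(p) for p in np.split(perm, bounds)]
    patients = rng.permutation(np.unique(patient_ids))
    bounds = np.cumsum([int(round(f * len(patients)))
                        for f in fractions[:-1]])
    parts = np.split(patients, bounds)
    return [np.sort(np.flatnonzero(np.isin(patient_ids, part)))
            for part in parts]


def _as_batch(ds: WindowDataset) -> dict[str, np.ndarray]:
    return {"P": ds.P, "F": ds.F, "gender": ds.gender, "age": ds.age,
            "y": ds.y}


def run_once(dataset: WindowDataset, config: RunConfig,
             seed: int) -> MetricsReport:
    """One randomized run: rebalance, split, fit, calibrate, evaluate."""
    keep = rebalance_windows(dataset.y, config.keep_fraction, seed)
    ds = dataset.subset(keep)
    # input shapes follow the dataset (the facility layout adapts to the
    # number of districts the top facilities span)
    net = replace(config.network, seed=seed,
                  t=ds.P.shape[1],
                  n_provision_cols=ds.P.shape[2],
                  n_facility_cols=ds.F.shape[2],
                  n_labels=ds.y.shape[1])
    pids = ds.patient_id if config.split_by_patient else None

    if config.method == "rf":
        tr, te = split_indices(len(ds), config.rf_split, seed, pids)
        train, test = ds.subset(tr), ds.subset(te)
        Xtr = flatten_inputs(train.P, train.F, train.gender, train.age)
        Xte = flatten_inputs(test.P, test.F, test.gender, test.age)
        rf = fit_baseline("rf", Xtr, train.y, net)
        scores = rf.predict_scores(Xte)
        y_hat = rf.predict(Xte)
    else:
        tr, va, te = split_indices(len(ds), config.nn_split, seed, pids)
        train, val, test = ds.subset(tr), ds.subset(va), ds.subset(te)
        if config.method == "mlp":
            Xtr = flatten_inputs(train.P, train.F, train.gender, train.age)
            Xva = flatten_inputs(val.P, val.F, val.gender, val.age)
            Xte = flatten_inputs(test.P, test.F, test.gender, test.age)
            mlp = fit_baseline("mlp", Xtr, train.y, net, Xva, val.y)
            scores = mlp.predict_scores(Xte)
            y_hat = (scores > mlp.thresholds).astype(np.int8)
        elif config.method == "tcnn":
            model = TCNNModel(net)
            train_model(model, _as_batch(train), _as_batch(val), net)
            model.thresholds = calibrate_thresholds(
                model.predict_scores(val.P, val.F, val.gender, val.age),
                val.y)
            scores = model.predict_scores(test.P, test.F,
                                          test.gender, test.age)
            y_hat = (scores > model.thresholds).astype(np.int8)
        else:
            raise ValueError(f"unknown method {config.method!r}")

    return evaluate_predictions(test.y, y_hat, scores, F_windows=test.F)


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, dict]:
    """Mean ± sd of the scalar metrics across completed runs."""
    scalars: dict[str, list[float]] = {}
    for r in reports:
        vals = {"mean_hamming": r.mean_hamming,
                "exact_accuracy": r.exact_accuracy,
                "top10_exact_accuracy": r.top10_exact_accuracy,
                **r.overall}
        for k, v in vals.items():
            scalars.setdefault(k, []).append(v)
    out = {}
    for k, vs in scalars.items():
        arr = np.asarray(vs, dtype=float)
        out[k] = {"mean": float(np.nanmean(arr)),
                  "sd": float(np.nanstd(arr, ddof=1)) if len(arr) > 1 else None}
    return out


def run_experiment(dataset: WindowDataset,
                   config: RunConfig) -> tuple[list[MetricsReport], dict]:
    """Repeat :func:`run_once` ``n_runs`` times with seeds base+1..base+n.

    A failed run is logged and skipped; remaining runs continue.  The
    aggregate reports mean and (with >= 2 runs) standard deviation per
    scalar metric.
    """
    reports: list[MetricsReport] = []
    for r in range(1, config.n_runs + 1):
        seed = config.base_seed + r
        try:
            reports.append(run_once(dataset, config, seed))
            logger.info("run %d/%d done (seed %d)", r, config.n_runs, seed)
        except Exception:
            logger.exception("run %d (seed %d) failed; continuing", r, seed)
    return reports, aggregate_reports(reports)
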