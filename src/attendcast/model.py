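"""Structured temporal CNN for multi-label facility-attendance prediction,
plus the random-forest and flat MLP baselines.

The network consumes, per window, two scaled temporal matrices — ``P``
(52 weeks x 8 provision clusters) and ``F`` (52 weeks x 19 facility
columns) — plus gender and age.  Each matrix passes through two parallel
temporal blocks (one max-pooled, one average-pooled); a block applies, for
every kernel size ``s`` in ``S``, 64 filters spanning ``s`` weeks and all
columns, pools to 26 time steps, sums the filter outputs and concatenates
across kernel sizes.  The four block outputs plus gender and age feed a
dense head (128 -> 32 -> 11 tanh units).  Training minimizes the BP-MLL
pairwise ranking loss with Adam and early stopping on validation loss;
per-label decision thresholds are calibrated afterwards to minimize
FP + FN on the validation set.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .nn import Adam, ConvSumPool, Dense, bpmll_loss_grad

logger = logging.getLogger(__name__)

DEFAULT_KERNEL_SIZES = tuple(range(6, 52, 3))  # {6, 9, ..., 51}, n_S = 16


@dataclass(frozen=True)
class TCNNBlockSpec:
    """Shape parameters of one temporal convolution block."""

    t: int = 52
    d: int = 19
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    n_filters: int = 64
    pool: str = "max"  # "max" | "avg"

    def __post_init__(self):
        if self.t % 2:
            raise ValueError("t must be even (pooling halves it exactly)")
        for s in self.kernel_sizes:
            if not 1 <= s <= self.t:
                raise ValueError(f"kernel size {s} outside [1, {self.t}]")

    @property
    def output_len(self) -> int:
        return len(self.kernel_sizes) * (self.t // 2)


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the structured TCNN (and the flat MLP head)."""

    t: int = 52
    n_provision_cols: int = 8
    n_facility_cols: int = 19
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    n_filters: int = 64
    hidden_sizes: tuple[int, int] = (128, 32)
    n_labels: int = 11
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 5
    seed: int = 0

    @property
    def block_output_len(self) -> int:
        return len(self.kernel_sizes) * (self.t // 2)

    @property
    def dense_input_len(self) -> int:
        # four blocks (P max/avg, F max/avg) plus gender and age
        return 4 * self.block_output_len + 2

    @property
    def flat_input_len(self) -> int:
        return self.t * (self.n_provision_cols + self.n_facility_cols) + 2


class TCNNBlock:
    """Multi-kernel-size temporal block: conv -> pool -> filter sum,
    concatenated across kernel sizes."""

    def __init__(self, spec: TCNNBlockSpec, rng: np.random.Generator):
        self.spec = spec
        self.branches = [
            ConvSumPool(s, spec.d, spec.n_filters, spec.pool, rng)
            for s in spec.kernel_sizes
        ]
        self.params = [p for br in self.branches for p in br.params]
        self.grads = [g for br in self.branches for g in br.grads]

    def forward(self, X: np.ndarray) -> np.ndarray:
        return np.concatenate([br.forward(X) for br in self.branches], axis=1)

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        half = self.spec.t // 2
        dX = None
        for i, br in enumerate(self.branches):
            g = br.backward(g_out[:, i * half:(i + 1) * half])
            dX = g if dX is None else dX + g
        return dX


def tcnn_block_forward(X: np.ndarray, spec: TCNNBlockSpec,
                       rng: np.random.Generator | None = None,
                       block: TCNNBlock | None = None) -> np.ndarray:
    """Functional forward pass of one block (fresh weights unless given)."""
    if block is None:
        block = TCNNBlock(spec, rng or np.random.default_rng(0))
    X = np.atleast_3d(X)
    if X.ndim == 3 and X.shape[1:] != (spec.t, spec.d):
        raise ValueError(f"expected input shape (N, {spec.t}, {spec.d}), "
                         f"got {X.shape}")
    return block.forward(X)


class TCNNModel:
    """The full four-block structured TCNN with a dense head."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        mk = lambda d, pool: TCNNBlock(
            TCNNBlockSpec(t=config.t, d=d, kernel_sizes=config.kernel_sizes,
                          n_filters=config.n_filters, pool=pool), rng)
        self.blocks = [mk(config.n_provision_cols, "max"),
                       mk(config.n_provision_cols, "avg"),
                       mk(config.n_facility_cols, "max"),
                       mk(config.n_facility_cols, "avg")]
        h1, h2 = config.hidden_sizes
        self.head = [Dense(config.dense_input_len, h1, rng),
                     Dense(h1, h2, rng),
                     Dense(h2, config.n_labels, rng)]
        self.params = ([p for b in self.blocks for p in b.params]
                       + [p for l in self.head for p in l.params])
        self.grads = ([g for b in self.blocks for g in b.grads]
                      + [g for l in self.head for g in l.grads])
        self.thresholds: np.ndarray | None = None

    def forward(self, P: np.ndarray, F: np.ndarray, gender: np.ndarray,
                age: np.ndarray) -> np.ndarray:
        for name, arr in (("P", P), ("F", F)):
            if arr.min() < 0.0 or arr.max() > 1.0:
                logger.warning("%s input holds values outside [0, 1]; "
                               "expected phi-scaled counts", name)
        parts = [self.blocks[0].forward(P), self.blocks[1].forward(P),
                 self.blocks[2].forward(F), self.blocks[3].forward(F),
                 gender[:, None], age[:, None]]
        v = np.concatenate(parts, axis=1).astype(np.float32)
        self._split = np.cumsum([p.shape[1] for p in parts])[:-1]
        h = v
        for layer in self.head:
            h = layer.forward(h)
        return h

    def backward(self, dC: np.ndarray) -> None:
        g = dC.astype(np.float32)
        for layer in reversed(self.head):
            g = layer.backward(g)
        gP1, gP2, gF1, gF2, _, _ = np.split(g, self._split, axis=1)
        self.blocks[0].backward(gP1)
        self.blocks[1].backward(gP2)
        self.blocks[2].backward(gF1)
        self.blocks[3].backward(gF2)

    def predict_scores(self, P, F, gender, age,
                       batch_size: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, len(P), batch_size):
            sl = slice(lo, lo + batch_size)
            out.append(self.forward(P[sl], F[sl], gender[sl], age[sl]))
        return np.concatenate(out, axis=0)

    def predict(self, P, F, gender, age) -> np.ndarray:
        if self.thresholds is None:
            raise RuntimeError("thresholds not calibrated; call "
                               "calibrate_thresholds first")
        return (self.predict_scores(P, F, gender, age)
                > self.thresholds).astype(np.int8)

    # -- persistence ------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config,
                         "weights": self.get_weights(),
                         "thresholds": self.thresholds}, fh)

    @classmethod
    def load(cls, path) -> "TCNNModel":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(state["config"])
        model.set_weights(state["weights"])
        model.thresholds = state["thresholds"]
        return model


@dataclass
class TrainingLog:
    """Per-epoch train/validation losses and the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    n_excluded_all_ones: int = 0


def train_model(model, train_data: dict, val_data: dict,
                config: NetworkConfig) -> TrainingLog:
    """Minimize the mean BP-MLL loss with Adam and early stopping.

    ``train_data``/``val_data`` map ``{"P", "F", "gender", "age", "y"}`` to
    arrays (the MLP baseline instead uses ``{"X", "y"}``).  Stops when the
    validation loss has not improved for ``config.patience`` consecutive
    epochs and restores the best-validation weights.
    """
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params, lr=config.learning_rate)
    log = TrainingLog()
    n = len(train_data["y"])
    best_val, best_weights, since_best = np.inf, None, 0

    def fwd(data, sl):
        if "X" in data:
            return model.forward(data["X"][sl])
        return model.forward(data["P"][sl], data["F"][sl],
                             data["gender"][sl], data["age"][sl])

    def eval_loss(data):
        total, count = 0.0, 0
        for lo in range(0, len(data["y"]), 512):
            sl = slice(lo, lo + 512)
            c = fwd(data, sl)
            loss, _, _ = bpmll_loss_grad(c, data["y"][sl])
            m = len(data["y"][sl])
            total += loss * m
            count += m
        return total / max(count, 1)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_batches = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            c = fwd(train_data, idx)
            loss, dC, n_exc = bpmll_loss_grad(c, train_data["y"][idx])
            log.n_excluded_all_ones += n_exc
            model.backward(dC)
            opt.step(model.grads)
            ep_loss += loss
            ep_batches += 1
        if not np.isfinite(ep_loss):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {epoch}")
        log.train_loss.append(ep_loss / max(ep_batches, 1))
        vl = eval_loss(val_data)
        log.val_loss.append(vl)
        if vl < best_val - 1e-12:
            best_val, best_weights, since_best = vl, model.get_weights(), 0
            log.best_epoch = epoch
        else:
            since_best += 1
            if since_best > config.patience:
                break
    if best_weights is not None:
        model.set_weights(best_weights)
    return log


def calibrate_thresholds(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-label thresholds minimizing FP + FN on a validation set.

    Candidates are the midpoints between consecutive sorted unique scores
    plus below-min/above-max sentinels; ties resolve to the smallest
    candidate.  Prediction rule: positive iff score > threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty validation set")
    n_labels = scores.shape[1]
    theta = np.zeros(n_labels)
    for j in range(n_labels):
        s, y = scores[:, j], labels[:, j]
        uniq = np.unique(s)
        lo_sent, hi_sent = uniq[0] - 1.0, uniq[-1] + 1.0
        if y.all():
            theta[j] = lo_sent
            logger.info("label %d all-positive in validation; "
                        "threshold below min", j)
            continue
        if not y.any():
            theta[j] = hi_sent
            logger.info("label %d all-negative in validation; "
                        "threshold above max", j)
            continue
        candidates = np.concatenate(
            [[lo_sent], (uniq[:-1] + uniq[1:]) / 2.0, [hi_sent]])
        best_cost, best_theta = np.inf, candidates[0]
        for th in candidates:
            yhat = s > th
            cost = int((yhat & (y == 0)).sum() + (~yhat & (y == 1)).sum())
            if cost < best_cost:
                best_cost, best_theta = cost, th
        theta[j] = best_theta
    return theta


# ---------------------------------------------------------------------------
# baselines on flattened inputs

def flatten_inputs(P, F, gender, age) -> np.ndarray:
    """Concatenate flattened temporal matrices with gender and age:
    52*8 + 52*19 + 2 = 1406 columns at the default shapes."""
    n = len(gender)
    return np.concatenate(
        [P.reshape(n, -1), F.reshape(n, -1),
         gender[:, None], age[:, None]], axis=1)


class MLPBaseline:
    """Dense network on the flattened window vector, trained with BP-MLL
    and the same threshold calibration as the TCNN."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h1, h2 = config.hidden_sizes
        self.layers = [Dense(config.flat_input_len, h1, rng),
                       Dense(h1, h2, rng),
                       Dense(h2, config.n_labels, rng)]
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]
        self.thresholds: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = X.astype(np.float32)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, dC: np.ndarray) -> None:
        g = dC.astype(np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_scores(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        return np.concatenate([self.forward(X[lo:lo + batch_size])
                               for lo in range(0, len(X), batch_size)])

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w


class RFBaseline:
    """Single multi-output random forest on the flattened window vector."""

    def __init__(self, n_estimators: int = 100, seed: int = 0, **kwargs):
        self.forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, **kwargs)
        self._constant_cols: dict[int, int] = {}

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RFBaseline":
        self.forest.fit(X, Y)
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-label positive-class probabilities."""
        proba = self.forest.predict_proba(X)
        n_labels = len(self.forest.classes_)
        out = np.zeros((len(X), n_labels))
        for j, (pj, classes) in enumerate(zip(proba, self.forest.classes_)):
            if pj.shape[1] == 2:
                out[:, j] = pj[:, 1]
            else:  # label constant in training
                out[:, j] = float(classes[0])
        return out

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_scores(X) > threshold).astype(np.int8)


def fit_baseline(kind: str, X: np.ndarray, Y: np.ndarray,
                 config: NetworkConfig,
                 X_val: np.ndarray | None = None,
                 Y_val: np.ndarray | None = None):
    """Train a baseline of the given kind ("rf" | "mlp") on flattened
    inputs; the MLP additionally needs a validation split for early
    stopping and threshold calibration."""
    kind = kind.lower()
    if kind == "rf":
        return RFBaseline(seed=config.seed).fit(X, Y)
    if kind == "mlp":
        if X_val is None or Y_val is None:
            raise ValueError("MLP baseline requires a validation split")
        mlp = MLPBaseline(config)
        train_model(mlp, {"X": X, "y": Y}, {"X": X_val, "y": Y_val}, config)
        mlp.thresholds = calibrate_thresholds(mlp.predict_scores(X_val), Y_val)
        return mlp
    raise ValueError(f"unknown baseline kind {kind!r}; expected 'rf' or 'mlp'")
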