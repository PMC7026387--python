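"""Training protocol: -R^2 loss, data splits, k-fold CV, seeded fitting.

The regression objective is the negative coefficient of determination
computed per mini-batch,

    loss = -(1 - SSE/SStot) = SSE/SStot - 1,

whose gradient equals the squared-error gradient rescaled by the batch
target variance; minimizing it therefore minimizes squared error for a
fixed batch composition.  A zero-variance batch falls back to plain mean
squared error with a logged notice rather than producing NaN.

Evaluation follows two protocols: a single 90/10 train/test split, and
10-fold cross-validation in which the data are shuffled once (seeded) into
near-equal folds and each fold serves once as the held-out test set.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .architectures import DNNSpec, ResNetSpec, build_model
from .fingerprints import FeatureMatrix
from .metrics import EvaluationReport, evaluate, r_squared, rmse
from .nn.network import Network
from .nn.optim import SGD, Adam

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "CVResult",
    "neg_r2_loss",
    "split_train_test",
    "make_folds",
    "fit_network",
    "train_model",
    "cross_validate",
    "grid_search",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for one training run."""

    optimizer: str = "adam"          # 'adam' | 'sgd'
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 20
    l2_lambda: float | None = None   # None -> take the architecture spec's value
    seed: int = 0
    loss: str = "neg_r2"             # 'neg_r2' | 'mse'
    validation_fraction: float = 0.1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 2 and self.loss == "neg_r2":
            raise ValueError("batch_size must be >= 2 for the -R^2 loss (batch variance)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.loss not in ("neg_r2", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


def neg_r2_loss(predicted, observed) -> float:
    """Batch loss -(1 - SSE/SStot); falls back to SSE/n at zero variance."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be 1-D vectors of equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sse = float(np.sum((y - p) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("zero batch variance: -R^2 undefined, falling back to SSE/n")
        return sse / y.size
    return sse / ss_tot - 1.0


def _loss_and_grad(pred: np.ndarray, y: np.ndarray, kind: str) -> tuple[float, np.ndarray]:
    resid = pred - y
    if kind == "neg_r2":
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            logger.warning("zero batch variance: -R^2 undefined, using SSE/n for this batch")
            n = y.size
            return float(np.sum(resid**2)) / n, 2.0 * resid / n
        return float(np.sum(resid**2)) / ss_tot - 1.0, 2.0 * resid / ss_tot
    n = y.size
    return float(np.sum(resid**2)) / n, 2.0 * resid / n


def split_train_test(n: int, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint covering split; |test| = round(n * test_fraction)."""
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(math.floor(n * test_fraction + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of 0..n-1 into k near-equal folds."""

    n: int
    k: int
    fold_of: np.ndarray
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    @property
    def fold_sizes(self) -> list[int]:
        return [int(np.sum(self.fold_of == f)) for f in range(self.k)]


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Shuffle indices once (seeded) and deal them into k folds whose sizes
    differ by at most one: the first n mod k folds get the extra record."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} records")
    perm = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, k)
    fold_of = np.empty(n, dtype=np.int64)
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        fold_of[perm[start : start + size]] = f
        start += size
    return FoldAssignment(n=n, k=k, fold_of=fold_of, seed=seed)


def fit_network(net: Network, X, y, config: TrainConfig) -> list[dict]:
    """Mini-batch training with early stopping; returns the epoch history.

    An inner validation slice (``validation_fraction`` of the training rows,
    seeded) is monitored by R^2; the best-validation weights are restored at
    the end.  All randomness (validation split, batch shuffling, dropout)
    descends from ``config.seed``.
    """
    X = np.asarray(X, dtype=net.dtype)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError("X and y must be non-empty and aligned")
    history: list[dict] = []
    if config.max_epochs == 0:
        return history

    rng = np.random.default_rng(config.seed)
    # reseed dropout layers from the training seed for reproducibility
    for layer in net.iter_layers():
        if hasattr(layer, "rng") and hasattr(layer, "rate"):
            layer.rng = np.random.default_rng(rng.integers(2**31))

    n = X.shape[0]
    n_val = int(round(n * config.validation_fraction))
    use_val = n_val >= 2
    if use_val:
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if np.var(y[val_idx]) == 0:
            use_val = False
            tr_idx = np.arange(n)
    else:
        tr_idx = np.arange(n)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    n_tr = Xtr.shape[0]

    # calibrate the output affine to the training targets so the head does
    # not have to crawl to the target location one optimizer step at a time
    sd = float(ytr.std())
    net.output_loc = float(ytr.mean())
    net.output_scale = sd if sd > 0 else 1.0

    l2 = config.l2_lambda
    if l2 is None:
        l2 = getattr(net.spec, "l2_lambda", 0.0)
    opt_cls = {"adam": Adam, "sgd": SGD}[config.optimizer]
    opt = opt_cls(lr=config.learning_rate, weight_decay=l2)
    layers = list(net.iter_layers())

    best_metric = -np.inf
    best_state = None
    patience_left = config.early_stop_patience

    for epoch in range(config.max_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n_tr)
        losses = []
        for start in range(0, n_tr, config.batch_size):
            bidx = order[start : start + config.batch_size]
            if bidx.size < 2 and config.loss == "neg_r2":
                continue  # a singleton batch has no variance
            pred = net.forward(Xtr[bidx], training=True)
            loss, dpred = _loss_and_grad(pred.astype(float), ytr[bidx], config.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: loss={loss!r}, "
                    f"lr={config.learning_rate}, batch={bidx.size}; "
                    "reduce the learning rate or initialization scale"
                )
            net.backward(dpred)
            opt.step(layers)
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "seconds": time.perf_counter() - t0}
        if use_val:
            val_pred = net.forward(X[val_idx], training=False).astype(float)
            entry["val_r2"] = r_squared(y[val_idx], val_pred)
            entry["val_rmse"] = rmse(y[val_idx], val_pred)
            metric = entry["val_r2"]
        else:
            metric = -entry["train_loss"]
        history.append(entry)
        logger.debug("epoch %d: %s", epoch, entry)
        if metric > best_metric:
            best_metric = metric
            best_state = net.get_state()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if config.early_stop_patience > 0 and patience_left <= 0:
                break
    if best_state is not None:
        net.set_state(best_state)
    return history


def train_model(arch: ResNetSpec | DNNSpec, data: FeatureMatrix,
                config: TrainConfig) -> tuple[Network, list[dict]]:
    """Build an architecture and fit it on a feature matrix."""
    if data.n == 0:
        raise ValueError("empty feature matrix")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    net = build_model(arch, input_length=data.X.shape[1], rng=rng)
    history = fit_network(net, data.X, data.y, config)
    return net, history


@dataclass
class CVResult:
    """Per-fold held-out reports plus min-max ranges, mirroring how k-fold
    performance is conventionally reported (e.g. R^2 = 0.74-0.79)."""

    per_fold: list[EvaluationReport | None]
    folds: FoldAssignment
    arch: ResNetSpec | DNNSpec
    config: TrainConfig
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def _ok(self) -> list[EvaluationReport]:
        return [r for r in self.per_fold if r is not None]

    @property
    def range_r2(self) -> tuple[float, float]:
        vals = [r.r2 for r in self._ok]
        return (min(vals), max(vals))

    @property
    def range_rmse(self) -> tuple[float, float]:
        vals = [r.rmse for r in self._ok]
        return (min(vals), max(vals))

    def to_dict(self) -> dict:
        return {
            "k": self.folds.k,
            "per_fold": [r.to_dict() if r is not None else None for r in self.per_fold],
            "range_r2": list(self.range_r2) if self._ok else None,
            "range_rmse": list(self.range_rmse) if self._ok else None,
            "failures": self.failures,
        }


def cross_validate(arch: ResNetSpec | DNNSpec, data: FeatureMatrix, k: int,
                   config: TrainConfig) -> CVResult:
    """k-fold cross-validation with independently initialized trainings.

    Rows are first sorted by compound id, so the result is invariant to the
    input row order.  A failing fold is recorded and the remaining folds
    still run.
    """
    order = np.argsort(data.compound_ids.astype(str), kind="stable")
    data = data.subset(order)
    folds = make_folds(data.n, k, config.seed)
    reports: list[EvaluationReport | None] = []
    failures: dict[int, str] = {}
    for f in range(k):
        test_idx = folds.fold_indices(f)
        train_idx = np.flatnonzero(folds.fold_of != f)
        fold_seed = int(np.random.SeedSequence([config.seed, 11, f]).generate_state(1)[0] % (2**31))
        fold_config = replace(config, seed=fold_seed)
        try:
            net, _ = train_model(arch, data.subset(train_idx), fold_config)
            test = data.subset(test_idx)
            y_hat = net.forward(test.X, training=False).astype(float)
            reports.append(evaluate(test.y, y_hat, molecular_weight=test.molecular_weight))
        except Exception as exc:  # keep remaining folds alive
            logger.error("fold %d failed: %s", f, exc)
            reports.append(None)
            failures[f] = str(exc)
    return CVResult(per_fold=reports, folds=folds, arch=arch, config=config, failures=failures)


def grid_search(arch_grid, data: FeatureMatrix, k: int, base_config: TrainConfig,
                config_overrides: list[dict] | None = None):
    """Exhaustive driver over architecture specs x config overrides.

    Returns (arch, config, CVResult) triples sorted by mean held-out R^2,
    best first.  This is a transparent loop, not an automated tuner.
    """
    overrides = config_overrides or [{}]
    results = []
    for arch in arch_grid:
        for ov in overrides:
            cfg = replace(base_config, **ov)
            cv = cross_validate(arch, data, k, cfg)
            ok = [r.r2 for r in cv.per_fold if r is not None]
            mean_r2 = float(np.mean(ok)) if ok else -np.inf
            results.append((arch, cfg, cv, mean_r2))
    results.sort(key=lambda t: t[3], reverse=True)
    return [(a, c, cv) for a, c, cv, _ in results]
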