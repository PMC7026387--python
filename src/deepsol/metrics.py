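"""Regression and classification metrics for solubility prediction.

The two headline regression metrics are the coefficient of determination

    R^2 = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2

(unbounded below; a constant-mean predictor scores exactly 0) and the root
mean squared error, both computed on logS values.  Two coarser, chemistry-
facing metrics accompany them: the percentage of compounds predicted within
a factor of ten of the experimental solubility (one log10 unit in logS) and
a four-way solubility-category classification accuracy on the pharmacopoeia
bins practically-insoluble (<0.1 g/L), slightly soluble [0.1, 10) g/L,
soluble [10, 100) g/L and freely soluble (>=100 g/L).

Uncertainty on any metric is quantified by a seeded nonparametric bootstrap
over (y, yhat) pairs with percentile confidence intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "r_squared",
    "rmse",
    "pct_within_10fold",
    "SolubilityCategory",
    "classify_category",
    "category_accuracy",
    "bootstrap_metrics",
    "BootstrapSummary",
    "EvaluationReport",
    "evaluate",
]


class SolubilityCategory(enum.Enum):
    """Coarse solubility bins defined on solubility in g/L.

    The four intervals partition (0, inf); lower bounds are inclusive so a
    compound at exactly 0.1 g/L is *slightly_soluble*.
    """

    PRACTICALLY_INSOLUBLE = "practically_insoluble"  # < 0.1 g/L
    SLIGHTLY_SOLUBLE = "slightly_soluble"            # [0.1, 10)
    SOLUBLE = "soluble"                              # [10, 100)
    FREELY_SOLUBLE = "freely_soluble"                # >= 100


_CATEGORY_EDGES_G_PER_L = (0.1, 10.0, 100.0)


def _as_1d(name: str, v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    if a.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _paired(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    ya = _as_1d("y", y)
    pa = _as_1d("y_hat", y_hat)
    if ya.shape != pa.shape:
        raise ValueError(f"length mismatch: y has {ya.size}, y_hat has {pa.size}")
    return ya, pa


def r_squared(y, y_hat) -> float:
    """Coefficient of determination 1 - SSE/SStot.

    Raises ``ValueError`` when ``y`` has zero variance (the denominator is
    undefined) or fewer than two elements.
    """
    ya, pa = _paired(y, y_hat)
    if ya.size < 2:
        raise ValueError("r_squared needs at least 2 observations")
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined: observed values are all equal")
    ss_err = float(np.sum((ya - pa) ** 2))
    return 1.0 - ss_err / ss_tot


def rmse(y, y_hat) -> float:
    """Root mean squared error sqrt(mean((y - y_hat)^2))."""
    ya, pa = _paired(y, y_hat)
    return float(np.sqrt(np.mean((ya - pa) ** 2)))


def pct_within_10fold(y, y_hat) -> float:
    """Percentage of predictions within 10-fold of the experimental value.

    A 10-fold ratio in linear solubility is exactly one log10 unit, so the
    rule is |yhat_i - y_i| <= 1 (boundary inclusive), reported on a 0-100
    scale.
    """
    ya, pa = _paired(y, y_hat)
    return float(100.0 * np.mean(np.abs(pa - ya) <= 1.0))


def solubility_g_per_l(log_s, molecular_weight) -> np.ndarray:
    """Convert logS (log10 mol/L) to solubility in g/L given MW in g/mol."""
    ls = np.asarray(log_s, dtype=float)
    mw = np.asarray(molecular_weight, dtype=float)
    if np.any(mw <= 0):
        raise ValueError("molecular weight must be positive")
    return (10.0 ** ls) * mw


def classify_category(log_s: float, molecular_weight: float) -> SolubilityCategory:
    """Bin one compound into a solubility category.

    logS (mol/L) is converted to g/L via the molecular weight, then binned.
    """
    g_per_l = float(solubility_g_per_l(log_s, molecular_weight))
    if not np.isfinite(g_per_l):
        raise ValueError("logS conversion produced a non-finite solubility")
    idx = int(np.searchsorted(_CATEGORY_EDGES_G_PER_L, g_per_l, side="right"))
    return list(SolubilityCategory)[idx]


def category_accuracy(y, y_hat, molecular_weight) -> float:
    """Percentage of compounds whose predicted and experimental categories agree."""
    ya, pa = _paired(y, y_hat)
    mw = _as_1d("molecular_weight", molecular_weight)
    if mw.shape != ya.shape:
        raise ValueError("molecular_weight length mismatch")
    true_bin = np.searchsorted(_CATEGORY_EDGES_G_PER_L, solubility_g_per_l(ya, mw), side="right")
    pred_bin = np.searchsorted(_CATEGORY_EDGES_G_PER_L, solubility_g_per_l(pa, mw), side="right")
    return float(100.0 * np.mean(true_bin == pred_bin))


@dataclass(frozen=True)
class BootstrapSummary:
    """Bootstrap distribution summary of one metric."""

    metric_name: str
    b: int
    mean: float
    sd: float
    ci95: tuple[float, float]
    seed: int
    n_degenerate: int = 0  # resamples skipped for zero y-variance


def bootstrap_metrics(
    y,
    y_hat,
    b: int = 10_000,
    seed: int = 0,
) -> dict[str, BootstrapSummary]:
    """Bootstrap R^2 and RMSE over paired resamples with replacement.

    ``b`` index vectors of length n are drawn with a seeded generator;
    resamples whose observed values are all identical (zero variance, R^2
    undefined) are skipped for R^2 and counted in ``n_degenerate``.
    Returns percentile 95% confidence intervals.
    """
    ya, pa = _paired(y, y_hat)
    n = ya.size
    if n < 2:
        raise ValueError("bootstrap needs at least 2 observations")
    if b < 1:
        raise ValueError("b must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b, n))
    ys = ya[idx]          # (b, n)
    ps = pa[idx]
    resid2 = (ys - ps) ** 2
    rmse_b = np.sqrt(resid2.mean(axis=1))
    ss_tot = ((ys - ys.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ok = ss_tot > 0
    if not np.any(ok):
        raise ValueError("all bootstrap resamples have zero variance in y")
    r2_b = 1.0 - resid2.sum(axis=1)[ok] / ss_tot[ok]

    def summarize(name: str, vals: np.ndarray, degen: int) -> BootstrapSummary:
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return BootstrapSummary(
            metric_name=name,
            b=b,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=0)),
            ci95=(float(lo), float(hi)),
            seed=seed,
            n_degenerate=degen,
        )

    n_degen = int(b - ok.sum())
    return {
        "r2": summarize("r2", r2_b, n_degen),
        "rmse": summarize("rmse", rmse_b, 0),
    }


@dataclass
class EvaluationReport:
    """Paired predictions plus every headline metric.

    ``category_accuracy`` is only populated when molecular weights are
    available (the g/L category bins need them).
    """

    y: np.ndarray
    y_hat: np.ndarray
    n: int
    r2: float
    rmse: float
    pct_within_10fold: float
    category_accuracy: float | None = None
    bootstrap: dict[str, BootstrapSummary] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "pct_within_10fold": self.pct_within_10fold,
        }
        if self.category_accuracy is not None:
            out["category_accuracy"] = self.category_accuracy
        for name, s in self.bootstrap.items():
            out[f"bootstrap_{name}"] = {
                "b": s.b, "mean": s.mean, "sd": s.sd,
                "ci95_low": s.ci95[0], "ci95_high": s.ci95[1],
            }
        return out

    def format_r2(self, floor: float = 0.2) -> str:
        """Display convention for weak fits: values below ``floor`` print
        as '<floor'; the raw value is always retained in ``r2``."""
        return f"<{floor}" if self.r2 < floor else f"{self.r2:.3f}"


def evaluate(
    y,
    y_hat,
    molecular_weight=None,
    bootstrap_b: int = 0,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble a full evaluation report for one prediction set."""
    ya, pa = _paired(y, y_hat)
    cat = None
    if molecular_weight is not None:
        cat = category_accuracy(ya, pa, molecular_weight)
    boot = bootstrap_metrics(ya, pa, b=bootstrap_b, seed=seed) if bootstrap_b else {}
    return EvaluationReport(
        y=ya,
        y_hat=pa,
        n=int(ya.size),
        r2=r_squared(ya, pa),
        rmse=rmse(ya, pa),
        pct_within_10fold=pct_within_10fold(ya, pa),
        category_accuracy=cat,
        bootstrap=boot,
    )
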