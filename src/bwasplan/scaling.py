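"""Accuracy scaling laws for brain-wide association studies.

Individual-level phenotype prediction accuracy in BWAS depends jointly on the
training sample size ``N`` and the fMRI scan time per participant ``T``.  Two
models capture this dependence:

* the **theoretical model**  ``rho(N, T) = K0 * sqrt(1 / (1 + K1/N + K2/(N*T)))``,
  where ``K0`` is the asymptotic (infinite-data) accuracy, ``K1`` captures the
  sample-size-limited error of the regression coefficients, and ``K2`` captures
  prediction error caused by functional-connectivity measurement noise, whose
  variance shrinks like ``1/T``;
* the **logarithmic model** ``y = z * log2(N*T) + k``, valid for short scans
  (conventionally ``T <= 20`` minutes), where accuracy depends on ``N`` and
  ``T`` only through the total scan duration ``N*T``.

This module evaluates and fits both models, normalizes accuracies onto a
common log2(total-duration) scale, and compares goodness of fit across
phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

__all__ = [
    "AccuracyGrid",
    "TheoreticalParams",
    "LogarithmicParams",
    "InsufficientDataError",
    "DegenerateSlopeError",
    "UndefinedCodError",
    "evaluate_theoretical",
    "fit_theoretical",
    "fit_logarithmic",
    "normalize_accuracies",
    "goodness_of_fit",
    "compare_model_fits",
    "adherence_correlation",
    "PairedTestResult",
    "AdherenceResult",
]

#: default cap on scan time (minutes) for the logarithmic fit
DEFAULT_T_CAP_MIN = 20.0

MIN_CELLS_FOR_FIT = 4

CELL_COLUMNS = ("n_train", "t_min", "accuracy", "n_reps")


class InsufficientDataError(ValueError):
    """Too few grid cells for the requested fit."""


class DegenerateSlopeError(ValueError):
    """Normalization requested with a zero logarithmic slope."""


class UndefinedCodError(ValueError):
    """Coefficient of determination undefined (zero observed variance)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccuracyGrid:
    """Per-phenotype table of mean prediction accuracy indexed by (N, T).

    ``cells`` is a DataFrame with columns ``n_train`` (training participants),
    ``t_min`` (scan time per participant, minutes), ``accuracy`` (mean over
    repetitions) and ``n_reps``.
    """

    dataset_id: str
    phenotype_id: str
    metric: str  # "pearson" | "cod"
    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.metric not in ("pearson", "cod"):
            raise ValueError(f"unknown metric {self.metric!r}")
        cells = pd.DataFrame(self.cells)
        missing = [c for c in CELL_COLUMNS if c not in cells.columns and c != "n_reps"]
        if missing:
            raise ValueError(f"accuracy grid missing columns: {missing}")
        if "n_reps" not in cells.columns:
            cells = cells.assign(n_reps=1)
        cells = cells.loc[:, list(CELL_COLUMNS)].reset_index(drop=True)
        if len(cells) == 0:
            raise ValueError("accuracy grid has no cells")
        if (cells["n_train"] <= 0).any() or (cells["t_min"] <= 0).any():
            raise ValueError("n_train and t_min must be positive")
        if cells.duplicated(["n_train", "t_min"]).any():
            dup = cells[cells.duplicated(["n_train", "t_min"], keep=False)]
            raise ValueError(
                "duplicate (n_train, t_min) cells: "
                + ", ".join(f"({r.n_train}, {r.t_min})" for r in dup.itertuples())
            )
        if not np.isfinite(cells["accuracy"].to_numpy(float)).all():
            raise ValueError("accuracies must be finite")
        if self.metric == "pearson":
            acc = cells["accuracy"].to_numpy(float)
            if (acc < -1).any() or (acc > 1).any():
                raise ValueError("pearson accuracies must lie in [-1, 1]")
        object.__setattr__(self, "cells", cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def max_accuracy(self) -> float:
        return float(self.cells["accuracy"].max())

    @property
    def fraction_positive(self) -> float:
        return float((self.cells["accuracy"] > 0).mean())

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = self.cells
        return (
            c["n_train"].to_numpy(float),
            c["t_min"].to_numpy(float),
            c["accuracy"].to_numpy(float),
        )


@dataclass(frozen=True)
class TheoreticalParams:
    """Fitted parameters of the theoretical accuracy law."""

    k0: float
    k1: float
    k2: float
    r2: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.k0 <= 1):
            raise ValueError(f"k0 must lie in (0, 1], got {self.k0}")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be nonnegative")

    def predict(self, n, t):
        return evaluate_theoretical(self, n, t)


@dataclass(frozen=True)
class LogarithmicParams:
    """OLS fit of accuracy on log2(total scan duration), short scans only."""

    slope_z: float
    intercept_k: float
    r2: float = float("nan")
    t_cap_min: float = DEFAULT_T_CAP_MIN

    def predict(self, n, t):
        n = np.asarray(n, float)
        t = np.asarray(t, float)
        return self.slope_z * np.log2(n * t) + self.intercept_k


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def evaluate_theoretical(params: TheoreticalParams, n, t):
    """Expected prediction accuracy at sample size ``n`` and scan time ``t``.

    Both arguments may be scalars or arrays; ``inf`` is accepted and treated
    as the corresponding limit.  Nondecreasing in both arguments.
    """
    n = np.asarray(n, float)
    t = np.asarray(t, float)
    if np.any(n <= 0) or np.any(t <= 0):
        raise ValueError("n and t must be positive")
    with np.errstate(invalid="ignore"):
        denom = 1.0 + params.k1 / n + params.k2 / (n * t)
    # inf * inf etc. -> terms vanish in the limit
    denom = np.where(np.isnan(denom), 1.0, denom)
    out = params.k0 / np.sqrt(denom)
    return out if out.ndim else float(out)


def goodness_of_fit(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    ``SS_tot`` is taken about the mean of ``observed``.  Raises
    :class:`UndefinedCodError` when the observed values have zero variance.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(obs) == 0:
        raise UndefinedCodError("observed values have zero variance")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# fitting the theoretical model
# ---------------------------------------------------------------------------

_K0_BOUNDS = (1e-8, 1.0)
_K1_MAX = 1e8
_K2_MAX = 1e10


def _theoretical_loss_grad(x, n, t, y):
    k0, k1, k2 = x
    d = 1.0 + k1 / n + k2 / (n * t)
    root = np.sqrt(d)
    m = k0 / root
    r = m - y
    j = len(y)
    loss = float(np.mean(r * r))
    dm_dk0 = 1.0 / root
    common = -0.5 * k0 * d ** (-1.5)
    dm_dk1 = common / n
    dm_dk2 = common / (n * t)
    grad = 2.0 / j * np.array(
        [np.sum(r * dm_dk0), np.sum(r * dm_dk1), np.sum(r * dm_dk2)]
    )
    return loss, grad


def _linearized_start(n, t, y):
    """OLS of 1/y^2 on [1, 1/n, 1/(nt)] gives a good launch point when y > 0."""
    mask = y > 1e-3
    if mask.sum() < 3:
        return None
    ni, ti, yi = n[mask], t[mask], y[mask]
    A = np.column_stack([np.ones_like(ni), 1.0 / ni, 1.0 / (ni * ti)])
    b, *_ = np.linalg.lstsq(A, 1.0 / yi**2, rcond=None)
    if b[0] <= 0:
        return None
    k0 = min(1.0, 1.0 / math.sqrt(b[0]))
    k1 = max(0.0, b[1] / b[0])
    k2 = max(0.0, b[2] / b[0])
    return np.array([k0, k1, k2])


def fit_theoretical(
    grid: AccuracyGrid,
    *,
    n_starts: int = 20,
    seed: int = 0,
) -> TheoreticalParams:
    """Fit the theoretical law to a grid by (multi-start) MSE minimization.

    The loss is the mean squared error between the model and the
    rep-averaged cell accuracies, minimized by bounded L-BFGS with analytic
    gradients from ``n_starts`` seeded Latin-hypercube launch points plus a
    linearized OLS launch point.  Constraints: ``k0 in (0, 1]``,
    ``k1, k2 >= 0``.  Deterministic given ``seed``.

    A flat grid (all accuracies identical) returns ``k1 = k2 = 0`` with
    ``k0`` equal to the common value and ``r2 = 1`` by convention.
    """
    if grid.n_cells < MIN_CELLS_FOR_FIT:
        raise InsufficientDataError(
            f"need >= {MIN_CELLS_FOR_FIT} cells, got {grid.n_cells}"
        )
    n, t, y = grid.arrays()
    if np.ptp(y) == 0:
        k0 = float(np.clip(y[0], _K0_BOUNDS[0], 1.0))
        return TheoreticalParams(k0=k0, k1=0.0, k2=0.0, r2=1.0, converged=True)

    starts = []
    lin = _linearized_start(n, t, y)
    if lin is not None:
        starts.append(lin)
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    u = sampler.random(n_starts)
    # k0 uniform on (0.02, 1); k1, k2 log-uniform over wide ranges
    lhs = np.column_stack(
        [
            0.02 + 0.98 * u[:, 0],
            10.0 ** (-1 + 7 * u[:, 1]),
            10.0 ** (9 * u[:, 2]),
        ]
    )
    starts.extend(lhs)

    bounds = [_K0_BOUNDS, (0.0, _K1_MAX), (0.0, _K2_MAX)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _theoretical_loss_grad,
            np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            args=(n, t, y),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    k0, k1, k2 = best.x
    pred = k0 / np.sqrt(1.0 + k1 / n + k2 / (n * t))
    r2 = goodness_of_fit(y, pred)
    # L-BFGS can abort its line search at an already-excellent solution;
    # judge convergence by the projected gradient, not the status flag
    _, grad = _theoretical_loss_grad(best.x, n, t, y)
    at_bound = np.isclose(best.x, [b[0] for b in bounds]) | np.isclose(
        best.x, [b[1] for b in bounds]
    )
    grad_ok = np.all(at_bound | (np.abs(grad) < 1e-6))
    return TheoreticalParams(
        k0=float(k0), k1=float(k1), k2=float(k2), r2=r2,
        converged=bool(best.success or grad_ok),
    )


# ---------------------------------------------------------------------------
# logarithmic model
# ---------------------------------------------------------------------------


def fit_logarithmic(
    grid: AccuracyGrid, t_cap_min: float = DEFAULT_T_CAP_MIN
) -> LogarithmicParams:
    """OLS of accuracy on log2(N*T), using only cells with ``t <= t_cap_min``."""
    cells = grid.cells[grid.cells["t_min"] <= t_cap_min]
    if len(cells) < 2:
        raise InsufficientDataError(
            f"need >= 2 cells with t_min <= {t_cap_min}, got {len(cells)}"
        )
    x = np.log2(cells["n_train"].to_numpy(float) * cells["t_min"].to_numpy(float))
    y = cells["accuracy"].to_numpy(float)
    if np.ptp(y) == 0:  # constant accuracy: exact fit with zero slope
        return LogarithmicParams(0.0, float(y[0]), r2=1.0, t_cap_min=t_cap_min)
    slope, intercept = np.polyfit(x, y, 1)
    r2 = goodness_of_fit(y, slope * x + intercept)
    return LogarithmicParams(float(slope), float(intercept), r2=r2, t_cap_min=t_cap_min)


def normalize_accuracies(grid: AccuracyGrid, params: LogarithmicParams) -> pd.DataFrame:
    """Map a grid onto the common normalized scale ``(y - k) / z``.

    On this scale a phenotype obeying the logarithmic model lies exactly on
    the ``log2(N*T)`` curve regardless of its own slope and intercept, which
    is what allows phenotypes from different datasets to be pooled.  Returns
    a DataFrame with the cell coordinates, ``log2_total_duration`` and
    ``normalized_accuracy``.
    """
    if params.slope_z == 0:
        raise DegenerateSlopeError("cannot normalize with slope_z = 0")
    c = grid.cells.copy()
    c["log2_total_duration"] = np.log2(c["n_train"] * c["t_min"])
    c["normalized_accuracy"] = (c["accuracy"] - params.intercept_k) / params.slope_z
    c.insert(0, "phenotype", grid.phenotype_id)
    c.insert(0, "dataset", grid.dataset_id)
    return c


# ---------------------------------------------------------------------------
# model comparison across phenotypes
# ---------------------------------------------------------------------------


class PairedTestResult(NamedTuple):
    statistic: float
    pvalue: float
    n: int


class AdherenceResult(NamedTuple):
    rho: float
    pvalue: float
    n_perm: int


def compare_model_fits(
    r2_a: Sequence[float], r2_b: Sequence[float]
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired per-phenotype R2 values."""
    a = np.asarray(r2_a, float)
    b = np.asarray(r2_b, float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired values")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(0.0, 1.0, a.size)
    stat, p = stats.wilcoxon(a, b, alternative="two-sided")
    return PairedTestResult(float(stat), float(p), a.size)


def adherence_correlation(
    fit_r2: Sequence[float],
    max_accuracy: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> AdherenceResult:
    """Spearman correlation between model fit and peak predictability.

    Phenotypes that are predicted well tend to adhere to the theoretical
    model; this quantifies that with Spearman's rho and a label-permutation
    p-value (``n_perm`` shuffles, reproducible given ``seed``).
    """
    x = np.asarray(fit_r2, float)
    y = np.asarray(max_accuracy, float)
    if x.shape != y.shape:
        raise ValueError("paired lists must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant list")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AdherenceResult(rho, p, n_perm)
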