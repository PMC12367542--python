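"""Economic optimization of BWAS designs.

Study cost model: scanning ``N`` participants for ``T`` minutes each costs
``(T/60 * S + O) * N`` where ``S`` is the scanner cost per hour and ``O`` the
per-participant overhead (recruitment, neuropsychological testing, other
modalities).  Two dual optimizations are supported:

* **within a fixed budget** — for each scan time the budget buys the largest
  affordable sample; pick the scan time maximizing the predicted fraction of
  maximum accuracy;
* **for a fixed accuracy target** — walk the iso-accuracy contour and pick
  the (N, T) pair with the lowest study cost.

On top of these sit scenario grids (targets x overheads x scan rates x
datasets), cost-inefficiency and savings curves for *fixed* scan times, and a
phenotype-level bootstrap for the most cost-effective fixed scan time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .scaling import TheoreticalParams
from .surface import (
    DEFAULT_TRAIN_FRACTION,
    DesignSurface,
    UnattainableTargetError,
    build_average_surface,
    contour_sample,
)

__all__ = [
    "CostSpec",
    "Scenario",
    "ScenarioResult",
    "BudgetOptimum",
    "InfeasibleError",
    "study_cost",
    "optimize_within_budget",
    "optimize_for_target",
    "build_scenarios",
    "cost_inefficiency_curve",
    "savings_vs_reference",
    "bootstrap_best_fixed_time",
    "DEFAULT_FIXED_T_GRID",
    "DEFAULT_OPT_T_GRID",
    "DEFAULT_TARGETS",
    "DEFAULT_OVERHEADS",
    "DEFAULT_SCAN_COSTS",
]

#: scan-time grid for the optimizers: 1 to 200 min in 1-min steps
DEFAULT_OPT_T_GRID = tuple(range(1, 201))
#: fixed-scan-time grid for inefficiency/savings curves: 5 to 100 in 5-min steps
DEFAULT_FIXED_T_GRID = tuple(range(5, 101, 5))
#: default scenario conditions: 3 targets x 2 overheads x 2 scan rates
DEFAULT_TARGETS = (0.80, 0.90, 0.95)
DEFAULT_OVERHEADS = (500.0, 1000.0)
DEFAULT_SCAN_COSTS = (500.0, 1000.0)


class InfeasibleError(ValueError):
    """No feasible design under the given constraints."""


@dataclass(frozen=True)
class CostSpec:
    """Economic assumptions: scan cost per hour S, overhead per participant O,
    and (optionally) a total fMRI budget B."""

    scan_cost_per_hour: float
    overhead_per_participant: float
    budget: float | None = None

    def __post_init__(self) -> None:
        if self.scan_cost_per_hour < 0 or self.overhead_per_participant < 0:
            raise ValueError("costs must be nonnegative")
        if self.budget is not None and self.budget <= 0:
            raise ValueError("budget must be positive when present")

    def per_participant(self, t_min) -> np.ndarray:
        """Cost of one participant scanned for ``t_min`` minutes."""
        t = np.asarray(t_min, float)
        return t / 60.0 * self.scan_cost_per_hour + self.overhead_per_participant


def study_cost(n, t_min, spec: CostSpec):
    """Total cost (T/60 * S + O) * N.  Linear in N, affine in T."""
    n = np.asarray(n, float)
    t = np.asarray(t_min, float)
    if np.any(n < 0) or np.any(t < 0):
        raise ValueError("n and t_min must be nonnegative")
    out = spec.per_participant(t) * n
    return out if out.ndim else float(out)


class BudgetOptimum(NamedTuple):
    n_recruited: int
    t_min: float
    fraction: float


def optimize_within_budget(
    surface: DesignSurface,
    spec: CostSpec,
    t_grid: Sequence[float] = DEFAULT_OPT_T_GRID,
) -> BudgetOptimum:
    """Maximize the accuracy fraction within a fixed fMRI budget.

    For each scan time ``t`` the budget buys ``N = floor(B / (t/60*S + O))``
    participants; the (N, t) pair with the largest surface fraction wins,
    ties broken toward the smaller scan time.
    """
    if spec.budget is None:
        raise ValueError("CostSpec.budget required")
    t = np.asarray(t_grid, float)
    n = np.floor(spec.budget / spec.per_participant(t))
    feasible = n * surface.train_fraction >= 1
    if not feasible.any():
        raise InfeasibleError("budget cannot recruit a single trainable participant")
    t_f, n_f = t[feasible], n[feasible]
    frac = surface.fraction_at(n_f, t_f)
    order = np.argsort(t_f, kind="stable")
    t_f, n_f, frac = t_f[order], n_f[order], frac[order]
    best = int(np.argmax(frac))  # argmax returns the first (smallest t) on ties
    return BudgetOptimum(int(n_f[best]), float(t_f[best]), float(frac[best]))


@dataclass(frozen=True)
class Scenario:
    """One cost-optimization scenario: a dataset surface, an accuracy target
    and the economic assumptions."""

    dataset_id: str
    surface: DesignSurface
    target_fraction: float
    spec: CostSpec


@dataclass(frozen=True)
class ScenarioResult:
    dataset_id: str
    target_fraction: float
    cost_spec: CostSpec
    optimal_t_min: float
    optimal_n: int
    min_cost: float
    inefficiency_curve: Mapping[float, float] = field(default_factory=dict)


def _contour_costs(
    surface: DesignSurface,
    target: float,
    spec: CostSpec,
    t_grid: Sequence[float],
) -> pd.DataFrame:
    """Cost of the cheapest integer sample achieving the target at each t."""
    contour = contour_sample(surface, target, t_grid)
    n = np.ceil(contour["n_recruited"].to_numpy() - 1e-9)
    n = np.maximum(n, math.ceil(surface.min_n_recruited - 1e-9))
    cost = study_cost(n, contour["t_min"].to_numpy(), spec)
    return pd.DataFrame({"t_min": contour["t_min"], "n_recruited": n, "cost": cost})


def optimize_for_target(
    surface: DesignSurface,
    target_fraction: float,
    spec: CostSpec,
    t_grid: Sequence[float] = DEFAULT_OPT_T_GRID,
    dataset_id: str = "",
) -> ScenarioResult:
    """Minimize study cost subject to reaching ``target_fraction``.

    Samples the target contour over ``t_grid``, rounds samples up to whole
    participants, and returns the cheapest (N, T); ties toward smaller T.
    """
    table = _contour_costs(surface, target_fraction, spec, t_grid)
    table = table.sort_values("t_min", kind="stable")
    best = table.iloc[int(np.argmin(table["cost"].to_numpy()))]
    return ScenarioResult(
        dataset_id=dataset_id,
        target_fraction=target_fraction,
        cost_spec=spec,
        optimal_t_min=float(best["t_min"]),
        optimal_n=int(best["n_recruited"]),
        min_cost=float(best["cost"]),
    )


def build_scenarios(
    surfaces: Mapping[str, DesignSurface],
    targets: Sequence[float] = DEFAULT_TARGETS,
    overheads: Sequence[float] = DEFAULT_OVERHEADS,
    scan_costs: Sequence[float] = DEFAULT_SCAN_COSTS,
) -> list[Scenario]:
    """Cartesian scenario grid: datasets x targets x overheads x scan rates.

    The default conditions (3 targets x 2 overheads x 2 scan rates = 12 per
    dataset) give 108 scenarios over nine datasets.
    """
    out = []
    for dataset_id, surface in surfaces.items():
        for target in targets:
            for o in overheads:
                for s in scan_costs:
                    out.append(
                        Scenario(
                            dataset_id=dataset_id,
                            surface=surface,
                            target_fraction=target,
                            spec=CostSpec(scan_cost_per_hour=s, overhead_per_participant=o),
                        )
                    )
    return out


class InefficiencyCurves(NamedTuple):
    fixed_t: np.ndarray
    mean_inefficiency: np.ndarray  # mean over scenarios of cost(t)/cost_opt - 1
    normalized: np.ndarray  # mean curve minus its minimum
    per_scenario: pd.DataFrame  # rows: scenario index, columns: fixed t
    best_fixed_t: float


def cost_inefficiency_curve(
    scenarios: Sequence[Scenario],
    fixed_t_grid: Sequence[float] = DEFAULT_FIXED_T_GRID,
    opt_t_grid: Sequence[float] = DEFAULT_OPT_T_GRID,
) -> InefficiencyCurves:
    """Average relative extra cost of fixing the scan time.

    Per scenario and fixed ``t``: the cost of the cheapest sample achieving
    the target at that ``t``, divided by the scenario's optimal cost, minus 1.
    Averaged across scenarios; also reported normalized by subtracting the
    curve's minimum so the best fixed time sits at zero.  Scenarios for which
    a fixed ``t`` is infeasible are dropped from that t's average with a
    warning.
    """
    fixed_t = np.asarray(fixed_t_grid, float)
    rows = []
    for sc in scenarios:
        opt = optimize_for_target(
            sc.surface, sc.target_fraction, sc.spec, opt_t_grid, sc.dataset_id
        )
        try:
            fixed = _contour_costs(sc.surface, sc.target_fraction, sc.spec, fixed_t)
            ineff = fixed["cost"].to_numpy() / opt.min_cost - 1.0
        except UnattainableTargetError:
            warnings.warn(
                f"scenario {sc.dataset_id} target {sc.target_fraction}: "
                "infeasible at some fixed scan times; excluded"
            )
            ineff = np.full(fixed_t.shape, np.nan)
        rows.append(ineff)
    per_scenario = pd.DataFrame(rows, columns=fixed_t)
    mean = per_scenario.mean(axis=0, skipna=True).to_numpy()
    normalized = mean - np.nanmin(mean)
    best = float(fixed_t[int(np.nanargmin(mean))])
    return InefficiencyCurves(fixed_t, mean, normalized, per_scenario, best)


def savings_vs_reference(
    scenarios: Sequence[Scenario],
    reference_t: float = 10.0,
    fixed_t_grid: Sequence[float] = DEFAULT_FIXED_T_GRID,
    opt_t_grid: Sequence[float] = DEFAULT_OPT_T_GRID,
) -> pd.DataFrame:
    """Percent cost savings of each fixed scan time over ``reference_t``:
    ``100 * (1 - mean_scenarios[cost(t) / cost(reference_t)])``."""
    fixed_t = np.asarray(fixed_t_grid, float)
    if reference_t not in fixed_t:
        raise ValueError("reference_t must be in fixed_t_grid")
    ratios = []
    for sc in scenarios:
        fixed = _contour_costs(sc.surface, sc.target_fraction, sc.spec, fixed_t)
        cost = fixed["cost"].to_numpy()
        ref = cost[np.flatnonzero(fixed_t == reference_t)[0]]
        ratios.append(cost / ref)
    mean_ratio = np.mean(ratios, axis=0)
    return pd.DataFrame(
        {"t_min": fixed_t, "savings_pct": 100.0 * (1.0 - mean_ratio)}
    )


class BootstrapBestTime(NamedTuple):
    best_t: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray


def bootstrap_best_fixed_time(
    fits_by_dataset: Mapping[str, Sequence[TheoreticalParams]],
    targets: Sequence[float] = DEFAULT_TARGETS,
    overheads: Sequence[float] = DEFAULT_OVERHEADS,
    scan_costs: Sequence[float] = DEFAULT_SCAN_COSTS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    fixed_t_grid: Sequence[float] = DEFAULT_FIXED_T_GRID,
    opt_t_grid: Sequence[float] = DEFAULT_OPT_T_GRID,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapBestTime:
    """Percentile bootstrap CI for the most cost-effective fixed scan time.

    The resampling unit is the phenotype, resampled with replacement within
    each dataset; each replicate rebuilds the per-dataset average surfaces,
    the scenario grid and the mean inefficiency curve, and records its argmin
    on ``fixed_t_grid``.  The point estimate comes from the original data.
    Reproducible given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    fits_by_dataset = {k: list(v) for k, v in fits_by_dataset.items()}

    def _best(fbd: Mapping[str, Sequence[TheoreticalParams]]) -> float:
        surfaces = {
            ds: build_average_surface(fits, train_fraction)
            for ds, fits in fbd.items()
        }
        scen = build_scenarios(surfaces, targets, overheads, scan_costs)
        return cost_inefficiency_curve(scen, fixed_t_grid, opt_t_grid).best_fixed_t

    point = _best(fits_by_dataset)
    n_phen_total = sum(len(v) for v in fits_by_dataset.values())
    if n_phen_total == 1:
        warnings.warn("single phenotype: bootstrap CI degenerates to the point estimate")
        return BootstrapBestTime(point, point, point, np.full(n_boot, point))

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        resampled = {
            ds: [fits[i] for i in rng.integers(0, len(fits), size=len(fits))]
            for ds, fits in fits_by_dataset.items()
        }
        reps[b] = _best(resampled)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapBestTime(point, float(lo), float(hi), reps)
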