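"""Fraction-of-maximum-accuracy surfaces over (sample size, scan time).

A fitted theoretical model is normalized by its asymptotic accuracy ``K0``,
yielding the fraction of the maximum achievable prediction accuracy attained
at a given recruited sample size ``N`` and scan time ``T``:

    fraction(N, T) = sqrt(1 / (1 + K1/(f*N) + K2/(f*N*T)))

where ``f`` is the fraction of recruited participants used for training
(0.9 under a tenfold cross-validation design; the remaining participants form
the test fold).  ``K0`` cancels, so surfaces from phenotypes with very
different peak accuracies can be averaged into a single design reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scaling import AccuracyGrid, TheoreticalParams

__all__ = [
    "DesignSurface",
    "UnattainableTargetError",
    "fraction_of_max",
    "build_average_surface",
    "contour_sample",
    "iso_duration_slice",
    "filter_phenotypes",
    "DEFAULT_N_GRID",
    "DEFAULT_T_GRID",
]

DEFAULT_TRAIN_FRACTION = 0.9
#: default export grids: N in {25, 50, ..., 10000}, T in {1, ..., 200} minutes
DEFAULT_N_GRID = np.arange(25, 10001, 25, dtype=float)
DEFAULT_T_GRID = np.arange(1, 201, dtype=float)

BISECTION_TOL = 0.01  # participants


class UnattainableTargetError(ValueError):
    """Requested accuracy fraction cannot be reached at any finite N."""


def _check_train_fraction(f: float) -> None:
    if not (0 < f <= 1):
        raise ValueError(f"train_fraction must lie in (0, 1], got {f}")


def fraction_of_max(
    params: TheoreticalParams,
    n_recruited,
    t,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
):
    """Fraction of the phenotype's maximum achievable accuracy at (N, T).

    Accuracy is evaluated at the training sample size
    ``train_fraction * n_recruited`` and divided by ``k0`` (which cancels),
    so the result is independent of the phenotype's peak accuracy.
    """
    _check_train_fraction(train_fraction)
    n = np.asarray(n_recruited, float)
    t = np.asarray(t, float)
    if np.any(n * train_fraction < 1):
        raise ValueError("train_fraction * n_recruited must be >= 1")
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    f_n = train_fraction * n
    out = 1.0 / np.sqrt(1.0 + params.k1 / f_n + params.k2 / (f_n * t))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DesignSurface:
    """Average fraction-of-maximum surface over a set of phenotype fits.

    The surface is analytic: ``fraction_at`` evaluates the unweighted mean of
    per-phenotype fractions at arbitrary (N, T), and ``sample`` materializes
    it on a grid for export.  Monotone nondecreasing in both arguments.
    """

    fits: tuple[TheoreticalParams, ...]
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    source_phenotypes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.fits) == 0:
            raise ValueError("surface needs at least one fitted phenotype")
        _check_train_fraction(self.train_fraction)
        object.__setattr__(self, "fits", tuple(self.fits))
        object.__setattr__(
            self, "source_phenotypes", tuple(tuple(p) for p in self.source_phenotypes)
        )

    @property
    def n_phenotypes(self) -> int:
        return len(self.fits)

    def fraction_at(self, n_recruited, t):
        """Unweighted mean fraction across phenotypes; broadcasts over arrays."""
        n = np.asarray(n_recruited, float)
        t = np.asarray(t, float)
        f_n = self.train_fraction * n
        if np.any(f_n < 1):
            raise ValueError("train_fraction * n_recruited must be >= 1")
        k1 = np.array([p.k1 for p in self.fits])
        k2 = np.array([p.k2 for p in self.fits])
        denom = 1.0 + k1 / f_n[..., None] + k2 / (f_n[..., None] * t[..., None])
        out = np.mean(1.0 / np.sqrt(denom), axis=-1)
        return out if out.ndim else float(out)

    @property
    def min_n_recruited(self) -> float:
        """Smallest recruited N with at least one training participant."""
        return 1.0 / self.train_fraction

    def sample(
        self,
        n_grid: Sequence[float] = DEFAULT_N_GRID,
        t_grid: Sequence[float] = DEFAULT_T_GRID,
    ) -> pd.DataFrame:
        n_grid = np.asarray(n_grid, float)
        t_grid = np.asarray(t_grid, float)
        nn, tt = np.meshgrid(n_grid, t_grid, indexing="ij")
        frac = self.fraction_at(nn.ravel(), tt.ravel())
        return pd.DataFrame(
            {"n_recruited": nn.ravel(), "t_min": tt.ravel(), "fraction": frac}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_fraction": self.train_fraction,
                "source_phenotypes": [list(p) for p in self.source_phenotypes],
                "fits": [
                    {"k0": p.k0, "k1": p.k1, "k2": p.k2, "r2": p.r2}
                    for p in self.fits
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DesignSurface":
        d = json.loads(text)
        fits = tuple(
            TheoreticalParams(k0=f["k0"], k1=f["k1"], k2=f["k2"], r2=f.get("r2", float("nan")))
            for f in d["fits"]
        )
        return cls(
            fits=fits,
            train_fraction=d["train_fraction"],
            source_phenotypes=tuple(tuple(p) for p in d["source_phenotypes"]),
        )


def build_average_surface(
    fits: Iterable[TheoreticalParams],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    source_phenotypes: Iterable[tuple[str, str]] = (),
) -> DesignSurface:
    """Unweighted phenotype-level average surface (datasets contribute in
    proportion to their phenotype counts)."""
    fits = tuple(fits)
    if not fits:
        raise ValueError("empty fit list")
    if not all(p.converged for p in fits):
        raise ValueError("all fits must have converged")
    return DesignSurface(
        fits=fits, train_fraction=train_fraction, source_phenotypes=tuple(source_phenotypes)
    )


def _closed_form_contour_n(
    params: TheoreticalParams, target: float, t, train_fraction: float
):
    """n = (k1 + k2/t) / (f * (1/target^2 - 1)), the exact contour for one fit."""
    t = np.asarray(t, float)
    denom = train_fraction * (1.0 / target**2 - 1.0)
    n = (params.k1 + params.k2 / t) / denom
    return np.maximum(n, 1.0 / train_fraction)


def contour_sample(
    surface_or_params,
    target_fraction: float,
    t_grid: Sequence[float],
    train_fraction: float | None = None,
    tol: float = BISECTION_TOL,
) -> pd.DataFrame:
    """Smallest recruited N reaching ``target_fraction`` at each scan time.

    For a single theoretical fit the closed form is used; for an averaged
    surface, vectorized bisection on the monotone N axis (tolerance ``tol``
    participants).  N is returned as a real number; round up when costing.
    """
    if not (0 < target_fraction < 1):
        raise UnattainableTargetError(
            f"target fraction must lie in (0, 1), got {target_fraction}"
        )
    t = np.asarray(t_grid, float)
    if np.any(t <= 0):
        raise ValueError("scan times must be positive")

    if isinstance(surface_or_params, TheoreticalParams):
        f = DEFAULT_TRAIN_FRACTION if train_fraction is None else train_fraction
        _check_train_fraction(f)
        n = _closed_form_contour_n(surface_or_params, target_fraction, t, f)
        return pd.DataFrame({"t_min": t, "n_recruited": n})

    surface: DesignSurface = surface_or_params
    if train_fraction is not None and train_fraction != surface.train_fraction:
        raise ValueError("train_fraction fixed by the surface")
    lo = np.full_like(t, surface.min_n_recruited)
    # grow upper bracket until the target is attained everywhere
    hi = np.maximum(lo * 2, 100.0)
    for _ in range(80):
        frac = surface.fraction_at(hi, t)
        if np.all(frac >= target_fraction):
            break
        hi = np.where(frac < target_fraction, hi * 4, hi)
        if np.any(hi > 1e15):
            raise UnattainableTargetError(
                f"target {target_fraction} not attainable at some scan times"
            )
    # cells already satisfied at the minimum n keep the minimum
    at_min = surface.fraction_at(lo, t) >= target_fraction
    while np.max(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        ok = surface.fraction_at(mid, t) >= target_fraction
        hi = np.where(ok, mid, hi)
        lo = np.where(ok, lo, mid)
    n = np.where(at_min, surface.min_n_recruited, hi)
    return pd.DataFrame({"t_min": t, "n_recruited": n})


def iso_duration_slice(
    params: TheoreticalParams, total_minutes: float, t_grid: Sequence[float]
) -> pd.DataFrame:
    """Accuracy along a fixed total scan duration ``N*T = total_minutes``.

    With ``k1 > 0`` the slice is strictly decreasing in ``t`` (shifting
    minutes from new participants to longer scans always loses accuracy once
    the sample-size-limited term matters); with ``k1 = 0`` it is flat.
    """
    t = np.asarray(t_grid, float)
    n = total_minutes / t
    if np.any(n < 1):
        raise ValueError("total_minutes too small for some scan times (n < 1)")
    acc = params.predict(n, t)
    return pd.DataFrame({"n_train": n, "t_min": t, "accuracy": acc})


def filter_phenotypes(
    grids: Sequence[AccuracyGrid], rule: str
) -> list[AccuracyGrid]:
    """Select phenotypes by predictability.

    ``max_gt_0.1``:  maximum cell accuracy > 0.1 (the stricter rule).
    ``positive_90pct``: accuracy positive in >= 90% of (N, T) cells.
    """
    if len(grids) == 0:
        raise ValueError("no grids provided")
    if rule == "max_gt_0.1":
        return [g for g in grids if g.max_accuracy > 0.1]
    if rule == "positive_90pct":
        return [g for g in grids if g.fraction_positive >= 0.9]
    raise ValueError(f"unknown rule {rule!r}")
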