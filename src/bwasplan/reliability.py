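"""Split-half BWAS reliability as a function of sample size and scan time.

A brain-wide association statistic (a vector with one value per FC edge) is
computed independently in two disjoint halves of the cohort, and the
agreement between the two vectors is quantified with an intraclass
correlation over edges.  Two association statistics are supported:

* ``univariate_t`` — the edgewise phenotype-correlation t statistic,
  ``t = r * sqrt((n-2) / (1-r^2))``;
* ``haufe`` — the Haufe activation vector (feature-prediction covariance)
  of a kernel ridge predictor trained on the half.

The default ICC is the one-way random, single-measurement form: with the
edge as the grouping unit and the two halves as the two measurements,
``ICC = (MS_between - MS_within) / (MS_between + MS_within)``, which
penalizes mean offsets between halves.  A consistency-type alternative
(Pearson correlation over edges) is available via ``icc_kind``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .prediction import PredictorSpec, _fit_predict, _kernel, haufe_transform

__all__ = [
    "SplitHalfResult",
    "univariate_edge_stats",
    "split_half_icc",
    "reliability_experiment",
]


@dataclass(frozen=True)
class SplitHalfResult:
    half_size: int
    t_min: float
    icc: float
    stat_kind: str


def univariate_edge_stats(features: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Per-edge t statistics of the edge-phenotype Pearson correlation."""
    X = np.asarray(features, float)
    y = np.asarray(phenotype, float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if y.std() == 0:
        raise ValueError("phenotype has zero variance")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    sy = np.sqrt(np.sum(yc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.where(sx == 0, 0.0, r)  # zero-variance edges carry no association
    sat = np.flatnonzero(np.abs(r) >= 1 - 1e-12)
    if sat.size:
        raise ValueError(f"|r| = 1 at edges {sat.tolist()}: t is infinite")
    return r * np.sqrt((n - 2) / (1 - r**2))


def split_half_icc(vec_a, vec_b, icc_kind: str = "oneway") -> float:
    """Intraclass correlation between two per-edge statistic vectors.

    ``oneway``: one-way random single-measurement ICC with edges as groups
    and the two halves as measurements.  ``consistency``: Pearson
    correlation over edges (insensitive to additive/scale offsets).
    """
    a = np.asarray(vec_a, float)
    b = np.asarray(vec_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length vectors")
    if a.size < 3:
        raise ValueError("need at least 3 edges")
    if icc_kind == "consistency":
        if a.std() == 0 or b.std() == 0:
            raise ValueError("zero variance: ICC undefined")
        return float(np.corrcoef(a, b)[0, 1])
    if icc_kind != "oneway":
        raise ValueError(f"unknown icc_kind {icc_kind!r}")
    m = a.size
    pairs = np.column_stack([a, b])
    grand = pairs.mean()
    group_means = pairs.mean(axis=1)
    ms_between = 2.0 * np.sum((group_means - grand) ** 2) / (m - 1)
    ms_within = np.sum((pairs - group_means[:, None]) ** 2) / m
    denom = ms_between + ms_within
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    return float((ms_between - ms_within) / denom)


def _half_statistic(features, phenotype, idx, stat_kind, spec, rng):
    if stat_kind == "univariate_t":
        return univariate_edge_stats(features[idx], phenotype[idx])
    if stat_kind == "haufe":
        K = _kernel(features[idx], spec.kernel) if spec.model == "krr" else None
        local = np.arange(len(idx))
        fitted = _fit_predict(
            features[idx], K, local, local, phenotype[idx], spec, rng
        )
        return haufe_transform(features[idx], fitted)
    raise ValueError(f"unknown stat_kind {stat_kind!r}")


def reliability_experiment(
    cohort,
    half_sizes: Sequence[int],
    t_list: Sequence[float],
    n_reps: int = 10,
    seed: int = 0,
    stat_kind: str = "univariate_t",
    spec: PredictorSpec | None = None,
    icc_kind: str = "oneway",
) -> pd.DataFrame:
    """Mean split-half ICC for every (half size, scan time) combination.

    Each repetition draws two disjoint random halves of the requested size,
    computes the association statistic in each, and records their ICC;
    degenerate (zero-variance) edges are dropped pairwise with a count.
    Returns a long-form DataFrame with columns ``half_size, t_min, icc,
    stat_kind, n_dropped_edges``.
    """
    from .cohort import observe_fc  # local import to avoid a cycle

    if cohort.n_subjects < 2 * max(half_sizes):
        raise ValueError("cohort too small for the requested half sizes")
    if spec is None:
        spec = PredictorSpec(inner_folds=5)
    rng = np.random.default_rng(seed)
    features = {t: observe_fc(cohort, t) for t in t_list}
    rows = []
    for t in t_list:
        X = features[t]
        for h in half_sizes:
            iccs, dropped = [], 0
            for _ in range(n_reps):
                perm = rng.permutation(cohort.n_subjects)
                half_a, half_b = perm[:h], perm[h : 2 * h]
                assert not np.intersect1d(half_a, half_b).size
                va = _half_statistic(X, cohort.phenotype, half_a, stat_kind, spec, rng)
                vb = _half_statistic(X, cohort.phenotype, half_b, stat_kind, spec, rng)
                ok = np.isfinite(va) & np.isfinite(vb)
                dropped += int((~ok).sum())
                iccs.append(split_half_icc(va[ok], vb[ok], icc_kind))
            rows.append(
                {
                    "half_size": h,
                    "t_min": t,
                    "icc": float(np.mean(iccs)),
                    "stat_kind": stat_kind,
                    "n_dropped_edges": dropped,
                }
            )
    return pd.DataFrame(rows)
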