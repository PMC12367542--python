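"""Phenotype prediction workflow at desk scale.

Mirrors the BWAS prediction design whose accuracies the scaling law is fitted
to: functional-connectivity features feed a kernel (or linear) ridge
regression, evaluated under nested cross-validation where

* family members are never split across folds,
* the training set is subsampled to several sizes while the **test fold is
  held fixed across sizes**, so accuracies are comparable across N,
* the ridge parameter is selected by an inner cross-validation on the
  training set only,
* optionally, acquisition sites are regressed from the phenotype using
  coefficients estimated on the training set and applied to the test set.

Also provides the statistical companions used downstream: the Haufe
transform (feature-prediction covariances, the interpretable counterpart of
multivariate weights), the corrected resampled t-test for comparing
cross-validated accuracies, and Benjamini-Yekutieli FDR control.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.linear_model import Ridge

from .scaling import AccuracyGrid, fit_theoretical

__all__ = [
    "CVScheme",
    "PredictorSpec",
    "PredictionResult",
    "compute_fc",
    "vectorize_fc",
    "unvectorize_fc",
    "family_folds",
    "site_clusters",
    "nested_cv_accuracy",
    "haufe_transform",
    "corrected_resampled_ttest",
    "by_fdr",
    "randomized_run_fit_change",
    "RunOrderFitChange",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 4, 16))


@dataclass(frozen=True)
class PredictorSpec:
    """Ridge predictor settings: model family, kernel, and the inner-CV
    regularization grid."""

    model: str = "krr"  # krr | lrr
    kernel: str = "correlation"  # correlation | linear (krr only)
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    inner_folds: int = 10

    def __post_init__(self) -> None:
        if self.model not in ("krr", "lrr"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.kernel not in ("correlation", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if len(self.lambda_grid) == 0 or any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda_grid must be non-empty and strictly positive")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation design.

    ``kfold_family``: k folds that never split a family.  ``leave_p_siteclusters_out``:
    every combination of ``p`` site clusters forms a test set.  Within one
    repetition the test fold is identical across all ``subsample_sizes``.
    """

    kind: str = "kfold_family"
    n_folds: int = 10
    p: int = 3
    subsample_sizes: tuple[int, ...] = ()
    n_reps: int = 1
    seed: int = 0
    site_regression: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("kfold_family", "leave_p_siteclusters_out"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------


def compute_fc(
    time_series: np.ndarray, first_t_min: float, tr_seconds: float
) -> np.ndarray:
    """Pearson FC matrix from the first ``first_t_min`` minutes of data.

    ``time_series`` is parcels x frames; the first
    ``floor(first_t_min * 60 / tr_seconds)`` frames are used.  Unit diagonal,
    symmetric.
    """
    ts = np.asarray(time_series, float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("time_series must be parcels x frames with >= 2 parcels")
    frames = int(first_t_min * 60.0 / tr_seconds + 1e-9)
    if frames < 2:
        raise ValueError("first_t_min too short: fewer than 2 frames")
    if frames > ts.shape[1]:
        raise ValueError(
            f"not enough frames: need {frames}, have {ts.shape[1]}"
        )
    sub = ts[:, :frames]
    sd = sub.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant parcel series: parcels {bad.tolist()}")
    fc = np.corrcoef(sub)
    np.fill_diagonal(fc, 1.0)
    return fc


def vectorize_fc(fc: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangular entries in row-major order (p*(p-1)/2)."""
    fc = np.asarray(fc, float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("FC matrix must be square")
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("FC matrix must be symmetric")
    i, j = np.tril_indices(fc.shape[0], -1)
    return fc[i, j]


def unvectorize_fc(vec: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`."""
    vec = np.asarray(vec, float)
    p = int(round((1 + math.sqrt(1 + 8 * vec.size)) / 2))
    if p * (p - 1) // 2 != vec.size:
        raise ValueError(f"length {vec.size} is not p*(p-1)/2 for integer p")
    out = np.empty((p, p))
    i, j = np.tril_indices(p, -1)
    out[i, j] = vec
    out[j, i] = vec
    np.fill_diagonal(out, diag)
    return out


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------


def family_folds(
    family_ids: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Assign whole families to folds, largest families first, always into
    the currently smallest fold; family order is shuffled within equal sizes
    so repeated calls give different (but always family-respecting) splits."""
    family_ids = np.asarray(family_ids)
    fams: dict = {}
    for idx, f in enumerate(family_ids):
        fams.setdefault(f, []).append(idx)
    groups = list(fams.values())
    rng.shuffle(groups)
    groups.sort(key=len, reverse=True)  # stable: keeps shuffle within sizes
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for g in groups:
        smallest = min(range(n_folds), key=lambda k: len(folds[k]))
        folds[smallest].extend(g)
    return [np.array(sorted(f), dtype=int) for f in folds if len(f)]


def site_clusters(site_ids: np.ndarray, n_clusters: int) -> np.ndarray:
    """Greedy size-balancing bin-packing of sites into clusters; returns a
    cluster id per subject."""
    site_ids = np.asarray(site_ids)
    sites, counts = np.unique(site_ids, return_counts=True)
    order = np.argsort(counts)[::-1]
    load = np.zeros(n_clusters, int)
    assign: dict = {}
    for k in order:
        c = int(np.argmin(load))
        assign[sites[k]] = c
        load[c] += counts[k]
    return np.array([assign[s] for s in site_ids], dtype=int)


# ---------------------------------------------------------------------------
# ridge machinery
# ---------------------------------------------------------------------------


def _kernel(features: np.ndarray, kind: str) -> np.ndarray:
    if kind == "correlation":
        return np.corrcoef(features)
    return features @ features.T


def _krr_solve(K_tr, y_tr, K_te_tr, lam):
    """Dual ridge: alpha = (K + lam*I)^-1 (y - ybar); predict K_te alpha + ybar."""
    ybar = y_tr.mean()
    A = K_tr + lam * np.eye(len(y_tr))
    alpha = linalg.solve(A, y_tr - ybar, assume_a="pos")
    return K_te_tr @ alpha + ybar


def _krr_eig_path(K_tr, y_tr, K_te_tr, lams):
    """Predictions for a whole lambda grid from one eigendecomposition."""
    ybar = y_tr.mean()
    w, Q = linalg.eigh(K_tr)
    w = np.clip(w, 0.0, None)
    z = Q.T @ (y_tr - ybar)
    KQ = K_te_tr @ Q
    return [KQ @ (z / (w + lam)) + ybar for lam in lams]


def _select_lambda_krr(K, train_idx, y, lams, inner_folds, rng):
    """Inner k-fold CV on the training set; smallest-SSE lambda wins
    (ties go to the smaller lambda, the grid being ascending)."""
    perm = rng.permutation(train_idx)
    folds = np.array_split(perm, inner_folds)
    sse = np.zeros(len(lams))
    for f in folds:
        tr = np.setdiff1d(train_idx, f, assume_unique=False)
        preds = _krr_eig_path(
            K[np.ix_(tr, tr)], y[tr], K[np.ix_(f, tr)], lams
        )
        for k, p in enumerate(preds):
            sse[k] += np.sum((y[f] - p) ** 2)
    return lams[int(np.argmin(sse))]


def _select_lambda_lrr(X, train_idx, y, lams, inner_folds, rng):
    perm = rng.permutation(train_idx)
    folds = np.array_split(perm, inner_folds)
    sse = np.zeros(len(lams))
    for f in folds:
        tr = np.setdiff1d(train_idx, f, assume_unique=False)
        for k, lam in enumerate(lams):
            model = Ridge(alpha=lam).fit(X[tr], y[tr])
            sse[k] += np.sum((y[f] - model.predict(X[f])) ** 2)
    return lams[int(np.argmin(sse))]


def _fit_predict(features, K, train_idx, test_idx, y, spec, rng):
    lams = np.asarray(spec.lambda_grid, float)
    if spec.model == "krr":
        lam = _select_lambda_krr(K, train_idx, y, lams, spec.inner_folds, rng)
        return _krr_solve(
            K[np.ix_(train_idx, train_idx)],
            y[train_idx],
            K[np.ix_(test_idx, train_idx)],
            lam,
        )
    lam = _select_lambda_lrr(features, train_idx, y, lams, spec.inner_folds, rng)
    model = Ridge(alpha=lam).fit(features[train_idx], y[train_idx])
    return model.predict(features[test_idx])


def _site_residualize(y, site_ids, train_idx):
    """Regress site indicators out of the phenotype; coefficients estimated
    on the training subjects only, applied everywhere."""
    sites = np.unique(site_ids)
    Z = np.column_stack(
        [np.ones(len(y))] + [(site_ids == s).astype(float) for s in sites[1:]]
    )
    beta, *_ = np.linalg.lstsq(Z[train_idx], y[train_idx], rcond=None)
    return y - Z @ beta


def _pearson(a, b):
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _cod(y_test, y_pred, y_train_mean):
    denom = np.sum((y_test - y_train_mean) ** 2)
    if denom == 0:
        return float("nan")
    return float(1.0 - np.sum((y_test - y_pred) ** 2) / denom)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionResult:
    """Per-repetition accuracies plus averaging into an AccuracyGrid."""

    rep_accuracies: pd.DataFrame  # rep, fold, n_train, t_min, pearson, cod
    dataset_id: str = "synthetic"
    phenotype_id: str = "phenotype"

    def to_grid(self, metric: str = "pearson") -> AccuracyGrid:
        g = (
            self.rep_accuracies.groupby(["n_train", "t_min"])[metric]
            .agg(["mean", "count"])
            .reset_index()
        )
        cells = g.rename(columns={"mean": "accuracy", "count": "n_reps"})
        if metric == "pearson":
            cells["accuracy"] = cells["accuracy"].clip(-1, 1)
        return AccuracyGrid(
            dataset_id=self.dataset_id,
            phenotype_id=self.phenotype_id,
            metric=metric,
            cells=cells,
        )

    @staticmethod
    def concat(results: Sequence["PredictionResult"]) -> "PredictionResult":
        tables = []
        for off, r in enumerate(results):
            t = r.rep_accuracies.copy()
            t["rep"] = t["rep"] + off * 10_000  # keep reps distinct
            tables.append(t)
        first = results[0]
        return PredictionResult(
            pd.concat(tables, ignore_index=True),
            dataset_id=first.dataset_id,
            phenotype_id=first.phenotype_id,
        )


def _outer_splits(scheme, n, family_ids, site_cluster_ids, rng):
    """Yield test-index arrays for one repetition."""
    if scheme.kind == "kfold_family":
        fam = family_ids if family_ids is not None else np.arange(n)
        return family_folds(fam, scheme.n_folds, rng)
    if site_cluster_ids is None:
        raise ValueError("leave_p_siteclusters_out requires site cluster labels")
    clusters = np.unique(site_cluster_ids)
    splits = []
    for combo in itertools.combinations(clusters, scheme.p):
        splits.append(np.flatnonzero(np.isin(site_cluster_ids, combo)))
    return splits


def nested_cv_accuracy(
    features_by_t: Mapping[float, np.ndarray],
    phenotype: np.ndarray,
    scheme: CVScheme,
    spec: PredictorSpec,
    family_ids: np.ndarray | None = None,
    site_ids: np.ndarray | None = None,
    site_cluster_ids: np.ndarray | None = None,
    dataset_id: str = "synthetic",
    phenotype_id: str = "phenotype",
) -> PredictionResult:
    """Accuracy for every (training size, scan time) cell.

    ``features_by_t`` maps scan time (minutes) to a subjects x edges feature
    matrix.  Within each repetition and outer fold, the test set is fixed and
    the training pool is subsampled to each requested size, so cells differ
    only in the amount of training data.  Deterministic given ``scheme.seed``.
    """
    y_raw = np.asarray(phenotype, float)
    n = len(y_raw)
    for t, f in features_by_t.items():
        if f.shape[0] != n:
            raise ValueError(f"features at t={t} have {f.shape[0]} rows, expected {n}")
    if scheme.site_regression and site_ids is None:
        raise ValueError("site_regression requested without site labels")

    kernels = {
        t: _kernel(f, spec.kernel) if spec.model == "krr" else None
        for t, f in features_by_t.items()
    }
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for rep in range(scheme.n_reps):
        splits = _outer_splits(scheme, n, family_ids, site_cluster_ids, rng)
        for fold_id, test_idx in enumerate(splits):
            pool = np.setdiff1d(np.arange(n), test_idx)
            sizes = scheme.subsample_sizes or (len(pool),)
            if max(sizes) > len(pool):
                raise ValueError(
                    f"subsample size {max(sizes)} exceeds training pool {len(pool)}"
                )
            order = rng.permutation(pool)
            for size in sizes:
                train_idx = np.sort(order[:size])
                y = (
                    _site_residualize(y_raw, site_ids, train_idx)
                    if scheme.site_regression
                    else y_raw
                )
                for t, feats in features_by_t.items():
                    # child stream per cell: accuracies for a given size are
                    # invariant to which other sizes were requested
                    cell_rng = np.random.default_rng(
                        [scheme.seed & 0x7FFFFFFF, 7, rep, fold_id, size,
                         int(round(float(t) * 1000))]
                    )
                    pred = _fit_predict(
                        feats, kernels[t], train_idx, test_idx, y, spec, cell_rng
                    )
                    rows.append(
                        {
                            "rep": rep,
                            "fold": fold_id,
                            "n_train": size,
                            "t_min": t,
                            "pearson": _pearson(y[test_idx], pred),
                            "cod": _cod(y[test_idx], pred, y[train_idx].mean()),
                        }
                    )
    return PredictionResult(
        pd.DataFrame(rows), dataset_id=dataset_id, phenotype_id=phenotype_id
    )


# ---------------------------------------------------------------------------
# statistical companions
# ---------------------------------------------------------------------------


def haufe_transform(train_features: np.ndarray, predictions: np.ndarray) -> np.ndarray:
    """Activation pattern: per-feature sample covariance with the predicted
    phenotype across training subjects.  Unlike raw weights, activations are
    interpretable as encoding directions."""
    X = np.asarray(train_features, float)
    yhat = np.asarray(predictions, float)
    if X.shape[0] != yhat.shape[0] or X.shape[0] < 2:
        raise ValueError("need >= 2 training subjects with matching predictions")
    if yhat.std() == 0:
        raise ValueError("predictions have zero variance")
    Xc = X - X.mean(axis=0)
    yc = yhat - yhat.mean()
    return Xc.T @ yc / (len(yhat) - 1)


def corrected_resampled_ttest(
    paired_diffs: Sequence[float], n_train: int, n_test: int
) -> tuple[float, float]:
    """Paired t-test with the variance correction for overlapping CV
    training sets: ``t = mean(d) / sqrt((1/J + n_test/n_train) * var(d))``
    with ``J`` differences and ``J - 1`` degrees of freedom."""
    d = np.asarray(paired_diffs, float)
    j = d.size
    if j < 2:
        raise ValueError("need at least 2 paired differences")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero variance with nonzero mean: t undefined")
    var = float(d.var(ddof=1))
    t = d.mean() / math.sqrt((1.0 / j + n_test / n_train) * var)
    p = 2.0 * stats.t.sf(abs(t), df=j - 1)
    return float(t), float(p)


def by_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR control (valid under arbitrary
    dependence).  Rejects all sorted hypotheses up to the largest ``i`` with
    ``p(i) <= i * q / (m * c(m))`` where ``c(m) = sum_{k<=m} 1/k``."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    if m == 0:
        return np.zeros(0, bool)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    thresh = np.arange(1, m + 1) * q / (m * c_m)
    passing = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(m, bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


# ---------------------------------------------------------------------------
# non-stationarity probe
# ---------------------------------------------------------------------------


class RunOrderFitChange(NamedTuple):
    r2_original: float
    r2_randomized: float
    grid_original: AccuracyGrid
    grid_randomized: AccuracyGrid


def randomized_run_fit_change(
    cohort,
    scheme: CVScheme,
    spec: PredictorSpec,
    t_list: Sequence[float],
    n_orders: int | None = None,
    seed: int = 0,
) -> RunOrderFitChange:
    """Theoretical-model fit before vs after per-subject run-order
    randomization.

    Under run-level non-stationarity (drift), the original run order ties
    specific drift patterns to specific scan times, which the 1/NT noise
    model cannot absorb; independently permuting each subject's runs (freshly
    for every CV repetition) restores exchangeability, so the fit should
    improve.  On a stationary cohort the change is pure Monte Carlo noise.
    """
    from .cohort import observe_fc, randomize_run_order  # local: avoid cycle

    if cohort.config.n_runs < 2:
        raise ValueError("run-order analysis requires >= 2 runs")
    reps = n_orders if n_orders is not None else scheme.n_reps

    feats_orig = {t: observe_fc(cohort, t) for t in t_list}
    res_orig = nested_cv_accuracy(
        feats_orig,
        cohort.phenotype,
        CVScheme(**{**scheme.__dict__, "n_reps": reps}),
        spec,
        family_ids=cohort.family_id,
    )
    rand_parts = []
    for j in range(reps):
        shuffled = randomize_run_order(cohort, seed + j)
        feats = {t: observe_fc(shuffled, t) for t in t_list}
        rand_parts.append(
            nested_cv_accuracy(
                feats,
                cohort.phenotype,
                CVScheme(**{**scheme.__dict__, "n_reps": 1, "seed": scheme.seed + j}),
                spec,
                family_ids=cohort.family_id,
            )
        )
    res_rand = PredictionResult.concat(rand_parts)
    grid_o = res_orig.to_grid("pearson")
    grid_r = res_rand.to_grid("pearson")
    fit_o = fit_theoretical(grid_o)
    fit_r = fit_theoretical(grid_r)
    return RunOrderFitChange(fit_o.r2, fit_r.r2, grid_o, grid_r)
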