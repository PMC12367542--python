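"""Synthetic cohorts with the statistical structure the scaling law assumes.

The theoretical accuracy law rests on a small set of generative assumptions:
each subject has a *true* functional-connectivity (FC) profile; the observed
FC estimated from ``T`` minutes of scan is the true profile plus noise whose
variance shrinks like ``1/T``; and the phenotype is a linear function of the
true profile plus independent noise.  This module generates cohorts with
exactly that structure — plus optional sibling blocks, acquisition sites,
multi-run sessions and injectable run-level non-stationarity — so that the
prediction, reliability and cost modules can be validated end-to-end without
any restricted imaging data.

Two observation modes are provided:

* ``direct_noise`` (default, fast): observed edges are the true edges plus
  Gaussian noise with per-edge variance ``obs_noise_sd**2 / t``; runs are
  materialized as independent run-level estimates so that run-order
  randomization is meaningful.
* ``time_series``: stationary multivariate Gaussian parcel series are
  generated whose population correlations encode the true edges, and FC is
  the empirical Pearson correlation of the first ``T`` minutes.  This mode
  exists to validate the 1/T variance assumption itself, including the
  mapping from time-course noise to edgewise FC noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "CohortConfigError",
    "generate_cohort",
    "observe_fc",
    "inject_nonstationarity",
    "randomize_run_order",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration; message lists the offending fields."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a synthetic cohort.

    ``obs_noise_sd`` is the edgewise observation-noise s.d. per unit minute:
    observing ``t`` minutes yields noise variance ``obs_noise_sd**2 / t``.
    ``n_runs * run_length_min`` bounds the usable scan time.  The defaults are
    desk scale: 50 parcels (1,225 edges), 2,000 subjects, 4 runs of 5 min,
    TR 0.8 s — small enough for minutes-scale simulation while preserving the
    regime the law describes.
    """

    n_subjects: int = 2000
    n_parcels: int = 50
    edge_signal_sd: float = 0.1
    obs_noise_sd: float = 0.2
    phenotype_weight_density: float = 0.2
    phenotype_noise_sd: float = 1.0
    n_runs: int = 4
    run_length_min: float = 5.0
    tr_seconds: float = 0.8
    family_block_size: int = 1
    n_sites: int = 1
    nonstationarity_drift_sd: float = 0.0
    mode: str = "direct_noise"
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if self.n_subjects < 2:
            errs.append("n_subjects must be >= 2")
        if self.n_parcels < 2:
            errs.append("n_parcels must be >= 2")
        for name in ("edge_signal_sd", "obs_noise_sd", "phenotype_noise_sd",
                     "nonstationarity_drift_sd"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        if not (0 < self.phenotype_weight_density <= 1):
            errs.append("phenotype_weight_density must lie in (0, 1]")
        if self.n_runs < 1:
            errs.append("n_runs must be >= 1")
        if self.run_length_min <= 0:
            errs.append("run_length_min must be > 0")
        if self.tr_seconds <= 0:
            errs.append("tr_seconds must be > 0")
        if self.family_block_size < 1:
            errs.append("family_block_size must be >= 1")
        if self.n_sites < 1:
            errs.append("n_sites must be >= 1")
        if self.mode not in ("direct_noise", "time_series"):
            errs.append("mode must be 'direct_noise' or 'time_series'")
        return errs

    @property
    def n_edges(self) -> int:
        return self.n_parcels * (self.n_parcels - 1) // 2

    @property
    def max_usable_t_min(self) -> float:
        return self.n_runs * self.run_length_min

    @property
    def frames_per_minute(self) -> float:
        return 60.0 / self.tr_seconds


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort.  Everything is reproducible from ``config.seed``."""

    config: CohortConfig
    true_features: np.ndarray  # (n_subjects, n_edges)
    phenotype: np.ndarray  # (n_subjects,)
    true_weights: np.ndarray  # (n_edges,)
    family_id: np.ndarray  # (n_subjects,)
    site_id: np.ndarray  # (n_subjects,)
    run_order: np.ndarray  # (n_subjects, n_runs); original order = arange
    drift_offsets: np.ndarray | None = None  # (n_runs, n_edges)
    drift_scale: np.ndarray | None = None  # (n_subjects,)

    @property
    def n_subjects(self) -> int:
        return self.config.n_subjects

    @property
    def has_drift(self) -> bool:
        return self.drift_offsets is not None

    def observe_fc(self, t_min: float) -> np.ndarray:
        return observe_fc(self, t_min)


# stream tags keep the independent noise sources of one seed apart
_TAG_TRUE, _TAG_WEIGHTS, _TAG_PHENO_NOISE = 1, 2, 3
_TAG_RUN_NOISE, _TAG_PARTIAL, _TAG_DRIFT, _TAG_SCALE = 11, 12, 13, 14
_TAG_SERIES, _TAG_BASECORR, _TAG_PERM = 21, 22, 23


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *map(int, tags)])


def _vec_lower(mat: np.ndarray) -> np.ndarray:
    p = mat.shape[-1]
    i, j = np.tril_indices(p, -1)
    return mat[..., i, j]


def _unvec_lower(vec: np.ndarray, p: int, diag: float = 1.0) -> np.ndarray:
    mat = np.full((p, p), 0.0)
    i, j = np.tril_indices(p, -1)
    mat[i, j] = vec
    mat[j, i] = vec
    np.fill_diagonal(mat, diag)
    return mat


def _nearest_corr(mat: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and renormalize the diagonal."""
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    w = np.clip(w, 1e-6, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort: true edges, sparse linear phenotype, families, sites.

    True edge values are i.i.d. N(0, ``edge_signal_sd**2``) (in time-series
    mode they are deviations around a shared base correlation matrix, clipped
    to a valid correlation range).  The weight vector is sparse with the
    configured density and rescaled so the noise-free linear predictor has
    unit sample variance; the phenotype adds N(0, ``phenotype_noise_sd**2``),
    so the population accuracy ceiling is
    ``1 / sqrt(1 + phenotype_noise_sd**2)``.
    """
    errs = config.validate()
    if errs:
        raise CohortConfigError("invalid cohort config: " + "; ".join(errs))
    n, e = config.n_subjects, config.n_edges
    true = _rng(config.seed, _TAG_TRUE).normal(0.0, config.edge_signal_sd, (n, e))
    if config.mode == "time_series":
        # keep base + deviation inside a comfortably valid correlation range
        np.clip(true, -3 * config.edge_signal_sd, 3 * config.edge_signal_sd, out=true)

    rng_w = _rng(config.seed, _TAG_WEIGHTS)
    n_active = max(1, int(round(config.phenotype_weight_density * e)))
    active = rng_w.choice(e, size=n_active, replace=False)
    w = np.zeros(e)
    w[active] = rng_w.normal(0.0, 1.0, n_active)
    linear = true @ w
    scale = float(linear.std())
    if scale == 0:  # degenerate draw (e.g. edge_signal_sd = 0)
        scale = 1.0
    w = w / scale
    noise = _rng(config.seed, _TAG_PHENO_NOISE).normal(
        0.0, config.phenotype_noise_sd, n
    )
    phenotype = true @ w + noise

    family_id = np.arange(n) // config.family_block_size
    site_id = np.arange(n) % config.n_sites
    run_order = np.tile(np.arange(config.n_runs), (n, 1))

    cohort = SyntheticCohort(
        config=config,
        true_features=true,
        phenotype=phenotype,
        true_weights=w,
        family_id=family_id,
        site_id=site_id,
        run_order=run_order,
    )
    if config.nonstationarity_drift_sd > 0:
        cohort = inject_nonstationarity(
            cohort, config.nonstationarity_drift_sd, config.seed
        )
    return cohort


def inject_nonstationarity(
    cohort: SyntheticCohort, drift_sd: float, seed: int
) -> SyntheticCohort:
    """Add run-indexed shared offsets (scaled per subject) to the runs.

    Each run ``r`` receives an offset vector ``o_r ~ N(0, drift_sd**2)``
    over edges, shared across subjects and applied with a per-subject scale.
    The scale is the subject's standardized phenotype, so the offsets carry a
    run-specific, phenotype-correlated FC component: the FC-phenotype
    relationship itself changes across runs (state non-stationarity), which
    is exactly what the scaling law's stationarity assumption rules out.
    Under the original run order this injects extra predictive signal whose
    strength decays with scan time in a way the 1/NT noise term cannot
    express; per-subject run randomization makes the runs exchangeable
    again.  Early-run FC also differs systematically from late-run FC.
    ``drift_sd = 0`` is the identity.
    """
    if drift_sd == 0:
        return cohort
    cfg = cohort.config
    if cfg.n_runs < 2:
        raise ValueError("non-stationarity requires at least 2 runs")
    offsets = _rng(seed, _TAG_DRIFT).normal(0.0, drift_sd, (cfg.n_runs, cfg.n_edges))
    pheno_sd = cohort.phenotype.std()
    scale = (cohort.phenotype - cohort.phenotype.mean()) / (
        pheno_sd if pheno_sd > 0 else 1.0
    )
    return replace(
        cohort,
        config=replace(cfg, nonstationarity_drift_sd=drift_sd),
        drift_offsets=offsets,
        drift_scale=scale,
    )


def randomize_run_order(cohort: SyntheticCohort, seed: int) -> SyntheticCohort:
    """Independently permute each subject's run order (seed-deterministic)."""
    cfg = cohort.config
    if cfg.n_runs == 1:
        return cohort
    rng = _rng(seed, _TAG_PERM)
    order = rng.permuted(
        np.tile(np.arange(cfg.n_runs), (cfg.n_subjects, 1)), axis=1
    )
    return replace(cohort, run_order=order)


# ---------------------------------------------------------------------------
# observation
# ---------------------------------------------------------------------------


def _run_noise_stack(cohort: SyntheticCohort) -> np.ndarray:
    """Per-run full-run estimate noise, keyed by *original* run index so that
    run-order permutations move the noise with the run."""
    cfg = cohort.config
    sd = cfg.obs_noise_sd / math.sqrt(cfg.run_length_min)
    return np.stack(
        [
            _rng(cfg.seed, _TAG_RUN_NOISE, r).normal(
                0.0, sd, (cfg.n_subjects, cfg.n_edges)
            )
            for r in range(cfg.n_runs)
        ]
    )


def observe_fc(cohort: SyntheticCohort, t_min: float) -> np.ndarray:
    """Observed FC features after ``t_min`` minutes of scanning.

    direct_noise mode: the minute-weighted mean of run-level estimates (true
    edges + drift + run noise), using complete runs plus a fraction of the
    next; the resulting edge noise variance is exactly
    ``obs_noise_sd**2 / t_min`` in the stationary case.

    time_series mode: empirical Pearson FC over the first ``t_min`` minutes
    of concatenated per-run stationary Gaussian series.
    """
    cfg = cohort.config
    if t_min <= 0:
        raise ValueError("t_min must be positive")
    if t_min > cfg.max_usable_t_min + 1e-9:
        raise ValueError(
            f"t_min={t_min} exceeds available data "
            f"({cfg.n_runs} runs x {cfg.run_length_min} min)"
        )
    if cfg.mode == "time_series":
        return _observe_fc_time_series(cohort, t_min)

    L = cfg.run_length_min
    n_full = int((t_min + 1e-9) // L)
    frac = t_min - n_full * L
    if frac < 1e-9:
        frac = 0.0

    noise = _run_noise_stack(cohort)  # (R, n, E)
    subj = np.arange(cfg.n_subjects)
    acc = np.zeros((cfg.n_subjects, cfg.n_edges))
    for slot in range(n_full):
        r = cohort.run_order[:, slot]
        est = cohort.true_features + noise[r, subj]
        if cohort.has_drift:
            est = est + cohort.drift_scale[:, None] * cohort.drift_offsets[r]
        acc += L * est
    if frac > 0:
        r = cohort.run_order[:, n_full]
        # fraction of a run carries extra noise on top of the full-run
        # estimate so that its variance is obs_noise_sd**2 / frac
        extra_sd = cfg.obs_noise_sd * math.sqrt(1.0 / frac - 1.0 / L)
        t_key = int(round(t_min * 1000))
        extra = np.stack(
            [
                _rng(cfg.seed, _TAG_PARTIAL, rr, t_key).normal(
                    0.0, extra_sd, (cfg.n_subjects, cfg.n_edges)
                )
                for rr in range(cfg.n_runs)
            ]
        )
        est = cohort.true_features + noise[r, subj] + extra[r, subj]
        if cohort.has_drift:
            est = est + cohort.drift_scale[:, None] * cohort.drift_offsets[r]
        acc += frac * est
    return acc / t_min


def _base_correlation(cfg: CohortConfig) -> np.ndarray:
    """Shared base correlation matrix from a 3-factor loading model."""
    rng = _rng(cfg.seed, _TAG_BASECORR)
    load = rng.normal(0.0, 1.0, (cfg.n_parcels, 3))
    cov = load @ load.T + 2.0 * np.eye(cfg.n_parcels)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _observe_fc_time_series(cohort: SyntheticCohort, t_min: float) -> np.ndarray:
    cfg = cohort.config
    base = _base_correlation(cfg)
    frames_per_run = int(round(cfg.run_length_min * cfg.frames_per_minute))
    n_frames = int((t_min * cfg.frames_per_minute) + 1e-9)
    if n_frames < 2:
        raise ValueError("t_min too short: fewer than 2 frames")
    out = np.empty((cfg.n_subjects, cfg.n_edges))
    for i in range(cfg.n_subjects):
        segments = []
        remaining = n_frames
        for slot in range(cfg.n_runs):
            if remaining <= 0:
                break
            r = int(cohort.run_order[i, slot])
            dev = cohort.true_features[i]
            if cohort.has_drift:
                dev = dev + cohort.drift_scale[i] * cohort.drift_offsets[r]
            target = _nearest_corr(_unvec_lower(dev, cfg.n_parcels, diag=0.0) + base)
            chol = np.linalg.cholesky(target)
            white = _rng(cfg.seed, _TAG_SERIES, i, r).normal(
                0.0, 1.0, (cfg.n_parcels, frames_per_run)
            )
            take = min(frames_per_run, remaining)
            segments.append((chol @ white)[:, :take])
            remaining -= take
        series = np.concatenate(segments, axis=1)
        out[i] = _vec_lower(np.corrcoef(series))
    return out
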