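"""Reading and writing accuracy tables, fit tables and run manifests.

Accuracy tables are long-form delimited text (comma or tab, auto-detected)
with a header: ``dataset, phenotype, metric, n_train, t_min, accuracy``
(``n_reps`` optional).  One :class:`~bwasplan.scaling.AccuracyGrid` is built
per (dataset, phenotype, metric) group.  ``adapt_table`` maps externally
released table layouts with differing column names onto this schema.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scaling import AccuracyGrid, LogarithmicParams, TheoreticalParams

__all__ = [
    "SchemaError",
    "read_accuracy_table",
    "write_accuracy_table",
    "adapt_table",
    "fits_to_frame",
    "frame_to_fits",
    "config_hash",
    "write_manifest",
    "read_manifest",
]

REQUIRED_COLUMNS = ("dataset", "phenotype", "metric", "n_train", "t_min", "accuracy")
NUMERIC_COLUMNS = ("n_train", "t_min", "accuracy")


class SchemaError(ValueError):
    """Table does not match the accuracy-table schema."""


def read_accuracy_table(path: str | Path) -> list[AccuracyGrid]:
    """Parse a long-form accuracy table into one grid per phenotype.

    Raises :class:`SchemaError` listing missing columns, or a row-level error
    with the 1-based file line number for non-numeric cells; duplicate
    (n_train, t_min) cells within a grid are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for col in NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            line = int(bad[0]) + 2  # header + 1-based
            raise SchemaError(
                f"non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = coerced
    if "n_reps" not in df.columns:
        df["n_reps"] = 1
    grids = []
    for (dataset, phenotype, metric), g in df.groupby(
        ["dataset", "phenotype", "metric"], sort=True
    ):
        grids.append(
            AccuracyGrid(
                dataset_id=str(dataset),
                phenotype_id=str(phenotype),
                metric=str(metric),
                cells=g[["n_train", "t_min", "accuracy", "n_reps"]],
            )
        )
    return grids


def write_accuracy_table(
    grids: Iterable[AccuracyGrid], path: str | Path, sep: str = ","
) -> None:
    frames = []
    for g in grids:
        c = g.cells.copy()
        c.insert(0, "metric", g.metric)
        c.insert(0, "phenotype", g.phenotype_id)
        c.insert(0, "dataset", g.dataset_id)
        frames.append(c)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


_COLUMN_ALIASES = {
    "dataset": ("dataset", "dataset_id", "study"),
    "phenotype": ("phenotype", "phenotype_id", "pheno", "behavior", "measure"),
    "metric": ("metric", "accuracy_metric", "score"),
    "n_train": ("n_train", "n", "sample_size", "train_size", "num_train"),
    "t_min": ("t_min", "t", "scan_time", "time", "scan_time_min"),
    "accuracy": ("accuracy", "acc", "value", "corr", "prediction_accuracy"),
    "n_reps": ("n_reps", "reps", "n_rep"),
}


def adapt_table(
    table: pd.DataFrame | str | Path,
    dataset_id: str | None = None,
    metric: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[AccuracyGrid]:
    """Import adapter for released accuracy tables with foreign column names.

    Columns are matched case-insensitively against common aliases (override
    with ``column_map``); ``dataset_id`` and ``metric`` fill in columns the
    source table lacks.
    """
    df = (
        pd.read_csv(table, sep=None, engine="python")
        if not isinstance(table, pd.DataFrame)
        else table.copy()
    )
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for target, aliases in _COLUMN_ALIASES.items():
        if column_map and target in column_map:
            rename[column_map[target]] = target
            continue
        for a in aliases:
            if a in lower:
                rename[lower[a]] = target
                break
    df = df.rename(columns=rename)
    if "dataset" not in df.columns:
        if dataset_id is None:
            raise SchemaError("no dataset column found and no dataset_id given")
        df["dataset"] = dataset_id
    if "metric" not in df.columns:
        if metric is None:
            raise SchemaError("no metric column found and no metric given")
        df["metric"] = metric
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"could not map columns for: {missing}")
    if "n_reps" not in df.columns:
        df["n_reps"] = 1
    grids = []
    for (dataset, phenotype, metric_), g in df.groupby(
        ["dataset", "phenotype", "metric"], sort=True
    ):
        grids.append(
            AccuracyGrid(
                dataset_id=str(dataset),
                phenotype_id=str(phenotype),
                metric=str(metric_),
                cells=g[["n_train", "t_min", "accuracy", "n_reps"]],
            )
        )
    return grids


# ---------------------------------------------------------------------------
# fitted-parameter tables
# ---------------------------------------------------------------------------


def fits_to_frame(
    fits: Mapping[tuple[str, str], TheoreticalParams | LogarithmicParams]
) -> pd.DataFrame:
    rows = []
    for (dataset, phenotype), p in fits.items():
        row = {"dataset": dataset, "phenotype": phenotype}
        if isinstance(p, TheoreticalParams):
            row.update(model="theoretical", k0=p.k0, k1=p.k1, k2=p.k2, r2=p.r2)
        else:
            row.update(
                model="logarithmic",
                slope_z=p.slope_z,
                intercept_k=p.intercept_k,
                r2=p.r2,
                t_cap_min=p.t_cap_min,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> dict[tuple[str, str], TheoreticalParams]:
    """Rebuild theoretical fits from a fit table (theoretical rows only)."""
    out = {}
    for r in df.itertuples():
        if getattr(r, "model", "theoretical") != "theoretical":
            continue
        out[(str(r.dataset), str(r.phenotype))] = TheoreticalParams(
            k0=float(r.k0), k1=float(r.k1), k2=float(r.k2), r2=float(r.r2)
        )
    return out


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: Mapping,
    seed: int | None = None,
    parent_hash: str | None = None,
) -> dict:
    """Write ``manifest.json`` echoing the configuration, package version,
    seed and a config hash; ``parent_hash`` links pipeline stages."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        ver = _pkg_version("bwasplan")
    except Exception:  # not installed (e.g. source tree on sys.path)
        ver = "unknown"
    manifest = {
        "command": command,
        "package_version": ver,
        "seed": seed,
        "config": dict(config),
        "config_hash": config_hash(config),
        "parent_hash": parent_hash,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())
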