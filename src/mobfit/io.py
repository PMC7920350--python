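"""Readers and writers for the package's plain-text artifact formats.

Everything is long-format CSV plus a JSON metadata sidecar: diff-friendly
and scale-tolerant.  A SpatialSystem persists as ``cells.csv`` +
``units.csv`` + ``system.json``; a FlowDataset as ``flows.csv`` +
``flows.json``; chains as one CSV with iteration/chain/parameter columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import Chain, ConvergenceResult, PosteriorChains
from .likelihood import FlowDataset
from .spatial import SpatialSystem


def read_raster(path) -> pd.DataFrame:
    """Read a fine-raster CSV/TSV with columns x, y, population[, admin_id]."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"x", "y", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"raster {path} is missing columns {sorted(missing)}")
    return df


def write_raster(raster: pd.DataFrame, path) -> None:
    raster.to_csv(path, index=False)


def write_system(system: SpatialSystem, outdir, merge_map: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    system.cells_frame().to_csv(outdir / "cells.csv", index=False)
    system.units_frame().to_csv(outdir / "units.csv", index=False)
    meta = {
        "scale": system.scale,
        "spacing": system.spacing,
        "n_cells": int(system.n_cells),
        "n_units": int(system.n_units),
        "merge_map": {str(k): str(v) for k, v in (merge_map or {}).items()},
    }
    (outdir / "system.json").write_text(json.dumps(meta, indent=2))


def read_system(outdir) -> SpatialSystem:
    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "cells.csv")
    meta = json.loads((outdir / "system.json").read_text())
    return SpatialSystem(
        scale=meta["scale"],
        x=cells["x"].to_numpy(),
        y=cells["y"].to_numpy(),
        population=cells["population"].to_numpy(),
        admin_id=cells["admin_id"].to_numpy(),
        spacing=meta.get("spacing"),
    )


def write_flow_dataset(data: FlowDataset, path) -> None:
    """Write flows.csv and a flows.json sidecar next to it."""
    path = Path(path)
    data.flows.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"directional": data.directional, "has_diagonal": data.has_diagonal},
        indent=2))


def read_flow_dataset(path) -> FlowDataset:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FlowDataset(df, directional=meta["directional"],
                       has_diagonal=meta["has_diagonal"])


def write_chains(posterior: PosteriorChains, path) -> None:
    posterior.to_frame().to_csv(path, index=False)


def read_chains(path, convergence: ConvergenceResult | None = None) -> PosteriorChains:
    df = pd.read_csv(path)
    param_names = tuple(c for c in df.columns
                        if c not in ("chain", "iteration", "loglik"))
    chains = []
    for ci, sub in df.groupby("chain"):
        sub = sub.sort_values("iteration")
        chains.append(Chain(
            draws=sub[list(param_names)].to_numpy(),
            loglik=sub["loglik"].to_numpy(),
            accept_rate=float("nan"),
            proposal_scales=np.full(len(param_names), np.nan),
        ))
    return PosteriorChains(chains=chains, param_names=param_names,
                           convergence=convergence)


def write_json(obj: dict, path) -> None:
    def _default(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        raise TypeError(f"not JSON serialisable: {type(v)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
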