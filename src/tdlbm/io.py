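"""Readers and writers: long-format curve tables, labels, configs, results.

Curve matrices travel as long-format delimited text with columns
``row_id,col_id,time,value`` (missing observations are simply omitted);
cluster labels as ``unit_id,axis,cluster`` sidecars; run configuration as a
single YAML document mirroring the RunConfig field names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import BlockPartition, CurveMatrix

LONG_COLUMNS = ["row_id", "col_id", "time", "value"]


class FormatError(ValueError):
    """Malformed input file."""


def read_long_csv(path, delimiter: str = ",", missing: str = "NA"
                  ) -> CurveMatrix:
    """Read a long-format curve table into a CurveMatrix.

    Row/column orderings follow first appearance in the file.  Entirely
    absent (row, col, time) combinations become missing values.  Each row
    unit's time grid is the sorted union of its observed times.
    """
    df = pd.read_csv(path, sep=delimiter, na_values=[missing],
                     keep_default_na=False, float_precision="round_trip",
                     dtype={"row_id": str, "col_id": str})
    if list(df.columns[:4]) != LONG_COLUMNS:
        raise FormatError(
            f"expected header {LONG_COLUMNS}, got {list(df.columns)}")
    try:
        df["time"] = df["time"].astype(float)
        df["value"] = df["value"].astype(float)
    except ValueError as e:
        raise FormatError(f"non-numeric time/value entry: {e}") from e
    dup = df.duplicated(subset=["row_id", "col_id", "time"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(f"duplicate (row_id, col_id, time) at line {line}")
    row_ids = list(dict.fromkeys(df["row_id"]))
    col_ids = list(dict.fromkeys(df["col_id"]))
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: j for j, c in enumerate(col_ids)}
    # per-row time grids (sorted unique times of that row unit)
    grids = {r: np.sort(df.loc[df["row_id"] == r, "time"].unique())
             for r in row_ids}
    T = max((g.size for g in grids.values()), default=0)
    n, d = len(row_ids), len(col_ids)
    values = np.full((n, d, T), np.nan)
    times = np.empty((n, T))
    for r, g in grids.items():
        i = ri[r]
        tt = g
        if tt.size < T:  # pad with extrapolated increasing times
            step = tt[-1] - tt[-2] if tt.size > 1 else 1.0
            extra = tt[-1] + step * np.arange(1, T - tt.size + 1)
            tt = np.concatenate([tt, extra])
        times[i] = tt
    ti = {(r, t): np.searchsorted(grids[r], t) for r in row_ids
          for t in grids[r]}
    for rec in df.itertuples(index=False):
        values[ri[rec.row_id], ci[rec.col_id], ti[(rec.row_id, rec.time)]] \
            = rec.value
    return CurveMatrix(values, times, row_ids=row_ids, col_ids=col_ids)


def write_long_csv(data: CurveMatrix, path, delimiter: str = ",") -> None:
    """Write a CurveMatrix in long format; missing entries are omitted.

    Full-precision floats (repr) so that a read-back round-trips exactly,
    and output is byte-deterministic for identical inputs.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(delimiter.join(LONG_COLUMNS) + "\n")
        for i, r in enumerate(data.row_ids):
            for j, c in enumerate(data.col_ids):
                for t_idx in range(data.T):
                    v = data.values[i, j, t_idx]
                    if np.isnan(v):
                        continue
                    fh.write(delimiter.join(
                        [r, c, repr(float(data.times[i, t_idx])),
                         repr(float(v))]) + "\n")


def write_labels(partition: BlockPartition, path, row_ids=None,
                 col_ids=None) -> None:
    """Label sidecar: unit_id, axis in {row, col}, cluster (1-based)."""
    row_ids = row_ids or [f"r{i}" for i in range(partition.n)]
    col_ids = col_ids or [f"c{j}" for j in range(partition.d)]
    with Path(path).open("w", newline="") as fh:
        fh.write("unit_id,axis,cluster\n")
        for rid, lab in zip(row_ids, partition.z):
            fh.write(f"{rid},row,{lab + 1}\n")
        for cid, lab in zip(col_ids, partition.w):
            fh.write(f"{cid},col,{lab + 1}\n")


def read_labels(path) -> BlockPartition:
    df = pd.read_csv(path, dtype={"unit_id": str})
    rows = df[df["axis"] == "row"]
    cols = df[df["axis"] == "col"]
    return BlockPartition(rows["cluster"].to_numpy() - 1,
                          cols["cluster"].to_numpy() - 1)


# ---------------------------------------------------------------------------
# configs and results
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def theta_to_dict(theta) -> dict:
    return {
        "pi": theta.pi.tolist(),
        "rho": theta.rho.tolist(),
        "blocks": [[{
            "beta": t.beta.tolist(),
            "mu_alpha": t.mu_alpha.tolist(),
            "sigma_alpha": t.sigma_alpha.tolist(),
            "sigma_eps": float(t.sigma_eps),
            "config": t.config.name,
        } for t in row] for row in theta.theta],
    }


def save_fit_result(result, out_dir, row_ids=None, col_ids=None) -> None:
    """FitResult -> labels.csv + theta.yaml + llc_trace.csv in out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labels(result.partition, out / "labels.csv", row_ids, col_ids)
    save_yaml({"theta": theta_to_dict(result.theta_hat),
               "llc_hat": float(result.llc_hat),
               "converged": bool(result.converged),
               "n_iterations_run": int(result.n_iterations_run),
               "K": result.K, "L": result.L}, out / "theta.yaml")
    pd.DataFrame({"iteration": np.arange(1, result.llc_trace.size + 1),
                  "llc": result.llc_trace}).to_csv(
        out / "llc_trace.csv", index=False)


def write_manifest(out_dir, seed, config: dict) -> None:
    """Machine-readable run manifest: seed, config hash, version."""
    from . import __version__
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "version": __version__,
        "config": config,
    }
    with (Path(out_dir) / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
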