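"""Delimited-text I/O for rates, histograms, dwells, trajectories, reports.

All columns carry SI-style unit suffixes (s, nm, pN, 1/s, µM implied by
context) to prevent unit drift; every writer embeds a config hash
comment so an artifact names the parameters that generated it.
Round-trips are stable: write-then-read yields an equal object.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gillespie import DwellSample, Trajectory
from .histogram import Histogram, HistogramError
from .rates import Condition, RateConstants

__all__ = [
    "config_hash", "read_rates_table", "write_rates_table",
    "read_histogram", "write_histogram", "read_dwells", "write_dwells",
    "write_trajectory", "read_trajectory", "write_report", "FormatError",
]


class FormatError(ValueError):
    """Malformed input file (wrong columns, bad values)."""


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} "
                          f"(found {list(df.columns)})")
    return df


def _write_table(df: pd.DataFrame, path: str | Path, meta: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# config: {config_hash(meta)}\n")
        df.to_csv(fh, index=False)


# -- rate constants ----------------------------------------------------------

def write_rates_table(rc: RateConstants, path: str | Path) -> None:
    rows = [(k, v) for k, v in asdict(rc).items()]
    with Path(path).open("w") as fh:
        fh.write("name\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v!r}\n")


def read_rates_table(path: str | Path) -> RateConstants:
    """Two-column (name, value) delimited table -> RateConstants.

    Unknown names are an error; omitted names keep their defaults.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from None
    if list(df.columns[:2]) != ["name", "value"]:
        raise FormatError(f"{path}: expected columns (name, value), "
                          f"found {list(df.columns)}")
    valid = set(asdict(RateConstants()))
    kw = {}
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        if row.name not in valid:
            raise FormatError(f"{path}:{ln}: unknown rate constant "
                              f"{row.name!r}")
        kw[row.name] = float(row.value)
    return RateConstants(**kw)


# -- histograms --------------------------------------------------------------

def write_histogram(hist: Histogram, path: str | Path,
                    meta: dict | None = None) -> None:
    df = pd.DataFrame({
        "t_lo_s": hist.edges[:-1],
        "t_hi_s": hist.edges[1:],
        "density_per_s": hist.density,
    })
    _write_table(df, path, meta or {"n_samples": hist.n_samples})


def read_histogram(path: str | Path) -> Histogram:
    df = _read_table(path, ["t_lo_s", "t_hi_s", "density_per_s"])
    lo = df["t_lo_s"].to_numpy(float)
    hi = df["t_hi_s"].to_numpy(float)
    if len(lo) == 0:
        raise FormatError(f"{path}: empty histogram")
    if not np.allclose(lo[1:], hi[:-1], rtol=1e-9, atol=1e-12):
        bad = int(np.argmax(~np.isclose(lo[1:], hi[:-1]))) + 3
        raise FormatError(f"{path}:{bad}: bins are not contiguous")
    edges = np.append(lo, hi[-1])
    try:
        return Histogram(edges, df["density_per_s"].to_numpy(float))
    except HistogramError as exc:
        raise FormatError(f"{path}: {exc}") from None


# -- dwell samples -----------------------------------------------------------

def write_dwells(sample: DwellSample, path: str | Path) -> None:
    meta = {"seed": sample.seed, "condition": asdict(sample.condition)}
    _write_table(sample.records, path, meta)


def read_dwells(path: str | Path,
                condition: Condition | None = None) -> DwellSample:
    df = _read_table(path, ["dwell_s", "prev", "next"])
    if (df["dwell_s"] <= 0).any():
        bad = int(df.index[df["dwell_s"] <= 0][0]) + 3
        raise FormatError(f"{path}:{bad}: dwell times must be > 0")
    if not set(df["prev"]).issubset({"f", "b"}) or \
            not set(df["next"]).issubset({"f", "b"}):
        raise FormatError(f"{path}: step directions must be 'f' or 'b'")
    return DwellSample(df[["dwell_s", "prev", "next"]],
                       condition or Condition(), seed=-1)


# -- trajectories ------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    meta = {"seed": traj.seed, "condition": asdict(traj.condition),
            "network": traj.network.name}
    _write_table(traj.position_trace(), path, meta)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ["t_s", "position_nm"])


# -- structured reports ------------------------------------------------------

def write_report(report: dict, path: str | Path) -> None:
    doc = dict(report)
    doc["config_hash"] = config_hash(report)
    Path(path).write_text(json.dumps(doc, indent=1, default=float) + "\n")
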