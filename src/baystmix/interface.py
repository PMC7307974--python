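"""File I/O and the case-study exposure-aggregation utility.

Count tables travel as long (tidy) CSV with columns area, time, count,
expected — one row per area-time cell, forming a complete grid.  The
exposure aggregator turns road-segment records (segment length x annual
average daily flow) into district-level traffic volumes for use as the
Poisson offset when the surveillance outcome is road accidents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import CountData

COUNT_COLUMNS = ("area", "time", "count", "expected")


@dataclass
class RoadSegmentRecord:
    """One road segment: owning district, length (km), AADF (vehicles/day)."""

    district_id: object
    length: float
    aadf: float


def read_counts_csv(path) -> CountData:
    """Read a tidy counts CSV into N x T matrices.

    Rows are reordered by sorted area then time label; the grid must be
    complete and counts/exposures valid, with offending rows named in
    errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts file lacks columns: {missing}")
    dup = df.duplicated(subset=["area", "time"])
    if dup.any():
        raise ValueError(f"duplicate (area,time) rows at lines "
                         f"{list(df.index[dup] + 2)}")
    bad = df.index[df["count"] < 0]
    if len(bad):
        raise ValueError(f"negative counts at rows {list(bad + 2)}")
    bad = df.index[df["expected"] <= 0]
    if len(bad):
        raise ValueError(f"nonpositive expected counts at rows {list(bad + 2)}")
    areas = sorted(df["area"].unique())
    times = sorted(df["time"].unique())
    grid = df.set_index(["area", "time"])
    wanted = pd.MultiIndex.from_product([areas, times])
    absent = wanted.difference(grid.index)
    if len(absent):
        a, t = absent[0]
        raise ValueError(f"incomplete grid: missing cell (area={a}, time={t})"
                         + (f" and {len(absent) - 1} more" if len(absent) > 1
                            else ""))
    grid = grid.reindex(wanted)
    shape = (len(areas), len(times))
    Y = grid["count"].to_numpy().reshape(shape)
    E = grid["expected"].to_numpy(dtype=float).reshape(shape)
    return CountData(Y=Y, E=E, area_labels=areas, time_labels=times)


def write_counts_csv(path, data: CountData) -> None:
    """Write CountData back to the tidy format (inverse of read_counts_csv)."""
    areas = (data.area_labels if data.area_labels is not None
             else list(range(data.n_areas)))
    times = (data.time_labels if data.time_labels is not None
             else list(range(data.n_times)))
    idx = pd.MultiIndex.from_product([areas, times], names=["area", "time"])
    df = pd.DataFrame({"count": data.Y.ravel(), "expected": data.E.ravel()},
                      index=idx).reset_index()
    df.to_csv(path, index=False)


def write_truth_csv(path, z_true, area_labels=None, time_labels=None) -> None:
    """Ground-truth allocation grid (1 = common, 0 = injected unusual)."""
    z = np.asarray(z_true)
    areas = area_labels if area_labels is not None else list(range(z.shape[0]))
    times = time_labels if time_labels is not None else list(range(z.shape[1]))
    idx = pd.MultiIndex.from_product([areas, times], names=["area", "time"])
    pd.DataFrame({"z_true": z.ravel()}, index=idx).reset_index().to_csv(
        path, index=False)


def read_truth_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    areas = sorted(df["area"].unique())
    times = sorted(df["time"].unique())
    grid = df.set_index(["area", "time"])["z_true"]
    grid = grid.reindex(pd.MultiIndex.from_product([areas, times]))
    if grid.isna().any():
        raise ValueError("incomplete truth grid")
    return grid.to_numpy().reshape(len(areas), len(times)).astype(np.int64)


def aggregate_exposure(segments) -> dict:
    """District traffic volume: TV_D = sum over segments of length * AADF.

    Accepts RoadSegmentRecord objects or (district_id, length, aadf)
    triples; districts with no segments are absent from the result.
    """
    seg_list = list(segments)
    if not seg_list:
        raise ValueError("need at least one road segment")
    out: dict = {}
    for k, seg in enumerate(seg_list):
        if isinstance(seg, RoadSegmentRecord):
            did, length, aadf = seg.district_id, seg.length, seg.aadf
        else:
            did, length, aadf = seg
        if length <= 0 or aadf <= 0:
            raise ValueError(f"segment {k}: length and AADF must be positive")
        out[did] = out.get(did, 0.0) + float(length) * float(aadf)
    return out
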