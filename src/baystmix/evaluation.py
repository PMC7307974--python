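"""Performance criteria for detection results against simulated ground truth.

Decision units are areas for the baseline model (it can only flag whole
areas, so an area is truly unusual if any of its time points was injected)
and area-time cells for the proposed model; confusion counts always sum to
the number of decision units (N or N*T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Sensitivity, specificity, false-positive proportion and global error.

    When summarising replicates, ``interval_2p5``/``interval_97p5`` hold
    the empirical 2.5 and 97.5 percentiles per metric.
    """

    sensitivity: float
    specificity: float
    fp_proportion: float
    global_error: float
    n_replicates: int = 1
    interval_2p5: dict = None
    interval_97p5: dict = None

    METRICS = ("sensitivity", "specificity", "fp_proportion", "global_error")


def confusion(flags, truth_unusual, unit: str = "area_time") -> ConfusionCounts:
    """Cross-tabulate declared against true unusual units.

    ``truth_unusual`` is boolean/binary with 1 marking a truly unusual
    unit.  For ``unit="area"`` an N x T truth matrix is collapsed to the
    area level (unusual if any time point is unusual) to match per-area
    flags.
    """
    flags = np.asarray(flags).astype(bool)
    truth = np.asarray(truth_unusual).astype(bool)
    if unit == "area":
        if truth.ndim == 2:
            truth = truth.any(axis=1)
        if flags.ndim != 1:
            raise ValueError("area-level flags must be one-dimensional")
    elif unit == "area_time":
        if flags.ndim != 2 or truth.ndim != 2:
            raise ValueError("area-time evaluation needs N x T matrices")
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if flags.shape != truth.shape:
        raise ValueError("flags and truth shapes do not match")
    tp = int(np.sum(flags & truth))
    fp = int(np.sum(flags & ~truth))
    fn = int(np.sum(~flags & truth))
    tn = int(np.sum(~flags & ~truth))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The four per-replicate criteria.

    fp_proportion is defined as 0 when nothing was declared (TP+FP = 0);
    sensitivity is undefined (NaN, with a warning) when no unit is truly
    unusual.
    """
    if c.TP + c.FN > 0:
        sens = c.TP / (c.TP + c.FN)
    else:
        warnings.warn("no truly unusual units: sensitivity undefined",
                      stacklevel=2)
        sens = np.nan
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else np.nan
    fp_prop = c.FP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else 0.0
    gerr = (c.FP + c.FN) / c.total
    return MetricsReport(sensitivity=sens, specificity=spec,
                         fp_proportion=fp_prop, global_error=gerr)


def summarize_replicates(reports: list[MetricsReport]) -> MetricsReport:
    """Mean and empirical 2.5/97.5 percentiles of each metric over replicates."""
    if not reports:
        raise ValueError("need at least one report")
    vals = {m: np.array([getattr(r, m) for r in reports], dtype=float)
            for m in MetricsReport.METRICS}
    means = {m: float(np.nanmean(v)) for m, v in vals.items()}
    lo = {m: float(np.nanpercentile(v, 2.5)) for m, v in vals.items()}
    hi = {m: float(np.nanpercentile(v, 97.5)) for m, v in vals.items()}
    return MetricsReport(sensitivity=means["sensitivity"],
                         specificity=means["specificity"],
                         fp_proportion=means["fp_proportion"],
                         global_error=means["global_error"],
                         n_replicates=len(reports),
                         interval_2p5=lo, interval_97p5=hi)


def no_aberration_summary(results) -> tuple[float, float]:
    """Null-scenario summary over replicates.

    Returns the proportion of replicates declaring at least one aberration
    and the mean number of declared aberrations among those replicates
    (0 when no replicate declares any).
    """
    if not results:
        raise ValueError("need at least one detection result")
    counts = np.array([int(np.sum(np.asarray(r.flags))) for r in results])
    positive = counts > 0
    prop = float(positive.mean())
    mean_count = float(counts[positive].mean()) if positive.any() else 0.0
    return prop, mean_count
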