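"""Classification of unusual units from posterior allocation probabilities.

Both models yield allocation probabilities f = P(z = 1 | data) — per area
for the baseline model, per area-time cell for the proposed model; low f
means the unit is poorly explained by the common trend.  The baseline
model uses a Bayesian false-discovery-rate rule to pick the flagging
threshold; the proposed model's hierarchical allocation prior already
controls multiplicity, so a fixed 0.05 cut-off is used directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FDR_ALPHA = 0.05
DEFAULT_FIXED_LEVEL = 0.05


@dataclass
class DetectionResult:
    """Binary flags (1 = declared unusual) plus the rule and threshold used."""

    flags: np.ndarray
    threshold_used: float
    rule: str

    @property
    def n_flagged(self) -> int:
        return int(np.sum(self.flags))

    def to_frame(self, area_labels=None, time_labels=None,
                 f=None) -> pd.DataFrame:
        """Tidy table of flagged units (one row per declared aberration)."""
        flags = np.asarray(self.flags)
        rows = []
        if flags.ndim == 1:
            for i in np.flatnonzero(flags):
                rows.append({
                    "area": area_labels[i] if area_labels is not None else i,
                    "time": None,
                    "f": None if f is None else float(np.asarray(f)[i]),
                    "rule": self.rule,
                    "threshold": self.threshold_used,
                })
        else:
            for i, t in zip(*np.nonzero(flags)):
                rows.append({
                    "area": area_labels[i] if area_labels is not None else i,
                    "time": time_labels[t] if time_labels is not None else t,
                    "f": None if f is None else float(np.asarray(f)[i, t]),
                    "rule": self.rule,
                    "threshold": self.threshold_used,
                })
        return pd.DataFrame(rows,
                            columns=["area", "time", "f", "rule", "threshold"])


def bayesian_fdr_classify(f, alpha: float = DEFAULT_FDR_ALPHA) -> DetectionResult:
    """Flag units by the Bayesian FDR rule.

    With f_(1) <= ... <= f_(n) the ordered allocation probabilities, k is
    the largest integer such that the mean of the k smallest is below
    alpha; the threshold is C = f_(k) and units with f <= C are declared
    unusual.  The "<=" convention makes the number of discoveries equal k
    (ties at C are all flagged); k = 0 flags nothing.
    """
    f = np.asarray(f, dtype=float)
    if f.size == 0:
        raise ValueError("empty probability vector")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not np.all(np.isfinite(f)):
        raise ValueError("allocation probabilities must be finite")
    srt = np.sort(f.ravel())
    running_means = np.cumsum(srt) / np.arange(1, srt.size + 1)
    below = np.flatnonzero(running_means < alpha)
    if below.size == 0:
        return DetectionResult(flags=np.zeros_like(f, dtype=np.int64),
                               threshold_used=0.0, rule="fdr")
    k = int(below.max()) + 1
    C = float(srt[k - 1])
    flags = (f <= C).astype(np.int64)
    return DetectionResult(flags=flags, threshold_used=C, rule="fdr")


def fixed_threshold_classify(f, level: float = DEFAULT_FIXED_LEVEL) -> DetectionResult:
    """Flag units whose allocation probability is strictly below `level`."""
    f = np.asarray(f, dtype=float)
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    flags = (f < level).astype(np.int64)
    return DetectionResult(flags=flags, threshold_used=float(level),
                           rule="fixed")
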