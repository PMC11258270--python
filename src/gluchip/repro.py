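"""Reproducibility and summary statistics for on-chip readouts.

Replicate circuits measured at a common set of timepoints form an
endpoint matrix (circuit x timepoint).  Reproducibility is quantified by
the maximum coefficient of variation across timepoints and the two-way
random-effects single-measure intraclass correlation ICC(2,1), treating
each circuit as a "judge" and each timepoint as a "target", and
summarized as Excellent / Acceptable / Poor.  Data are not
log-transformed before these procedures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EndpointMatrix",
    "auc_trapezoid",
    "max_cv",
    "icc2",
    "classify_reproducibility",
]


@dataclass(frozen=True)
class EndpointMatrix:
    """One endpoint measured on replicate circuits at shared timepoints.

    ``values`` is circuits x timepoints; NaN marks missing cells.
    """

    values: np.ndarray
    circuits: tuple[str, ...] = ()
    timepoints: tuple[str, ...] = ()
    condition: str = ""
    study: str = ""
    lab: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("endpoint matrix must be 2-D (circuits x timepoints)")
        if not self.circuits:
            object.__setattr__(self, "circuits", tuple(f"circuit{i+1}" for i in range(v.shape[0])))
        if not self.timepoints:
            object.__setattr__(self, "timepoints", tuple(f"t{j+1}" for j in range(v.shape[1])))

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    @classmethod
    def from_long(cls, df: pd.DataFrame, **annotations) -> "EndpointMatrix":
        """Build from long-format rows with columns circuit / timepoint /
        value (missing combinations become NaN)."""
        wide = df.pivot(index="circuit", columns="timepoint", values="value")
        return cls(
            values=wide.to_numpy(dtype=float),
            circuits=tuple(map(str, wide.index)),
            timepoints=tuple(map(str, wide.columns)),
            **annotations,
        )


def auc_trapezoid(times: Sequence[float], values: Sequence[float]) -> float:
    """Composite trapezoidal area under a concentration-time curve
    (concentration x hours)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2 or t.shape != v.shape:
        raise ValueError("need >= 2 (time, value) pairs of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def max_cv(matrix: EndpointMatrix) -> float:
    """Maximum over timepoints of the across-circuit coefficient of
    variation sd/mean (sample sd, n-1), in percent."""
    v = matrix.values
    cvs = []
    for j in range(v.shape[1]):
        col = v[:, j]
        col = col[np.isfinite(col)]
        if col.size < 2:
            raise ValueError(f"timepoint {matrix.timepoints[j]!r} has fewer than 2 circuits")
        mean = col.mean()
        if mean == 0:
            raise ValueError(f"zero mean at timepoint {matrix.timepoints[j]!r}: CV undefined")
        cvs.append(col.std(ddof=1) / mean)
    return float(100.0 * max(cvs))


def icc2(matrix: EndpointMatrix, literal_nc: bool = False) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, with circuits as judges and timepoints as targets.

    Computed from the two-way ANOVA mean squares as

        (MS_B - MS_E) / (MS_B + (n_r - 1) MS_E + n_r (MS_J - MS_E) / n_c)

    with MS_B the between-target (timepoint) mean square, MS_J the
    between-judge (circuit) mean square, MS_E the residual mean square
    and n_r the number of judges.  ``n_c`` is the number of targets in
    the standard definition (default); ``literal_nc=True`` uses the
    total number of observations instead, for comparison.
    """
    v = matrix.values
    if not matrix.complete:
        raise ValueError("ICC requires a complete matrix (no missing cells)")
    n_r, n_t = v.shape  # judges (circuits), targets (timepoints)
    if n_r < 2 or n_t < 2:
        raise ValueError("ICC requires >= 2 circuits and >= 2 timepoints")
    grand = v.mean()
    judge_means = v.mean(axis=1)
    target_means = v.mean(axis=0)
    ss_j = n_t * np.sum((judge_means - grand) ** 2)
    ss_b = n_r * np.sum((target_means - grand) ** 2)
    resid = v - judge_means[:, None] - target_means[None, :] + grand
    ss_e = np.sum(resid**2)
    ms_j = ss_j / (n_r - 1)
    ms_b = ss_b / (n_t - 1)
    ms_e = ss_e / ((n_r - 1) * (n_t - 1))
    n_c = n_r * n_t if literal_nc else n_t
    denom = ms_b + (n_r - 1) * ms_e + n_r * (ms_j - ms_e) / n_c
    return float((ms_b - ms_e) / denom)


def classify_reproducibility(max_cv_percent: float, icc: float) -> str:
    """Excellent if Max CV <= 5% or ICC >= 0.8; Acceptable if
    5% < Max CV < 15% or 0.2 <= ICC < 0.8; otherwise Poor.  Rules are
    checked in that precedence order."""
    if not (np.isfinite(max_cv_percent) and np.isfinite(icc)):
        raise ValueError("classification requires finite inputs")
    if max_cv_percent <= 5.0 or icc >= 0.8:
        return "Excellent"
    if 5.0 < max_cv_percent < 15.0 or 0.2 <= icc < 0.8:
        return "Acceptable"
    return "Poor"
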