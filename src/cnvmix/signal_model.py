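"""Copy-number signal model under normal-cell contamination.

A SNP-array log2-ratio measures sample versus reference intensity.  For a
tumor sample carrying ``j`` copies of a locus, diluted by a fraction ``p``
of normal (diploid) cells on a platform with additive background ``b``, the
expected log2-ratio is

    m(j; p, b) = log2( (j * (1 - p) + 2 * p + b) / (2 + b) )

which is exactly 0 for the diploid state ``j = 2`` and shrinks every
aberrant mean toward 0 as contamination grows.  This module houses that
formula, the least-squares calibration of the background factor ``b`` from
observed per-copy-number means, and the copy-number class system: each
mixture component is permanently identified with one class, i.e. with one
uniform prior interval on the log2-ratio axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "DEFAULT_BACKGROUND",
    "CopyNumberClass",
    "ContaminationModel",
    "theoretical_mean",
    "calibrate_background",
    "default_classes",
    "classes_for_contamination",
    "class_table",
    "write_class_table",
]

#: Background factor recovered by :func:`calibrate_background` from the
#: published per-copy-number mean log2-ratios (-1.24, -.49, 0, .365, .657,
#: .899, 1.106 for CN 0..5 and >5).  Not directly measurable; fixed here as
#: the package-wide default.
DEFAULT_BACKGROUND = 1.47

#: Copy number the open-ended ">5" class is evaluated at in the mean
#: formula.  j = 6 reproduces the published >5 mean of 1.106 with b = 1.47.
GT5_EFFECTIVE_CN = 6

# Uniform prior supports for the component means, CN 0,1,2,3,4,5,>5.  The
# diploid interval is symmetric about the null value 0; the others sit
# slightly toward 0 relative to the uncontaminated means so that moderate
# normal-cell contamination keeps each mean inside its interval.
_DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = (
    (-2.0, -0.8),
    (-0.6, -0.25),
    (-0.05, 0.05),
    (0.15, 0.4),
    (0.45, 0.66),
    (0.75, 0.9),
    (0.95, 1.3),
)


@dataclass(frozen=True)
class CopyNumberClass:
    """One mixture-component slot: an integer copy number and its uniform
    prior interval ``(lower, upper)`` on the log2-ratio scale.

    ``cn_label`` is the integer copy number; the open-ended ">5" class is
    stored as ``cn_label = 6`` (see :data:`GT5_EFFECTIVE_CN`).
    """

    index: int  # 1-based position in the class table
    cn_label: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.cn_label < 0:
            raise ValueError("cn_label must be a non-negative copy number")
        if not self.lower < self.upper:
            raise ValueError(
                f"empty interval ({self.lower}, {self.upper}) for class {self.index}"
            )

    @property
    def label(self) -> str:
        return ">5" if self.cn_label >= GT5_EFFECTIVE_CN else str(self.cn_label)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower < value < self.upper


@dataclass(frozen=True)
class ContaminationModel:
    """Normal-cell contamination fraction ``p`` and background factor ``b``."""

    p: float = 0.0
    b: float = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"contamination fraction p={self.p} outside [0, 1]")
        if self.b < 0.0:
            raise ValueError(f"background factor b={self.b} must be non-negative")


def theoretical_mean(j: float, model: ContaminationModel | None = None) -> float:
    """Expected log2-ratio for true copy number ``j``.

    Evaluates ``log2((j(1-p) + 2p + b) / (2 + b))``.  Returns exactly 0 for
    ``j = 2`` (numerator equals denominator) and for ``p = 1`` (pure normal
    cells give the diploid signal for any j).
    """
    if model is None:
        model = ContaminationModel()
    if j < 0:
        raise ValueError(f"copy number j={j} must be non-negative")
    return math.log2((j * (1.0 - model.p) + 2.0 * model.p + model.b) / (2.0 + model.b))


def calibrate_background(target_means: Iterable[tuple[float, float]]) -> float:
    """Least-squares fit of the background factor ``b`` to uncontaminated
    per-copy-number means.

    ``target_means`` is a collection of ``(j, mean)`` pairs observed at
    p = 0.  Minimizes ``sum_j (log2((j + b)/(2 + b)) - mean_j)^2`` over
    ``b > 0`` by bracketed scalar minimization.  Pairs with ``j = 2`` carry
    no information on ``b`` (the model mean is identically 0); supplying
    only such pairs raises ``ValueError``.
    """
    pairs = [(float(j), float(m)) for j, m in target_means]
    if not any(j != 2 for j, _ in pairs):
        raise ValueError("background factor is unidentifiable from j=2 pairs alone")

    def sse(b: float) -> float:
        return sum(
            (math.log2((j + b) / (2.0 + b)) - m) ** 2 for j, m in pairs
        )

    res = minimize_scalar(sse, bounds=(1e-9, 100.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def default_classes() -> list[CopyNumberClass]:
    """The seven default copy-number classes (CN 0,1,2,3,4,5,>5) with their
    published uniform prior intervals."""
    return [
        CopyNumberClass(index=i + 1, cn_label=i, lower=lo, upper=hi)
        for i, (lo, hi) in enumerate(_DEFAULT_INTERVALS)
    ]


def classes_for_contamination(
    p: float,
    b: float,
    half_widths: Sequence[float],
) -> list[CopyNumberClass]:
    """Build a class table recentered at the contamination-shrunk means.

    Interval ``j`` is centered at ``theoretical_mean(j; p, b)`` with the
    requested half-width; if neighboring intervals would overlap, all
    half-widths are shrunk by a common factor until the table is disjoint.
    The diploid interval is always centered at 0.  ``p = 1`` collapses every
    mean onto 0 and is rejected (classes become unidentifiable).
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"contamination fraction p={p} must lie in [0, 1)")
    widths = np.asarray(half_widths, dtype=float)
    if widths.ndim != 1 or len(widths) < 2:
        raise ValueError("need one positive half-width per class (at least two)")
    if np.any(widths <= 0):
        raise ValueError("half-widths must be positive")
    model = ContaminationModel(p=p, b=b)
    n_cls = len(widths)
    cns = [GT5_EFFECTIVE_CN if i == 6 else i for i in range(n_cls)]
    centers = np.array([theoretical_mean(j, model) for j in cns])
    # Uniform shrink factor keeping every adjacent pair disjoint (open
    # intervals may share an endpoint).
    gaps = np.diff(centers)
    need = widths[:-1] + widths[1:]
    scale = min(1.0, float(np.min(gaps / need)))
    widths = widths * scale
    return [
        CopyNumberClass(index=i + 1, cn_label=cns[i],
                        lower=float(centers[i] - widths[i]),
                        upper=float(centers[i] + widths[i]))
        for i in range(n_cls)
    ]


def class_table(
    classes: Sequence[CopyNumberClass],
    model: ContaminationModel | None = None,
) -> pd.DataFrame:
    """Tabulate a class list: index, cn_label, interval and theoretical mean."""
    if model is None:
        model = ContaminationModel()
    return pd.DataFrame(
        {
            "index": [c.index for c in classes],
            "cn_label": [c.label for c in classes],
            "lower": [c.lower for c in classes],
            "upper": [c.upper for c in classes],
            "theoretical_mean": [theoretical_mean(c.cn_label, model) for c in classes],
        }
    )


def write_class_table(path, classes: Sequence[CopyNumberClass],
                      model: ContaminationModel | None = None) -> None:
    class_table(classes, model).to_csv(path, sep="\t", index=False)
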