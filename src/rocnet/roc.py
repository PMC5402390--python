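"""Empirical ROC curves and the statistics built on them.

A risk factor measured in a diseased group (``u``, size ``n``) and a healthy
group (``v``, size ``m``) induces an empirical ROC curve: for every threshold
``f`` the false positive rate is the fraction of healthy values at or above
``f`` and the true positive rate is the fraction of diseased values at or
above ``f``.  The curve is represented piecewise-linearly through its
staircase vertices, which makes the trapezoidal area identical to the
Mann-Whitney statistic (ties weighted one half) and makes L1/L2 distances
between two curves exactly computable on their merged breakpoints.

Everything here depends on the data only through within- and across-group
order comparisons, so any strictly increasing transform of a factor leaves
the curve, the AUC, the screening statistic and all curve distances
bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

DISTANCE_METRICS = ("l1", "l2", "sup", "auc_diff")
CORRELATION_FORMS = ("inv1p", "exp_decay")


@dataclass(frozen=True)
class TwoGroupSample:
    """One factor's observations split by disease status.

    Parameters
    ----------
    factor_name
        Label carried through result tables.
    diseased_values
        Observations from the diseased / high-incidence group (``D = 1``).
    healthy_values
        Observations from the healthy / control group (``D = 0``).
    """

    factor_name: str
    diseased_values: np.ndarray
    healthy_values: np.ndarray

    def __post_init__(self) -> None:
        for attr, group in (("diseased_values", "diseased"), ("healthy_values", "healthy")):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise InvalidInputError(
                    f"factor {self.factor_name!r}: {group} group must be a non-empty 1-d sequence"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(
                    f"factor {self.factor_name!r}: non-finite values in {group} group"
                )
            object.__setattr__(self, attr, arr)

    @property
    def n(self) -> int:
        """Diseased-group size."""
        return self.diseased_values.size

    @property
    def m(self) -> int:
        """Healthy-group size."""
        return self.healthy_values.size

    @property
    def lambda_ratio(self) -> float:
        """Sample-size ratio n/m entering the asymptotic null."""
        return self.n / self.m


@dataclass(frozen=True)
class ROCCurve:
    """Piecewise-linear ROC curve through staircase vertices in the unit square.

    ``fpr_points`` and ``tpr_points`` are nondecreasing, start at (0, 0) and
    end at (1, 1).  ``R(t)`` is evaluated by linear interpolation; vertical
    jumps (repeated ``fpr`` values) have measure zero and do not affect areas
    or integral distances.
    """

    fpr_points: np.ndarray
    tpr_points: np.ndarray

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr_points, dtype=float)
        tpr = np.asarray(self.tpr_points, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1 or fpr.size < 2:
            raise InvalidInputError("ROC vertices must be two equal-length 1-d arrays, length >= 2")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise InvalidInputError("ROC vertex coordinates must be nondecreasing")
        if fpr[0] != 0.0 or tpr[0] != 0.0 or fpr[-1] != 1.0 or tpr[-1] != 1.0:
            raise InvalidInputError("ROC curve must run from (0,0) to (1,1)")
        object.__setattr__(self, "fpr_points", fpr)
        object.__setattr__(self, "tpr_points", tpr)

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        """Evaluate R(t) by linear interpolation between vertices."""
        return np.interp(t, self.fpr_points, self.tpr_points)

    def auc(self) -> float:
        """Trapezoidal area under the curve; see :func:`auc`."""
        return float(np.trapezoid(self.tpr_points, self.fpr_points))


def empirical_roc(sample: TwoGroupSample) -> ROCCurve:
    """Empirical ROC curve of one factor.

    Thresholds sweep the pooled distinct observed values in descending
    order; a value at or above the threshold is called positive.  Values
    shared by both groups produce single diagonal-sloped segments, the
    half-tie convention.
    """
    u = np.sort(sample.diseased_values)
    v = np.sort(sample.healthy_values)
    thresholds = np.unique(np.concatenate([u, v]))[::-1]
    # fraction of each group at or above every threshold, by rank counting
    tpr = (sample.n - np.searchsorted(u, thresholds, side="left")) / sample.n
    fpr = (sample.m - np.searchsorted(v, thresholds, side="left")) / sample.m
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    # the smallest pooled value already yields (1, 1)
    return ROCCurve(fpr, tpr)


def auc(roc: ROCCurve) -> float:
    """Exact trapezoidal area under a piecewise-linear ROC curve.

    For a curve fitted by :func:`empirical_roc` this equals the
    Mann-Whitney statistic ``(1/nm) * sum[1(u > v) + 0.5 * 1(u = v)]``.
    """
    return roc.auc()


def s_a_statistic(sample: TwoGroupSample) -> float:
    """Screening statistic ``S_A = sqrt(n) * |AUC - 1/2|``.

    ``n`` is the diseased-group size.  Under independence of factor and
    disease status the statistic converges to the absolute integral of
    ``B1(t) + sqrt(lambda) * B2(t)`` over [0, 1] with two independent
    Brownian bridges, which the null simulator draws from.  The absolute
    value makes the test two-sided, so protective factors (AUC < 1/2) are
    flagged as well.
    """
    return float(np.sqrt(sample.n) * abs(auc(empirical_roc(sample)) - 0.5))


def _collapse_vertices(fpr: np.ndarray, tpr: np.ndarray):
    """Distinct abscissae with lower (first) and upper (last) ordinate at each."""
    x, first = np.unique(fpr, return_index=True)
    last = fpr.size - 1 - np.unique(fpr[::-1], return_index=True)[1]
    return x, tpr[first], tpr[last]


def _segment_endpoint_values(fpr, tpr, grid):
    """Right-limit at each grid segment start and left-limit at its end.

    Vertical jumps of the staircase sit exactly at breakpoints, so on the
    open interior of every merged segment the curve is a single linear
    piece; evaluating one-sided limits keeps integral distances exact.
    """
    x, y_lo, y_hi = _collapse_vertices(fpr, tpr)
    idx = np.clip(np.searchsorted(x, grid[:-1], side="right") - 1, 0, x.size - 2)
    x0, x1 = x[idx], x[idx + 1]
    slope = (y_lo[idx + 1] - y_hi[idx]) / (x1 - x0)
    start = y_hi[idx] + slope * (grid[:-1] - x0)
    end = y_hi[idx] + slope * (grid[1:] - x0)
    return start, end


def roc_distance(a: ROCCurve, b: ROCCurve, metric: str = "l1") -> float:
    """Distance between two ROC curves viewed as functions of t.

    ``l1`` (default) is the exact integral of ``|R_a(t) - R_b(t)|`` on the
    merged breakpoint set, splitting segments at interior sign changes;
    ``l2`` is the root of the exact integral of the squared difference;
    ``sup`` the maximum absolute difference over merged vertices;
    ``auc_diff`` the absolute difference of areas.
    """
    if metric not in DISTANCE_METRICS:
        raise ConfigurationError(f"unknown ROC distance metric {metric!r}; choose from {DISTANCE_METRICS}")
    if metric == "auc_diff":
        return abs(a.auc() - b.auc())
    grid = np.union1d(a.fpr_points, b.fpr_points)
    a0, a1 = _segment_endpoint_values(a.fpr_points, a.tpr_points, grid)
    b0, b1 = _segment_endpoint_values(b.fpr_points, b.tpr_points, grid)
    h0, h1 = a0 - b0, a1 - b1
    dt = np.diff(grid)
    if metric == "sup":
        return float(max(np.max(np.abs(h0)), np.max(np.abs(h1))))
    if metric == "l2":
        return float(np.sqrt(np.sum(dt * (h0 * h0 + h0 * h1 + h1 * h1) / 3.0)))
    # l1: trapezoid where the sign is constant, else split at the root
    same_sign = h0 * h1 >= 0
    area = np.where(
        same_sign,
        0.5 * (np.abs(h0) + np.abs(h1)) * dt,
        0.5 * (h0 * h0 + h1 * h1) / np.maximum(np.abs(h0 - h1), np.finfo(float).tiny) * dt,
    )
    return float(np.sum(area))


def roc_correlation(d: float, form: str = "inv1p") -> float:
    """Map a curve distance to a correlation-like weight in (0, 1].

    ``inv1p`` (default) returns ``1 / (1 + d)``; ``exp_decay`` returns
    ``exp(-d)``.  Both are strictly decreasing in ``d`` and equal 1 iff the
    curves coincide.
    """
    if form not in CORRELATION_FORMS:
        raise ConfigurationError(f"unknown correlation form {form!r}; choose from {CORRELATION_FORMS}")
    if not np.isfinite(d) or d < 0:
        raise InvalidInputError(f"ROC distance must be finite and nonnegative, got {d}")
    return float(1.0 / (1.0 + d)) if form == "inv1p" else float(np.exp(-d))


@dataclass(frozen=True)
class TransformParams:
    """Robust location/scale of one factor: median and median absolute deviation.

    A zero MAD (constant factor) falls back to scale 1 with a warning so the
    transform stays defined.
    """

    center: float
    scale: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.scale) or self.scale <= 0:
            raise InvalidInputError("transform requires finite center and strictly positive scale")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "TransformParams":
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("transform parameters require finite values")
        center = float(np.median(arr))
        scale = float(np.median(np.abs(arr - center)))
        if scale == 0.0:
            warnings.warn(
                "median absolute deviation is zero (constant factor); using scale 1.0",
                stacklevel=2,
            )
            scale = 1.0
        return cls(center=center, scale=scale)


def median_mad_transform(
    values: Sequence[float], params: TransformParams | None = None
) -> np.ndarray:
    """Logistic squashing ``z = 1 / (1 + exp(-(f - center)/scale))`` into (0, 1).

    With ``params`` omitted the median and MAD of ``values`` are used.  The
    map is strictly increasing and sends the center to exactly 0.5, so the
    ROC curve of a transformed factor is vertex-for-vertex that of the raw
    factor; its only purpose is to put heterogeneous factors on one
    comparable (0, 1) scale for display.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("median_mad_transform requires finite values")
    if params is None:
        params = TransformParams.from_values(arr)
    return expit((arr - params.center) / params.scale)
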