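"""Independence analysis: do constancy and memory biases add up?

If the context (constancy) effect and the short-term-memory effect act
independently, the bias measured when both demands are present ("joint"
condition) should equal the constancy effect applied to the memory-biased
reference: take each memory match m(r_i) as a new reference and read off
the constancy match to it.  Constancy matches were only measured at the
three reference hues r_i, so the constancy function C is interpolated
piecewise-linearly through the measured (r_i, c(r_i)) and evaluated at
m(r_i); mild linear extrapolation beyond the reference range is allowed
(warned beyond 4% of the range, refused beyond 10%).

Departures from additivity are summarized by a non-additivity index

    NI = (|measured| - |predicted|) / (|measured| + |predicted|)

which is 0 at full additivity, negative when the measured joint bias is
smaller in magnitude than predicted (subadditivity), positive for
superadditivity, and bounded in [-1, 1].

Supporting statistics: the central-tendency slope (OLS slope of memory bias
on reference hue; negative = extreme references drawn toward the middle),
an exact one-tailed sign test, and Pearson bias-threshold correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ExtrapolationError,
    InvalidParameterError,
    UndefinedCorrelationError,
    UndefinedIndexError,
)

__all__ = [
    "MatchSet",
    "IndependenceResult",
    "predict_joint",
    "non_additivity_index",
    "central_tendency_slope",
    "sign_test_one_tailed",
    "bias_threshold_correlation",
    "summarize_independence",
]

logger = logging.getLogger(__name__)

#: extrapolation fractions of the reference range: warn above, refuse above
EXTRAPOLATION_WARN = 0.04
EXTRAPOLATION_MAX = 0.10


@dataclass(frozen=True)
class MatchSet:
    """Measured matches for one reference background.

    ``reference_hues[i]`` is r_i; ``memory_matches[i]`` = m(r_i),
    ``constancy_matches[i]`` = c(r_i), and (optionally)
    ``joint_matches[i]`` = j(r_i), all in radians on the hue axis.
    """

    reference_hues: np.ndarray
    memory_matches: np.ndarray
    constancy_matches: np.ndarray
    joint_matches: np.ndarray | None = None
    reference_background: str | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.reference_hues, dtype=float)
        m = np.asarray(self.memory_matches, dtype=float)
        c = np.asarray(self.constancy_matches, dtype=float)
        object.__setattr__(self, "reference_hues", r)
        object.__setattr__(self, "memory_matches", m)
        object.__setattr__(self, "constancy_matches", c)
        if self.joint_matches is not None:
            j = np.asarray(self.joint_matches, dtype=float)
            object.__setattr__(self, "joint_matches", j)
            if j.shape != r.shape:
                raise InvalidParameterError("joint_matches misaligned with reference_hues")
        if not (r.shape == m.shape == c.shape) or r.ndim != 1:
            raise InvalidParameterError("match arrays must be aligned 1-d arrays")
        if r.size < 2:
            raise InvalidParameterError("need at least two reference hues")
        if np.unique(r).size != r.size:
            raise InvalidParameterError("reference hues must be distinct")


def _interp_linear(x: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with linear end-segment extrapolation."""
    out = np.interp(x, xs, ys)
    below = x < xs[0]
    above = x > xs[-1]
    if below.any():
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        out = np.where(below, ys[0] + slope * (x - xs[0]), out)
    if above.any():
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.where(above, ys[-1] + slope * (x - xs[-1]), out)
    return out


def predict_joint(match_set: MatchSet) -> np.ndarray:
    """Predicted joint matches under independence: p(r_i) = C(m(r_i)).

    C is the piecewise-linear interpolant through (r_i, c(r_i)).  Memory
    matches falling outside the reference range are extrapolated linearly
    from the nearest segment; a warning is logged beyond
    ``EXTRAPOLATION_WARN`` of the range and an :class:`ExtrapolationError`
    raised beyond ``EXTRAPOLATION_MAX``.
    """
    order = np.argsort(match_set.reference_hues)
    r = match_set.reference_hues[order]
    c = match_set.constancy_matches[order]
    m = match_set.memory_matches

    span = r[-1] - r[0]
    departure = np.maximum(r[0] - m, m - r[-1]) / span
    worst = float(departure.max())
    if worst > EXTRAPOLATION_MAX:
        raise ExtrapolationError(
            f"memory match departs {worst:.1%} beyond the reference range "
            f"(limit {EXTRAPOLATION_MAX:.0%})"
        )
    if worst > EXTRAPOLATION_WARN:
        msg = (
            f"extrapolating constancy function {worst:.1%} beyond the "
            f"reference range (> {EXTRAPOLATION_WARN:.0%})"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return _interp_linear(m, r, c)


def non_additivity_index(measured_bias: float, predicted_bias: float) -> float:
    """NI = (|measured| - |predicted|) / (|measured| + |predicted|).

    Zero at equal magnitudes, negative for subadditivity (measured smaller
    than predicted), positive for superadditivity; bounded in [-1, 1].
    Undefined when both biases are zero.
    """
    am, ap = abs(float(measured_bias)), abs(float(predicted_bias))
    if am + ap == 0.0:
        raise UndefinedIndexError("non-additivity index undefined: both biases are zero")
    return (am - ap) / (am + ap)


def central_tendency_slope(biases, reference_hues) -> float:
    """OLS slope of bias on reference hue; negative indicates central tendency."""
    y = np.asarray(biases, dtype=float)
    x = np.asarray(reference_hues, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidParameterError("need aligned 1-d arrays with >= 2 points")
    if np.unique(x).size < 2:
        raise InvalidParameterError("reference hues are all identical; slope undefined")
    return float(stats.linregress(x, y).slope)


def sign_test_one_tailed(values, direction: str) -> float:
    """Exact one-tailed sign test against a fair coin.

    Returns the binomial probability of at least the observed number of
    ``direction``-consistent signs ("negative" or "positive") among the
    non-zero values under P = 0.5.  Ties (zeros) are dropped.
    """
    if direction not in ("negative", "positive"):
        raise InvalidParameterError("direction must be 'negative' or 'positive'")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("values must be non-empty")
    v = v[v != 0.0]
    if v.size == 0:
        raise InvalidParameterError("all values are ties; sign test undefined")
    hits = int((v < 0).sum()) if direction == "negative" else int((v > 0).sum())
    return float(stats.binomtest(hits, int(v.size), 0.5, alternative="greater").pvalue)


def bias_threshold_correlation(
    abs_biases,
    thresholds,
    *,
    exclude=None,
    exclusion_reason: str | None = None,
) -> tuple[float, float]:
    """Pearson correlation between bias magnitudes and thresholds.

    Also used for (non-additivity index, joint threshold) pairs.  Indices in
    ``exclude`` are dropped as flagged outliers; the justification is
    logged so no exclusion is silent.
    """
    x = np.asarray(abs_biases, dtype=float)
    y = np.asarray(thresholds, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("need aligned 1-d arrays")
    if exclude is not None and len(exclude) > 0:
        mask = np.ones(x.size, dtype=bool)
        mask[np.asarray(list(exclude), dtype=int)] = False
        logger.info(
            "excluding %d of %d points from correlation: %s",
            int((~mask).sum()), x.size, exclusion_reason or "flagged as outlier",
        )
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise InvalidParameterError("need >= 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in an input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class IndependenceResult:
    """Per-cell measured vs. predicted joint biases and their summary."""

    table: pd.DataFrame  # one row per (reference_background, reference_hue)
    mean_ni: float
    sign_test_p: float
    subadditivity_ratio: float
    n_cells: int

    def __str__(self) -> str:  # human-readable one-liner
        return (
            f"IndependenceResult(n_cells={self.n_cells}, mean NI={self.mean_ni:+.3f}, "
            f"one-tailed sign test p={self.sign_test_p:.4g}, "
            f"measured/predicted={self.subadditivity_ratio:.2f})"
        )


def summarize_independence(match_sets) -> IndependenceResult:
    """Predict joint biases for each match set and summarize non-additivity.

    ``match_sets`` is an iterable of :class:`MatchSet` with measured joint
    matches.  Returns per-cell measured/predicted biases and NIs plus the
    mean NI, a one-tailed sign test for subadditivity (NI < 0), and the
    ratio mean|measured| / mean|predicted|.
    """
    rows = []
    for ms in match_sets:
        if ms.joint_matches is None:
            raise InvalidParameterError("match set lacks measured joint matches")
        predicted = predict_joint(ms)
        for i, r in enumerate(ms.reference_hues):
            measured_bias = float(ms.joint_matches[i] - r)
            predicted_bias = float(predicted[i] - r)
            rows.append(
                {
                    "reference_background": ms.reference_background,
                    "reference_hue": float(r),
                    "measured_joint_bias": measured_bias,
                    "predicted_joint_bias": predicted_bias,
                    "non_additivity_index": non_additivity_index(
                        measured_bias, predicted_bias
                    ),
                }
            )
    if not rows:
        raise InvalidParameterError("no match sets provided")
    table = pd.DataFrame(rows)
    ni = table["non_additivity_index"].to_numpy()
    ratio = float(
        np.abs(table["measured_joint_bias"]).mean()
        / np.abs(table["predicted_joint_bias"]).mean()
    )
    return IndependenceResult(
        table=table,
        mean_ni=float(ni.mean()),
        sign_test_p=sign_test_one_tailed(ni, "negative"),
        subadditivity_ratio=ratio,
        n_cells=len(table),
    )
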