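"""Cumulative-normal psychometric function fitting for 2AFC hue data.

The probability of judging the test bluer is modeled as

    p(x) = lapse/2 + (1 - lapse) * Phi((x - location) / spread)

with a single symmetric lapse rate bounded to [0, 0.05].  Parameters are
estimated by direct maximum likelihood of the Bernoulli responses (binned by
test hue) with a deterministic multi-start L-BFGS-B optimization, so the
same data always yield the same fit.

Appearance and precision are read off the underlying normal, not the
lapse-scaled curve: the point of subjective equality (PSE) is the 50th
percentile (= ``location``), and the discrimination threshold is the hue
angle between the 75th and 50th percentiles, ``spread * Phi^{-1}(0.75)``.
Perceptual bias in a condition is its PSE minus the baseline PSE for the
same reference and reference background, which cancels any constant
response bias induced by the task wording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .exceptions import (
    CellMismatchError,
    EmptyCellError,
    FitNotConvergedError,
    NonIdentifiableError,
)

__all__ = [
    "CellKey",
    "BinnedResponses",
    "PmfFit",
    "pool_and_bin",
    "fit_pmf",
    "pse",
    "threshold",
    "precision",
    "bias",
    "bootstrap_ci",
    "Z75",
]

#: 75th percentile of the standard normal; threshold = spread * Z75
Z75 = float(norm.ppf(0.75))


class CellKey(NamedTuple):
    """Identifies one analysis cell."""

    condition: str
    reference_hue: float
    reference_background: str


@dataclass(frozen=True)
class BinnedResponses:
    """Per-test-hue response counts for one cell."""

    test_hues: np.ndarray
    n_trials: np.ndarray
    n_test_bluer: np.ndarray
    cell: CellKey | None = None

    def __post_init__(self) -> None:
        hues = np.asarray(self.test_hues, dtype=float)
        n = np.asarray(self.n_trials, dtype=np.int64)
        k = np.asarray(self.n_test_bluer, dtype=np.int64)
        object.__setattr__(self, "test_hues", hues)
        object.__setattr__(self, "n_trials", n)
        object.__setattr__(self, "n_test_bluer", k)
        if not (hues.shape == n.shape == k.shape) or hues.ndim != 1:
            raise ValueError("test_hues, n_trials, n_test_bluer must be aligned 1-d arrays")
        if np.any(np.diff(hues) <= 0):
            raise ValueError("test_hues must be strictly increasing")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_test_bluer <= n_trials")

    @property
    def n_total(self) -> int:
        return int(self.n_trials.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.n_test_bluer / np.maximum(self.n_trials, 1)


@dataclass(frozen=True)
class PmfFit:
    """A fitted cumulative-normal psychometric function."""

    location: float
    spread: float
    lapse: float
    log_likelihood: float
    n_total: int
    converged: bool
    cell: CellKey | None = None


def pool_and_bin(trials: pd.DataFrame) -> dict[CellKey, BinnedResponses]:
    """Pool trials (across phases) and bin responses by exact test hue.

    Returns one :class:`BinnedResponses` per (condition, reference hue,
    reference background) cell.  Counts are conserved: summed over cells
    and bins they equal the number of input rows.
    """
    if trials.empty:
        raise EmptyCellError("trial table is empty")
    out: dict[CellKey, BinnedResponses] = {}
    grouped = trials.groupby(
        ["condition", "reference_hue", "reference_background"], sort=True
    )
    for (cond, ref, background), df in grouped:
        cell = CellKey(str(cond), float(ref), str(background))
        agg = (
            df.groupby("test_hue", sort=True)["response_test_bluer"]
            .agg(["count", "sum"])
            .reset_index()
        )
        out[cell] = BinnedResponses(
            test_hues=agg["test_hue"].to_numpy(dtype=float),
            n_trials=agg["count"].to_numpy(dtype=np.int64),
            n_test_bluer=agg["sum"].to_numpy(dtype=np.int64),
            cell=cell,
        )
    return out


def _nll(theta: np.ndarray, x: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    loc, spread, lapse = theta
    p = lapse / 2.0 + (1.0 - lapse) * ndtr((x - loc) / spread)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def fit_pmf(binned: BinnedResponses, *, lapse_max: float = 0.05) -> PmfFit:
    """Maximum-likelihood cumulative-normal fit to binned 2AFC responses.

    Requires at least three distinct test hues and both response types in
    the pooled data; otherwise the location/spread are not identifiable and
    a :class:`NonIdentifiableError` is raised.  Optimization restarts from
    a fixed 3x3 grid of (location, spread) initial values, so the fit is a
    deterministic function of the data.
    """
    x, n, k = binned.test_hues, binned.n_trials, binned.n_test_bluer
    if x.size < 3:
        raise NonIdentifiableError(
            f"need >= 3 distinct test hues, got {x.size} (cell={binned.cell})"
        )
    total_k = int(k.sum())
    if total_k == 0 or total_k == binned.n_total:
        raise NonIdentifiableError(
            "all responses identical; psychometric location is unbounded "
            f"(cell={binned.cell}, n={binned.n_total})"
        )

    span = float(x[-1] - x[0])
    p_obs = binned.proportions
    loc_starts = (
        float(x[int(np.argmin(np.abs(p_obs - 0.5)))]),
        float(np.average(x, weights=n)),
        float(0.5 * (x[0] + x[-1])),
    )
    spread_starts = (span / 8.0, span / 3.0, span)
    bounds = [
        (x[0] - span, x[-1] + span),
        (span * 1e-3, span * 10.0),
        (0.0, lapse_max),
    ]

    best = None
    for loc0 in loc_starts:
        for spread0 in spread_starts:
            res = minimize(
                _nll,
                x0=np.array([loc0, spread0, 0.01]),
                args=(x, n.astype(float), k.astype(float)),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res

    loc, spread, lapse = (float(v) for v in best.x)
    return PmfFit(
        location=loc,
        spread=spread,
        lapse=lapse,
        log_likelihood=-float(best.fun),
        n_total=binned.n_total,
        converged=bool(best.success) and math.isfinite(best.fun),
        cell=binned.cell,
    )


def _require_converged(fit: PmfFit) -> None:
    if not fit.converged:
        raise FitNotConvergedError(f"fit did not converge (cell={fit.cell})")


def pse(fit: PmfFit) -> float:
    """Point of subjective equality: 50th percentile of the underlying normal."""
    _require_converged(fit)
    return fit.location


def threshold(fit: PmfFit) -> float:
    """Discrimination threshold: 75th minus 50th percentile (= spread * Z75)."""
    _require_converged(fit)
    return fit.spread * Z75


def precision(fit: PmfFit) -> float:
    """Precision: reciprocal of the discrimination threshold."""
    return 1.0 / threshold(fit)


def bias(fit: PmfFit, baseline_fit: PmfFit) -> float:
    """Perceptual bias: condition PSE minus baseline PSE for the same cell.

    Positive values are shifts toward bluer hues.  Both fits must share the
    reference hue and reference background; subtracting the baseline PSE
    removes any constant response bias.
    """
    _require_converged(fit)
    _require_converged(baseline_fit)
    if fit.cell is not None and baseline_fit.cell is not None:
        same = (
            fit.cell.reference_background == baseline_fit.cell.reference_background
            and math.isclose(fit.cell.reference_hue, baseline_fit.cell.reference_hue,
                             rel_tol=0.0, abs_tol=1e-9)
        )
        if not same:
            raise CellMismatchError(
                f"cells differ: {fit.cell} vs {baseline_fit.cell}"
            )
    return pse(fit) - pse(baseline_fit)


def bootstrap_ci(
    binned: BinnedResponses,
    fit: PmfFit,
    *,
    n_boot: int = 999,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap percentile CIs for location and spread.

    Responses are resampled from the fitted curve at the observed test hues
    and refitted; diagnostics only, not part of the analysis chain.
    """
    _require_converged(fit)
    rng = np.random.default_rng(seed)
    p_fit = fit.lapse / 2.0 + (1.0 - fit.lapse) * ndtr(
        (binned.test_hues - fit.location) / fit.spread
    )
    locs, spreads = [], []
    for _ in range(n_boot):
        k = rng.binomial(binned.n_trials, p_fit)
        # guard against degenerate resamples
        if k.sum() == 0 or k.sum() == binned.n_total:
            continue
        try:
            boot = fit_pmf(
                BinnedResponses(binned.test_hues, binned.n_trials, k, cell=binned.cell)
            )
        except NonIdentifiableError:
            continue
        locs.append(boot.location)
        spreads.append(boot.spread)
    lo, hi = (1.0 - level) / 2.0 * 100.0, (1.0 + level) / 2.0 * 100.0
    return {
        "location": tuple(np.percentile(locs, [lo, hi])),
        "spread": tuple(np.percentile(spreads, [lo, hi])),
    }
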