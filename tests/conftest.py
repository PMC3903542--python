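"""Shared fixtures: canonical designs and a Monte-Carlo PSE estimator."""

from __future__ import annotations

import numpy as np
import pytest

from huemem import (
    BayesianObserver,
    BinnedResponses,
    ObserverParams,
    StimulusPresentation,
    fit_pmf,
)

REFERENCE_HUES = (2.9, 3.2, 3.5)


@pytest.fixture
def reference_hues():
    return REFERENCE_HUES


@pytest.fixture
def default_params():
    return ObserverParams()


def simulate_pse(
    params: ObserverParams,
    *,
    reference_hue: float,
    reference_background: str = "gray",
    test_background: str = "gray",
    delayed: bool = False,
    levels,
    n_per_level: int = 2000,
    seed: int = 0,
):
    """Estimate a PSE by brute-force simulation at fixed test levels.

    Runs ``n_per_level`` independent trials of the observer at each test
    hue and fits the cumulative normal; returns the fit.  This is the
    Monte-Carlo oracle used to check closed-form predictions of the
    observer model.
    """
    observer = BayesianObserver(params)
    rng = np.random.default_rng(seed)
    reference = StimulusPresentation(
        reference_hue, reference_background, interval="first", remembered=delayed
    )
    levels = np.sort(np.asarray(levels, dtype=float))
    counts = []
    for level in levels:
        test = StimulusPresentation(float(level), test_background, interval="second")
        counts.append(sum(observer(reference, test, rng) for _ in range(n_per_level)))
    binned = BinnedResponses(
        test_hues=levels,
        n_trials=np.full(levels.size, n_per_level),
        n_test_bluer=np.asarray(counts),
    )
    return fit_pmf(binned)


@pytest.fixture
def pse_estimator():
    return simulate_pse
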