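"""A quantitative Bayesian observer for two-alternative hue judgments.

The observer judges which of two center patches ("reference" and "test")
appears bluer.  Hue is parameterized as an angle on the equiluminant hue
circle (radians, larger = bluer); because the stimuli span only a small arc
of the circle, hue is treated as an unwrapped real line and no circular
statistics are used.

The generative model, per trial and per stimulus interval:

1. A noisy hue signal is drawn around the patch's nominal hue with standard
   deviation ``sigma_sensory``; if the interval has to be retained in
   short-term memory, the width is multiplied by ``kappa_memory >= 1``.
2. The background color carries the illuminant information.  A noisy
   illuminant signal is drawn around the background's nominal illuminant
   value (0 for the gray background, ``illuminant_shift_blue`` for the blue
   background) with width ``sigma_illuminant`` (again widened by
   ``kappa_memory`` for a remembered interval), and combined with a Gaussian
   illuminant prior to yield the inferred illuminant.  When both intervals
   are simultaneous views of the same background, a single shared illuminant
   estimate is used (one scene, one estimate); otherwise the two intervals
   produce independent estimates.
3. The inferred surface reflectance is the posterior combination of
   (hue signal − inferred illuminant) with a Gaussian reflectance prior.

The observer reports "test bluer" when the inferred test reflectance exceeds
the inferred reference reflectance plus comparison noise and a constant
response criterion; with probability ``lapse_rate`` it guesses at random.

Every posterior here is the conjugate-Gaussian posterior mean, so the key
quantity is the shrinkage weight ``w = prior_sigma^2 / (prior_sigma^2 +
likelihood_sigma^2)``: the broader the likelihood (the noisier the signal),
the more the prior pulls the estimate toward its mean.  This single
mechanism produces the central-tendency bias of remembered hues, the
context bias across gray/blue backgrounds, and — because a remembered
background's illuminant estimate also shrinks toward the illuminant prior —
the underadditivity of the two effects when combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "GRAY",
    "BLUE",
    "ObserverParams",
    "StimulusPresentation",
    "BayesianObserver",
    "posterior_estimate",
    "shrinkage_weight",
    "simulate_response",
    "params_for_block",
]

GRAY = "gray"
BLUE = "blue"

Background = Literal["gray", "blue"]


def shrinkage_weight(prior_sigma: float, likelihood_sigma: float) -> float:
    """Weight given to the signal in a conjugate-Gaussian posterior mean.

    ``w = prior_sigma**2 / (prior_sigma**2 + likelihood_sigma**2)``.
    An infinite (uniform) prior gives ``w = 1``; an infinitely noisy signal
    gives ``w = 0``.
    """
    if not likelihood_sigma > 0:
        raise InvalidParameterError(
            f"likelihood_sigma must be > 0, got {likelihood_sigma!r}"
        )
    if not prior_sigma > 0:
        raise InvalidParameterError(f"prior_sigma must be > 0, got {prior_sigma!r}")
    if math.isinf(prior_sigma):
        return 1.0
    if math.isinf(likelihood_sigma):
        return 0.0
    ps2 = prior_sigma * prior_sigma
    return ps2 / (ps2 + likelihood_sigma * likelihood_sigma)


def posterior_estimate(
    signal: float,
    likelihood_sigma: float,
    prior_mean: float,
    prior_sigma: float,
) -> float:
    """Posterior-mean estimate of a Gaussian quantity from one noisy signal.

    Returns ``w * signal + (1 - w) * prior_mean`` with ``w`` from
    :func:`shrinkage_weight`.  The estimate always lies between the signal
    and the prior mean (inclusive).
    """
    w = shrinkage_weight(prior_sigma, likelihood_sigma)
    return w * signal + (1.0 - w) * prior_mean


@dataclass(frozen=True)
class StimulusPresentation:
    """One patch as presented on one trial.

    Parameters
    ----------
    hue:
        Nominal hue angle in radians; larger = bluer.
    background:
        ``"gray"`` or ``"blue"`` — the field behind this patch.
    interval:
        ``"first"`` or ``"second"``.  In delay conditions the reference is
        always shown in the first interval.
    remembered:
        True iff this is the first interval of a delay condition, i.e. the
        percept must be retained across the retention interval.
    """

    hue: float
    background: Background
    interval: Literal["first", "second"] = "second"
    remembered: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.hue):
            raise InvalidParameterError(f"hue must be finite, got {self.hue!r}")
        if self.background not in (GRAY, BLUE):
            raise InvalidParameterError(
                f"background must be 'gray' or 'blue', got {self.background!r}"
            )
        if self.interval not in ("first", "second"):
            raise InvalidParameterError(
                f"interval must be 'first' or 'second', got {self.interval!r}"
            )
        if self.remembered and self.interval != "first":
            raise InvalidParameterError("a remembered stimulus must be in the first interval")


def _check_sigma(name: str, value: float, allow_inf: bool = False, allow_zero: bool = False) -> None:
    ok = value > 0 or (allow_zero and value == 0)
    if not ok or (math.isinf(value) and not allow_inf):
        raise InvalidParameterError(f"{name} must be positive{' or inf' if allow_inf else ''}, got {value!r}")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the Bayesian observer.  All hue quantities in radians.

    Defaults describe a moderately noisy observer whose memory doubles the
    sensory noise and whose priors are informative enough to produce a
    visible central-tendency bias and clearly subadditive joint biases; see
    docs/methods.md for the reasoning behind each value.
    """

    #: width of the sensory hue likelihood for a simultaneously viewed patch
    sigma_sensory: float = 0.09
    #: multiplier (>= 1) on likelihood widths for a remembered interval
    kappa_memory: float = 2.0
    #: reflectance (surface hue) prior location
    prior_reflectance_mean: float = 3.2
    #: reflectance prior width; ``inf`` = uniform prior
    prior_reflectance_sigma: float = 0.35
    #: illuminant prior location (on the gray=0 / blue=shift axis)
    prior_illuminant_mean: float = 0.2
    #: illuminant prior width; ``inf`` = uniform prior
    prior_illuminant_sigma: float = 0.15
    #: inferred-illuminant offset of the blue background relative to gray
    illuminant_shift_blue: float = 0.4
    #: width of the illuminant likelihood for a simultaneously viewed background
    sigma_illuminant: float = 0.15
    #: comparison (decision) noise added to the reflectance difference
    sigma_decision: float = 0.05
    #: probability of a stimulus-independent random response
    lapse_rate: float = 0.02
    #: constant additive bias toward responding "test bluer" (task wording)
    response_criterion: float = 0.02

    def __post_init__(self) -> None:
        _check_sigma("sigma_sensory", self.sigma_sensory)
        _check_sigma("sigma_illuminant", self.sigma_illuminant)
        _check_sigma("prior_reflectance_sigma", self.prior_reflectance_sigma, allow_inf=True)
        _check_sigma("prior_illuminant_sigma", self.prior_illuminant_sigma, allow_inf=True)
        _check_sigma("sigma_decision", self.sigma_decision, allow_zero=True)
        if not self.kappa_memory >= 1:
            raise InvalidParameterError(f"kappa_memory must be >= 1, got {self.kappa_memory!r}")
        if not 0 <= self.lapse_rate < 0.5:
            raise InvalidParameterError(f"lapse_rate must be in [0, 0.5), got {self.lapse_rate!r}")
        for name in ("prior_reflectance_mean", "prior_illuminant_mean",
                     "illuminant_shift_blue", "response_criterion"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")

    def nominal_illuminant(self, background: str) -> float:
        """Nominal illuminant value attributed to a background.

        Only the gray/blue difference is identifiable; gray is fixed at 0.
        """
        if background == GRAY:
            return 0.0
        if background == BLUE:
            return self.illuminant_shift_blue
        raise InvalidParameterError(f"unknown background {background!r}")


class BayesianObserver:
    """Callable wrapper: ``observer(reference, test, rng) -> bool``."""

    def __init__(self, params: ObserverParams):
        if not isinstance(params, ObserverParams):
            raise InvalidParameterError("params must be an ObserverParams instance")
        self.params = params

    def __call__(
        self,
        reference: StimulusPresentation,
        test: StimulusPresentation,
        rng: np.random.Generator,
    ) -> bool:
        return simulate_response(self.params, reference, test, rng)


def _inferred_illuminant(
    params: ObserverParams,
    presentation: StimulusPresentation,
    rng: np.random.Generator,
) -> float:
    kappa = params.kappa_memory if presentation.remembered else 1.0
    width = params.sigma_illuminant * kappa
    signal = params.nominal_illuminant(presentation.background) + rng.normal(0.0, width)
    return posterior_estimate(
        signal, width, params.prior_illuminant_mean, params.prior_illuminant_sigma
    )


def _inferred_reflectance(
    params: ObserverParams,
    presentation: StimulusPresentation,
    illuminant: float,
    rng: np.random.Generator,
) -> float:
    kappa = params.kappa_memory if presentation.remembered else 1.0
    width = params.sigma_sensory * kappa
    signal = presentation.hue + rng.normal(0.0, width)
    return posterior_estimate(
        signal - illuminant, width, params.prior_reflectance_mean,
        params.prior_reflectance_sigma,
    )


def simulate_response(
    params: ObserverParams,
    reference: StimulusPresentation,
    test: StimulusPresentation,
    rng: np.random.Generator,
) -> bool:
    """Simulate one 2AFC response; True means "test judged bluer".

    The observer infers an illuminant per scene view and a reflectance per
    patch (see module docstring), then picks the patch whose inferred
    reflectance is bluer, subject to comparison noise, a constant response
    criterion, and lapses.  P(test bluer) is non-decreasing in the test hue
    with everything else fixed.
    """
    if not isinstance(params, ObserverParams):
        raise InvalidParameterError("params must be an ObserverParams instance")

    if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
        return bool(rng.random() < 0.5)

    # Simultaneous presentations on the same background are one scene view
    # and share one illuminant estimate (which then cancels exactly).
    shared_scene = (
        not reference.remembered
        and not test.remembered
        and reference.background == test.background
    )
    illum_ref = _inferred_illuminant(params, reference, rng)
    illum_test = illum_ref if shared_scene else _inferred_illuminant(params, test, rng)

    refl_ref = _inferred_reflectance(params, reference, illum_ref, rng)
    refl_test = _inferred_reflectance(params, test, illum_test, rng)

    noise = rng.normal(0.0, params.sigma_decision) if params.sigma_decision > 0 else 0.0
    return bool(refl_test - refl_ref + noise + params.response_criterion > 0.0)


def params_for_block(
    params: ObserverParams,
    block_background: str,
    reference_hues,
    *,
    distractors: bool = False,
    distractor_offset: float = 0.2,
) -> ObserverParams:
    """Re-center the observer's priors on a block's stimulus statistics.

    Both priors are assumed to update to the estimates gathered within a
    block of trials: the reflectance prior settles on the mean displayed hue
    and the illuminant prior on the mean nominal illuminant of the block's
    backgrounds.  Prior widths are left untouched.

    - reflectance prior mean = mean of the block's reference hues; when
      distractor patches (offset ``distractor_offset`` toward smaller hue
      angles) are shown during the delay, they make up half of the displayed
      patches and pull the mean by half the offset;
    - illuminant prior mean = 0 for a gray block, ``illuminant_shift_blue``
      for a blue block, and the midpoint for an asymmetric block.
    """
    hues = np.asarray(list(reference_hues), dtype=float)
    if hues.size == 0:
        raise InvalidParameterError("reference_hues must be non-empty")
    refl_mean = float(hues.mean())
    if distractors:
        refl_mean -= 0.5 * distractor_offset
    if block_background == GRAY:
        illum_mean = 0.0
    elif block_background == BLUE:
        illum_mean = params.illuminant_shift_blue
    elif block_background == "asymmetric":
        illum_mean = 0.5 * params.illuminant_shift_blue
    else:
        raise InvalidParameterError(f"unknown block background {block_background!r}")
    return replace(
        params,
        prior_reflectance_mean=refl_mean,
        prior_illuminant_mean=illum_mean,
    )
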