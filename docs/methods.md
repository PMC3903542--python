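# Methods

This note documents the generative model, the simulated procedure, the
estimation choices, and the limits of what the synthetic tests can show.

## The observer model

The observer performs 2AFC "which appears bluer" judgments on hue angles
from the equiluminant circle.  Because the three references and all test
levels span well under a radian, hue is treated as an unwrapped real line;
no circular statistics are used anywhere, and this convention is assumed by
every module.

Per trial and per stimulus interval the observer:

1. draws a hue signal ~ Normal(hue, (κ·σ_s)²), with κ = `kappa_memory` if
   the interval must be retained across the delay and κ = 1 otherwise;
2. draws an illuminant signal ~ Normal(I_bg, (κ·σ_i)²), where I_bg is 0 for
   the gray background and `illuminant_shift_blue` (Δ) for the blue one —
   only the gray/blue difference is identifiable, so gray is pinned at 0 —
   and forms the posterior-mean illuminant estimate under a Gaussian prior
   (mean μ_I, width σ_I,prior).  Two simultaneous patches on the *same*
   background are one scene view and share a single illuminant draw, which
   then cancels from the comparison; asymmetric or delayed intervals each
   get an independent estimate;
3. forms the posterior-mean reflectance of (hue signal − illuminant
   estimate) under a Gaussian reflectance prior (μ_R, σ_R,prior);
4. answers "test bluer" iff refl(test) − refl(ref) + Normal(0, σ_d²) +
   `response_criterion` > 0, and with probability `lapse_rate` instead
   answers at random.

All posteriors are conjugate-Gaussian posterior means,
w·signal + (1−w)·μ with w = σ²_prior/(σ²_prior + σ²_lik).  This is the
minimal quantitative instantiation that produces every qualitative effect
of interest and admits closed-form oracles; the exact closed form for the
memory PSE, used as a test oracle, is

    PSE(r) = μ_R + (w_mem / w_test)·(r − μ_R),

with w evaluated at the memory-widened (κσ_s) and simultaneous (σ_s)
likelihood widths respectively.  Note the prior acts on *both* intervals;
only the width modulation by κ distinguishes them.  Whether a real
observer's prior also acts on the simultaneously visible test is an open
empirical question; the symmetric treatment is this package's choice.

### Default parameters (the simulated study conditions)

| parameter | default | why |
| --- | --- | --- |
| reference hues | 2.9, 3.2, 3.5 rad | three similar green-to-blue-green hues, ~2–3 JNDs apart, close enough to discourage verbal labeling |
| σ_s (`sigma_sensory`) | 0.09 rad | gives baseline thresholds ≈ 0.09 rad, of the order of the ~0.13 rad average JND implied by the distractor offset (0.2 rad ≈ 1.5 JND) |
| κ (`kappa_memory`) | 2.0 | memory roughly doubles sensory noise; yields memory/no-memory threshold ratios ≈ 1.3–1.4 |
| σ_R,prior (`prior_reflectance_sigma`) | 0.35 rad | informative enough for a clear central tendency (shrinkage ratio w_mem/w_test ≈ 0.84, slope ≈ −0.16) without flattening the stimulus range |
| Δ (`illuminant_shift_blue`) | 0.4 rad | a strong, clearly visible context manipulation: constancy bias ≈ Δ·w_I ≈ 0.2 rad ≈ 2 JND |
| σ_i (`sigma_illuminant`) | 0.15 rad | background estimates are less precise than patch estimates; two independent illuminant estimates then measurably raise asymmetric-condition thresholds |
| σ_I,prior (`prior_illuminant_sigma`) | 0.15 rad | comparable to the illuminant likelihood, so a remembered background (κσ_i = 0.3) shrinks substantially toward the prior — the driver of subadditivity |
| σ_d (`sigma_decision`) | 0.05 rad | small comparison noise |
| `lapse_rate` | 0.02 | typical attentive-observer lapse; fits bound lapse to [0, 0.05] |
| `response_criterion` | 0.02 rad | small constant "bluer" response bias from task wording; identical across conditions, so baseline subtraction cancels it |

### Block-level priors

Both priors are assumed to settle on the statistics of the current block:
the reflectance prior mean is the mean displayed hue (the mean reference
hue; in distractor blocks the two distractor patches are half of the
displayed patches and pull it by half the 0.2 rad distractor offset), and
the illuminant prior mean is the mean nominal illuminant of the block's
backgrounds (0 in a gray block, Δ in a blue block, Δ/2 in an asymmetric
block).  There is no trial-by-trial updating within a block.  This
block-level updating matters: with a fixed, global illuminant prior the
memory condition would absorb the same illuminant shrinkage as the joint
condition and the effects would compose almost additively.

### Why subadditivity emerges

In the joint condition the remembered reference background's illuminant
estimate shrinks toward the prior at Δ/2, so the inferred illuminant
difference between the two fields is smaller than in the simultaneous
constancy condition — the contexts become functionally more similar, and
the measured joint bias falls short of the prediction composed from the
pure effects.  Under the defaults the reference-on-blue cells are more
strongly subadditive than reference-on-gray cells (the reflectance
shrinkage factor multiplies the reference's illuminant correction); the
package reports per-cell indices, so this asymmetry is visible rather than
averaged away.

## Simulated procedure

- **Staircases.**  The convergence rule is a Kaernbach-style weighted
  up–down: the level always moves down after "test bluer" and up
  otherwise, with up/down steps in the ratio p/(1−p) so the equilibrium is
  the target percentile (20% or 80%).  Four staircases per cell (two
  targets × starting points ±0.3 rad from the reference), 20 trials each,
  interleaved in a seeded random order in which every staircase advances
  exactly 20 times.  The base step starts at 3× the final step (0.06 rad)
  and is halved at each of the first two reversals, floored at the final
  step.  The asymptotic target rule is standard; the particular step
  schedule is this package's choice.
- **MOCS.**  Five levels, evenly spaced in hue between the 1st and 99th
  percentiles of the staircase-phase fit (operationalizing "roughly 0 and
  100% selection probability"), 10 repetitions per level per cell by
  default.  Levels are refreshed for a cell when an extreme level's
  observed proportion lies strictly inside (0.25, 0.75) — a conservative,
  automatable criterion for "range adjusted when necessary".  The second
  pass itself is always collected (doubling the MOCS data per cell); only
  the re-derivation of its levels is conditional on that trigger.
- **Counts.**  Uniform-background staircase block: 240 trials; asymmetric:
  480.  Symmetric conditions are run one background per block (a gray and
  a blue block per condition), which is what those counts imply.
- **Timing.**  The 500 ms presentations and 2 s delay have no real-time
  counterpart in the simulation; delay enters only through the
  remembered-interval flag, and durations are design metadata.

## Estimation

- **Fit.**  p(x) = λ/2 + (1−λ)·Φ((x−loc)/spread), maximum likelihood on
  responses binned by exact test hue, staircase and MOCS phases pooled.
  λ ∈ [0, 0.05] with a single symmetric lapse.  Optimization is L-BFGS-B
  from a fixed 3×3 grid of (location, spread) starts — deterministic, no
  seed dependence; an exhaustive grid search serves as the oracle in
  tests.  Fits with <3 distinct hues or all-identical responses are
  refused as non-identifiable and reported, not dropped.
- **Derived quantities.**  PSE and threshold are read off the *underlying*
  normal (PSE = location; threshold = spread·Φ⁻¹(0.75)), not the
  lapse-scaled curve; this keeps threshold = spread·z₀.₇₅ exact.  Whether
  thresholds should instead be computed on the lapse-scaled curve is a
  convention choice; the underlying-normal convention is declared here.
  Bias = PSE − baseline PSE for the same reference and reference
  background.  Parametric bootstrap CIs (999 resamples, seeded) are
  available as diagnostics only.
- **Independence.**  C is the piecewise-linear interpolant through the
  three (r, c(r)) nodes; predictions extrapolate linearly from the end
  segments, with a logged warning beyond 4% of the reference range and a
  hard error beyond 10% (a cap that prevents silent nonsense on noisy
  synthetic data).  NI = (|m|−|p|)/(|m|+|p|) is the simplest bounded index
  with the required sign semantics; it is undefined when both biases are
  zero.  The summary ratio is mean|measured| / mean|predicted| over cells
  (per-cell ratios are unstable when a predicted bias is near zero).  The
  sign test is the exact binomial tail; correlations are Pearson with
  optional, logged outlier exclusion.  Mixed-effects ANOVAs are out of
  scope: they are routine statistics, delegated to standard tools.

## What the synthetic data do and do not show

The generator emulates: three references on a small hue arc, binary
"bluer" responses, context-induced shifts from gray vs. blue backgrounds,
memory-induced precision loss and central tendency, block-wise prior
adaptation, and yellow-shifted distractors during the delay.  It does not
emulate: real chromatic rendering (no CIELAB/monitor model — chromaticity
tables from real apparatus are documentation, not simulation inputs),
spatial structure (checkerboards, color induction mechanisms), sequential
effects within a block, observer heterogeneity beyond parameter choice, or
non-Gaussian response processes.  Passing tests therefore validate the
*pipeline* — that the procedure and estimators recover what this model
family generates, and that the stated qualitative signatures follow from
the stated assumptions — not any claim about human observers.

## Problem sizes

The test suite and acceptance script choose sizes that make Monte-Carlo
error small relative to the effects: parameter recovery uses 100
replicates of 5×200 trials; the additivity null runs 10⁴ trials per cell
(MOCS repetitions 1984 on top of the 80 staircase trials); the
subadditivity check pools 12 joint cells from two replicate observers at
100 MOCS repetitions; the acceptance script's pipeline runs use 60
repetitions per level.  These are the package's standard desk-scale runs;
all are seeded and complete in seconds to a few minutes.

## Known limitations

- The conjugate-Gaussian instantiation is one of many models consistent
  with the qualitative framework; in particular the choice that the
  reflectance prior acts symmetrically on both intervals, and the
  block-average prior locations, are modeling decisions, not measured
  facts.
- Hue is unwrapped; the package must not be used with stimulus sets
  spanning a large arc of the hue circle.
- The staircase decision rule's step schedule is fixed (ratio 4:1 for the
  80%/20% targets); other schedules converge to the same targets but give
  different small-sample level distributions.
- `select_mocs_levels` assumes the staircase-phase fit is sane; with very
  few staircase trials the second MOCS pass exists precisely to recover
  from a bad first range, but pathological observers can still defeat it
  (such cells end up in the failure list).
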