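"""Two-phase data collection: interleaved staircases, then constant stimuli.

Runs one uniform-background staircase block (240 trials), fits the pooled
staircase data per cell, picks five MOCS levels spanning the fit, and runs
a MOCS block.
"""

from huemem import (
    BayesianObserver,
    Condition,
    ObserverParams,
    fit_pmf,
    pool_and_bin,
    run_mocs_block,
    run_staircase_block,
    select_mocs_levels,
)

observer = BayesianObserver(ObserverParams())
condition = Condition("symmetric_gray")
refs = (2.9, 3.2, 3.5)

stair = run_staircase_block(observer, condition, refs, seed=1)
print(f"staircase block: {len(stair)} trials "
      "(4 staircases x 20 trials x 3 references)")

levels = {}
for cell, binned in pool_and_bin(stair).items():
    fit = fit_pmf(binned)
    levels[(cell.reference_hue, cell.reference_background)] = select_mocs_levels(fit)
    print(f"  ref {cell.reference_hue:.1f}: staircase PSE {fit.location:.3f} rad -> "
          f"MOCS levels {['%.2f' % v for v in levels[(cell.reference_hue, cell.reference_background)]]}")

mocs = run_mocs_block(observer, condition, levels, repetitions=10, seed=2)
print(f"MOCS block: {len(mocs)} trials (5 levels x 10 reps x 3 refs)")
print("\nThe staircases concentrate trials near each reference's point of "
      "subjective equality; the MOCS levels span its 1st-99th percentiles.")
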