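"""The full pipeline: simulate -> fit -> independence analysis.

Runs all four blank conditions for one synthetic observer and prints the
headline numbers.  Writing `outdir` arguments to `huemem.run` (or using
the `huemem run` CLI) additionally saves trial tables, fit tables, and
figures.
"""

from huemem import ObserverParams, PipelineConfig, analyze, simulate

config = PipelineConfig(
    observer=ObserverParams(),
    conditions=("baseline", "constancy", "memory", "joint"),
    mocs_repetitions=40,
    mocs_second_pass=False,
    seed=7,
)
tables = simulate(config)
print({name: len(t) for name, t in tables.items()}, "trials per condition")

result = analyze(tables)
print(f"\nfit {len(result.fits)} cells; {len(result.failures)} failures")
print("\ncentral-tendency slopes (memory bias vs reference hue):")
print(result.slopes.to_string(index=False))
print("\nthreshold ratios:", {k: round(v, 2) for k, v in result.threshold_ratios.items()})
print("\nindependence:", result.independence["blank"])
print("\nA negative mean non-additivity index (measured joint bias smaller "
      "than predicted) reproduces the headline finding: constancy and memory "
      "do not combine additively.  With only 6 cells the sign test is weak; "
      "scripts/acceptance.py pools 12 cells from two replicate observers.")
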