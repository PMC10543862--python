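"""End-to-end method comparison with per-array axis collocation.

Simulates the full study: 50 arrays measured by a "manual" reference and an
"auto" candidate whose mid-modiolar axis is offset by ~0.3 mm per array,
compares the methods before and after collocation, and writes plots + JSON
into pipeline_out/.
"""

from modioloc import (
    SpiralCohortConfig,
    generate_cohort,
    generate_interrater_pair,
    render_outputs,
    run_apriori,
    run_comparison,
)

config = SpiralCohortConfig(seed=11)

rater_a, rater_b = generate_interrater_pair(config)
criteria = run_apriori(rater_a, rater_b, seed=config.seed)
print(f"a-priori criteria: +/-{criteria.precision_emd_mm:.3f} mm EMD, "
      f"+/-{criteria.precision_adoi_deg:.2f} deg aDOI")

cohort = generate_cohort(config)
report = run_comparison(list(cohort.auto), list(cohort.manual), criteria,
                        seed=config.seed)

for p, unit in (("EMD", "mm"), ("aDOI", "deg")):
    pre, post = report.pre[p], report.post[p]
    print(f"[{p}] bias {pre.bias:+.3f} {unit} "
          f"(criterion +/-{criteria.precision_for(p):.3f}: "
          f"{'PASS' if report.verdicts[p] else 'FAIL'})")
    print(f"  LoA half-width {((pre.loa_high - pre.loa_low) / 2):.3f} -> "
          f"{((post.loa_high - post.loa_low) / 2):.3f} {unit} "
          f"({report.loa_reduction_percent[p]:.1f}% reduction)")

paths = render_outputs(report, "pipeline_out")
print("wrote:", *paths, sep="\n  ")
# Collocation removes the systematic axis-offset component of the differences;
# what remains is close to the interrater noise floor.
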