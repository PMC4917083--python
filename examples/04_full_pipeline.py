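"""End-to-end run: simulate, fit, analyze, and write a report.

Uses a reduced cohort and short chains so the example finishes in well
under a minute; the persisted directory contains every table as CSV plus
a markdown report and the ground-truth comparison.
"""

import tempfile
from pathlib import Path

import taplearn as tl
from taplearn.curvefit import McmcConfig

out = Path(tempfile.mkdtemp(prefix="taplearn_run_"))
config = tl.AnalysisConfig(
    scenario="main",
    overrides={"n_per_cell": 2},
    seed=11,
    out_dir=str(out),
    mcmc=McmcConfig(n_iterations=1500, n_burnin=500, grouping="piano_age"),
)
bundle = tl.run_full(config)

print(f"run directory: {out}")
for p in sorted(out.iterdir()):
    print("  ", p.name)

print("\nestimated vs configured cell gains (raw score means):")
print(bundle.gain_recovery.to_string(index=False, float_format="%.2f"))
print("\nThe estimated gains track the generator's configured cell means; "
      "discrepancies reflect the within-cell noise at n = 2 per cell.")
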