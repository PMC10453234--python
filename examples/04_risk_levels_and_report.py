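"""Classify risks into warning levels and export a report.

Applies the warning threshold (default 1.0) to composite risks, prints the
distribution summary, and writes the assignments CSV + summary JSON that
the visual front end of such a system would consume.
"""

import tempfile

from tabgra import (
    GeneratorConfig,
    classify_risks,
    export_report,
    simulate_dataset,
    summarize_risks,
)

dataset = simulate_dataset(GeneratorConfig(n_samples=48, seed=9))
risks = dataset.true_risks

assignments = classify_risks(risks, dataset.clean_matrix.samples, threshold=1.0)
summary = summarize_risks(risks, threshold=1.0)

print(f"n={summary.n}  min {summary.minimum:.3f}  Q1 {summary.q1:.3f}  "
      f"median {summary.median:.3f}  Q3 {summary.q3:.3f}  max {summary.maximum:.3f}")
for level, share in summary.proportions.items():
    print(f"  {level:6s} {share:6.1%}")

with tempfile.TemporaryDirectory() as out:
    paths = export_report(assignments, summary, out, plots=True,
                          hazard=dataset.gra.hazard,
                          indicator_names=dataset.clean_matrix.indicator_names)
    print("\nwrote:", ", ".join(sorted(paths)))

# Green/yellow/red levels mean: below half the threshold, between half and
# the threshold, above it.  The Q3 line reads like 'three quarters of the
# samples are below this risk'.
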