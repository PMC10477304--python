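"""Generate a synthetic paired intervention study with known ground truth.

Builds a two-arm cohort, the full 2,803-feature multi-omic panel with a
small fraction of planted pre->post shifts, and diet logs with planted
exclusion-rule violations.
"""

import microdyn as md

cohort = md.generate_cohort(n_per_arm=50, seed=1)
print(f"cohort: {len(cohort)} participants, "
      f"{(cohort['arm'] == 'PPT').sum()} PPT / {(cohort['arm'] == 'MED').sum()} MED")

table, truth = md.generate_paired_features(cohort, md.PanelSpec(), seed=2)
print(f"feature table: {table.n_samples} samples x {table.n_features} features")
print(f"planted effects: {len(truth.affected_features)} features "
      "(these are the features a perfect differential test would recover)")

logs, diet_truth = md.generate_diet_logs(
    cohort, n_days=28, violation_rates={"low_calories": 0.05}, seed=3
)
print(f"diet logs: {len(logs)} participant-days, "
      f"{len(diet_truth.violating_days)} planted rule violations")
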