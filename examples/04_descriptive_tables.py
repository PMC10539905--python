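"""Descriptive tables: baseline prevalence, chi-squared, transitions.

Stages a synthetic cohort's raw measurements, tabulates baseline stage
prevalence by sex with a Pearson chi-squared test, and summarises
observed wave-to-wave transitions including the pooled shares that
deteriorated (moved to a worse stage or died) or improved.
"""

import sarcolife as sl

cohort = sl.simulate_cohort(
    sl.SyntheticConfig(n_subjects=1200, seed=21), emit_raw_measures=True
)
staged, _ = sl.stage_table(cohort.measurements)
baseline = staged[staged.wave == 1]

tab = sl.prevalence_table(baseline, "sex")
tab.index = tab.index.map({sl.MAN: "man", sl.WOMAN: "woman"})
print("baseline stage prevalence by sex (counts and row %):")
print(tab.to_string())

chi2 = sl.chi_squared(tab[["n_1", "n_2", "n_3"]])
print(f"\nchi-squared = {chi2.statistic:.2f}, df = {chi2.df}, "
      f"p = {chi2.display_p()}")

summary = sl.transition_table(cohort.panel)
print("\nwave-to-wave transition counts (rows: origin, cols: destination):")
print(summary.counts.to_string())
print(f"\npooled deterioration: {summary.deterioration_pct:.1f}%  "
      f"improvement: {summary.improvement_pct:.1f}%")
print(
    "\nDeterioration counts any move to a higher-severity state or death;\n"
    "improvement any move to a lower-severity state (severity: no\n"
    "sarcopenia < possible < sarcopenia < death)."
)
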