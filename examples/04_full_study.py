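"""Run the full study replica end to end on a synthetic cohort.

Exclusion cascade -> exposure coding -> 8 per-cell fits -> life tables with
bootstrap CIs -> stratified analyses, rendered to CSV/JSON.  Uses a reduced
cohort and bootstrap so the example runs in about a minute.
"""

from healthspan import default_config
from healthspan.pipeline import AnalysisConfig, render_report, run_full_study

config = AnalysisConfig(
    simulation=default_config(n=6_000, seed=11),
    bootstrap_B=200,
    stratifiers=("smoking",),       # the full set: smoking, bmi, walking,
    run_frequency_analysis=False,   # depression, ncd_risk
)
report = run_full_study(config)

print("exclusion accounting:")
print(report.exclusion.as_frame().to_string(index=False))

table = report.count_exposure_table
cols = ["sex", "group", "n", "dfle", "dfle_lo", "dfle_hi", "tle"]
print("\nDFLE at 65 by sex and number of activities (years, 95% CI):")
print(table[cols].round(1).to_string(index=False))
# The default generator is calibrated to a ~5-year DFLE gap between the
# no-activity and three-activity groups in both sexes; estimates at this
# cohort size scatter around that gradient.

paths = render_report(report, "scratch/example_report")
print(f"\nwrote {len(paths)} files to scratch/example_report/")
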