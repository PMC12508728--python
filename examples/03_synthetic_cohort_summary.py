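"""Generate the default synthetic study cohort and reproduce the
descriptive change table.

Six participants x three drink volumes x eight markers; the table reports
the mean +- SD of each participant's maximum (signed) change from baseline
plus a paired t-test of baseline vs extremum values.
"""

from hydromark import generate_cohort, summarize_cohort
from hydromark.stats import summary_frame

cohort = generate_cohort(n_participants=6, seed=42)
rows = summarize_cohort(cohort)
df = summary_frame(rows)

print(df.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(
    "\nLiver T1 rises by roughly 58/60/90 ms and spleen T1 by 45/70/150 ms "
    "for 0.5/1.0/1.5 L (the calibration targets); stiffness (LSM) falls; "
    "PDFF changes stay within noise, so its p-values are typically > 0.05."
)
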