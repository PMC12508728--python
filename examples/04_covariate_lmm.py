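"""Mixed-model covariate analysis of fitted time constants.

Builds a cohort with a built-in drink-volume effect on the liver time
constant (tau scaled by volume), fits every session, and asks the
random-intercept mixed model whether volume predicts tau.
"""

from hydromark import GeneratorConfig, PipelineConfig, fit_lmm
from hydromark.cohort import generate_cohort
from hydromark.io import covariates_to_frame
from hydromark.pipeline import fit_cohort, fits_to_frame, lmm_table

# volume_effect_beta=1 multiplies liver tau by (volume / 1 L)
cfg = GeneratorConfig(volume_effect_beta=1.0)
cohort = generate_cohort(6, cfg=cfg, seed=7)

fits = fit_cohort(cohort)
fits_df = fits_to_frame(fits)
table = lmm_table(fits_df, covariates_to_frame(cohort), organ="liver", response="tau_s")

res = fit_lmm(table)
print("response: liver tau (s); fixed effects and Wald tests")
for k in res.coefficients:
    print(f"  {k:22s} coef={res.coefficients[k]:10.2f}  p={res.p_values[k]:.4f}")
print(f"random-intercept variance: {res.random_intercept_var:.1f}")
print(f"converged: {res.converged}")
print(
    "\nWith the built-in effect, the volume coefficient is positive and "
    "significant: larger drinks slow the apparent uptake (longer tau). "
    "Participant-level covariates (age, BMI, ...) carry no built-in effect "
    "and should not be systematically significant."
)
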