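"""Linear mixed models relating fitted dynamic parameters to covariates.

Each fitted response-model parameter (most importantly the organ time
constant) is regressed on session- and participant-level covariates — drink
volume (numeric litres by default), age, BMI, baseline organ volume and the
IVC/Ao diameter ratio — with a per-participant random intercept, REML
estimation and Wald p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LmmResult", "fit_lmm", "DEFAULT_FIXED_EFFECTS"]

DEFAULT_FIXED_EFFECTS = ("volume", "age", "bmi", "baseline_organ_volume", "ivc_ao")


@dataclass
class LmmResult:
    """Fitted mixed model: one coefficient row per declared fixed effect."""

    response: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    random_intercept_var: float
    converged: bool
    n_obs: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "random_intercept_var": self.random_intercept_var,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "message": self.message,
        }


def _degenerate(response, effects, n, msg) -> LmmResult:
    nan = {e: float("nan") for e in effects}
    return LmmResult(
        response=response, coefficients=dict(nan), std_errors=dict(nan),
        p_values=dict(nan), random_intercept_var=float("nan"),
        converged=False, n_obs=n, message=msg,
    )


def fit_lmm(
    table: pd.DataFrame,
    response: str = "response",
    fixed_effects=DEFAULT_FIXED_EFFECTS,
    group_col: str = "participant",
    categorical_volume: bool = False,
    zscore: bool = False,
) -> LmmResult:
    """Random-intercept mixed model of one fitted parameter on covariates.

    Parameters
    ----------
    table : DataFrame
        One row per participant x session with columns ``group_col``, the
        fixed-effect covariates and ``response``.  No missing values.
    categorical_volume : bool
        Treat drink volume as a categorical factor rather than numeric litres.
    zscore : bool
        Standardise continuous covariates before fitting.

    Degenerate designs (constant response or covariates, non-convergence)
    return a flagged result rather than raising.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fixed_effects = list(fixed_effects)
    required = {group_col, response, *fixed_effects}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    if table[list(required)].isna().any().any():
        raise ValueError("missing values in model columns")
    data = table.copy()
    n = len(data)
    if data[group_col].nunique() < 2:
        return _degenerate(response, fixed_effects, n, "fewer than 2 participants")
    if float(np.var(data[response])) == 0.0:
        return _degenerate(response, fixed_effects, n, "zero response variance")

    # internal conditioning: centre/scale continuous covariates so the REML
    # score's X'V^-1 X stays invertible with covariates spanning four orders
    # of magnitude; coefficients are rescaled back, so the reported estimates
    # are on the raw covariate scale unless z-scoring is requested
    scale: dict[str, float] = {}
    terms = []
    for e in fixed_effects:
        if e == "volume" and categorical_volume:
            terms.append("C(volume)")
            continue
        if pd.api.types.is_numeric_dtype(data[e]):
            sd = float(data[e].std(ddof=0))
            if sd > 0:
                data[e] = (data[e] - float(data[e].mean())) / sd
                scale[e] = 1.0 if zscore else sd
        terms.append(e)
    formula = f"{response} ~ " + " + ".join(terms)

    # lbfgs can step to a huge random-effect variance and make the GLS solve
    # singular mid-iteration; derivative-free optimizers do not, so fall back
    fit = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "nm"):
            try:
                model = smf.mixedlm(formula, data, groups=data[group_col])
                fit = model.fit(reml=True, method=[method])
                break
            except Exception as exc:  # singular design and friends
                last_exc = exc
    if fit is None:
        return _degenerate(response, fixed_effects, n, f"fit failed: {last_exc}")

    coefs, ses, ps = {}, {}, {}
    for e in fixed_effects:
        if e == "volume" and categorical_volume:
            keys = [k for k in fit.params.index if k.startswith("C(volume)")]
        else:
            keys = [e] if e in fit.params.index else []
        for k in keys:
            s = scale.get(e, 1.0)
            coefs[k] = float(fit.params[k]) / s
            ses[k] = float(fit.bse[k]) / s
            ps[k] = float(fit.pvalues[k])
    if not coefs:
        return _degenerate(response, fixed_effects, n, "no estimable fixed effects")
    # participant-level covariates can saturate the between-participant design
    # (6 groups vs 4 such covariates); keep per-coefficient NaNs rather than
    # discarding the whole fit, since within-participant effects stay valid
    bad = sorted(k for k, v in ses.items() if not np.isfinite(v))
    msg = f"non-finite SEs for: {', '.join(bad)}" if bad else ""
    try:
        re_var = float(np.asarray(fit.cov_re)[0, 0])
    except Exception:
        re_var = float("nan")
    return LmmResult(
        response=response, coefficients=coefs, std_errors=ses, p_values=ps,
        random_intercept_var=re_var, converged=bool(fit.converged),
        n_obs=n, message=msg,
    )
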