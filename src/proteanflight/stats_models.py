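"""Linear mixed-effects models of airspeed selection.

All models share the same random structure: crossed random intercepts for
the day of the flight and for bird identity, implemented with statsmodels'
MixedLM through a single constant group and one variance component per
factor.  Estimation uses REML; likelihood-ratio comparisons refit both
models by ML.  For each fixed term the table reports the raw-scale
estimate, the estimate on centred-and-scaled predictors (continuous
predictors only — dummies are left untouched so both columns agree for
categorical terms), the standard error, t-value, a 1-df Wald chi-square
and its p-value.  Variance explained is decomposed Nakagawa-style into a
marginal R2 (fixed effects over total variance) and a conditional R2
(fixed plus random).

A caution on sampling rate: with 1 Hz observations smoothed over 5 s,
neighbouring samples are not independent, so chi-square statistics from a
full-rate fit are inflated.  The ``thin`` argument fits on every k-th
sample; parameter-recovery work in this package uses thin=5 (one sample
per smoothing window) so that confidence intervals are honest, while
full-rate fits remain available for comparability with analyses that
ignore the autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf


@dataclass
class LMEResult:
    """Fixed-effect table plus model-level summaries of one mixed fit."""

    terms: pd.DataFrame          # term, estimate, estimate_std, se, t, chi2, p
    aic: float
    llf: float
    r2_marginal: float
    r2_conditional: float
    vc: dict                     # random-effect variances by factor
    scale: float                 # residual variance
    n_obs: int
    converged: bool
    singular: bool
    formula: str
    model_result: object = field(repr=False, default=None)

    def estimate(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "se"])

    def conf_int(self, term: str, level: float = 0.95):
        z = sps.norm.ppf(0.5 + level / 2.0)
        est, se = self.estimate(term), self.se(term)
        return est - z * se, est + z * se


def standardize(values):
    """Centre and scale; returns (z, mean, sd). Raises on zero variance."""
    x = np.asarray(values, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance series")
    return (x - mean) / sd, mean, sd


def _vc_formulas(random_factors):
    return {f: f"0 + C({f})" for f in random_factors}


def _fit_mixedlm(formula, data, random_factors, reml=True):
    df = data.copy()
    df["_group"] = 1
    model = smf.mixedlm(formula, df, groups="_group", re_formula="0",
                        vc_formula=_vc_formulas(random_factors))
    # boundary fits (a variance component near 0) can defeat a single
    # optimizer; fall through the cascade and keep the best converged fit
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", None):
            try:
                res = (model.fit(reml=reml, method=method) if method
                       else model.fit(reml=reml))
            except Exception:
                continue
            candidates.append(res)
            if res.converged:
                break
    if not candidates:
        raise RuntimeError("mixed-model optimization failed for every optimizer")
    converged = [r for r in candidates if r.converged]
    pool = converged or candidates
    return max(pool, key=lambda r: r.llf)


def fit_lme(data: pd.DataFrame, formula: str,
            random_factors=("day", "bird"),
            continuous=None, thin: int = 1) -> LMEResult:
    """REML fit of a random-intercept model with crossed factors.

    Parameters
    ----------
    data : one row per observation; must contain the response, predictors
        and the random-factor columns.
    formula : patsy formula for the fixed part, e.g. ``"va ~ vz + altitude"``.
    continuous : names of continuous predictors to centre and scale for the
        standardized column (default: every numeric predictor in the formula
        except dummies).
    thin : fit on every ``thin``-th row (1 = all rows).
    """
    df = data.iloc[::thin].reset_index(drop=True).copy()
    for f in random_factors:
        if df[f].nunique() < 2:
            raise ValueError(f"random factor '{f}' needs at least 2 levels")

    res = _fit_mixedlm(formula, df, random_factors, reml=True)

    # standardized refit: centre and scale the continuous predictors
    response = formula.split("~")[0].strip()
    rhs_terms = [t.strip() for t in formula.split("~")[1].split("+")]
    if continuous is None:
        continuous = [t for t in rhs_terms
                      if ":" not in t and not t.startswith("C(") and t != "1"
                      and t in df.columns and np.issubdtype(df[t].dtype, np.number)]
    df_std = df.copy()
    scales = {}
    for c in continuous:
        df_std[c], mu, sd = standardize(df_std[c])
        scales[c] = (mu, sd)
    res_std = _fit_mixedlm(formula, df_std, random_factors, reml=True)

    fe = res.fe_params
    rows = []
    for term in fe.index:
        est = float(fe[term])
        se = float(res.bse_fe[term])
        t = est / se if se > 0 else np.nan
        chi2 = t**2
        p = float(sps.chi2.sf(chi2, df=1))
        est_std = float(res_std.fe_params[term]) if term in res_std.fe_params else np.nan
        rows.append({"term": term, "estimate": est, "estimate_std": est_std,
                     "se": se, "t": t, "chi2": chi2,
                     "p": p if term != "Intercept" else np.nan})
    terms = pd.DataFrame(rows)

    var_f = float(np.var(np.asarray(res.model.exog @ res.fe_params)))
    var_r = float(np.sum(res.vcomp)) if res.vcomp is not None and len(res.vcomp) else 0.0
    var_e = float(res.scale)
    total = var_f + var_r + var_e
    vc_names = list(getattr(res.model.exog_vc, "names", sorted(random_factors)))
    vc = {f: float(v) for f, v in zip(vc_names, res.vcomp)} \
        if res.vcomp is not None and len(res.vcomp) else {}
    singular = any(v < 1e-8 for v in vc.values()) if vc else False
    if singular:
        warnings.warn(f"singular fit: a random-effect variance is ~0 ({vc})")

    return LMEResult(
        terms=terms,
        aic=float(res.aic) if np.isfinite(res.aic) else float(-2 * res.llf + 2 * (len(fe) + len(vc) + 1)),
        llf=float(res.llf),
        r2_marginal=var_f / total,
        r2_conditional=(var_f + var_r) / total,
        vc=vc,
        scale=var_e,
        n_obs=len(df),
        converged=bool(res.converged),
        singular=singular,
        formula=formula,
        model_result=res,
    )


def fit_phase_models(data: pd.DataFrame, formula: str = "va ~ vz",
                     random_factors=("day", "bird"), thin: int = 1):
    """Separate fits for climbing (Vz > 0) and descending (Vz < 0) flight."""
    climb = data[data["vz"] > 0]
    desc = data[data["vz"] < 0]
    if len(climb) == 0:
        raise ValueError("no climbing observations (Vz > 0)")
    if len(desc) == 0:
        raise ValueError("no descending observations (Vz < 0)")
    return (fit_lme(climb, formula, random_factors, thin=thin),
            fit_lme(desc, formula, random_factors, thin=thin))


def compare_models(data: pd.DataFrame, full_formula: str, reduced_formula: str,
                   random_factors=("day", "bird"), thin: int = 1) -> dict:
    """Likelihood-ratio comparison of nested fixed structures (ML refits)."""
    df = data.iloc[::thin].reset_index(drop=True)
    full = _fit_mixedlm(full_formula, df, random_factors, reml=False)
    red = _fit_mixedlm(reduced_formula, df, random_factors, reml=False)
    df_full = len(full.fe_params)
    df_red = len(red.fe_params)
    if df_full <= df_red:
        raise ValueError("the reduced model must be nested in the full model")
    chi2 = max(2.0 * (full.llf - red.llf), 0.0)
    ddf = df_full - df_red
    return {
        "chi2": float(chi2),
        "df": int(ddf),
        "p": float(sps.chi2.sf(chi2, ddf)),
        "aic_full": float(full.aic),
        "aic_reduced": float(red.aic),
        "aic_difference": float(red.aic - full.aic),
    }


def route_altitude_model(plain_data: pd.DataFrame, thin: int = 1,
                         random_factors=("day", "bird")) -> LMEResult:
    """Altitude-over-the-plain contrast between valley and hill routes.

    The raw estimate of the valley term is the valley-minus-hill altitude
    difference in metres (hill is the reference level).
    """
    classes = set(plain_data["route_class"].unique())
    if not {"hill", "valley"} <= classes:
        raise ValueError("need both hill-class and valley-class observations")
    formula = "altitude_asl ~ C(route_class, Treatment(reference='hill'))"
    return fit_lme(plain_data, formula, random_factors, continuous=[], thin=thin)


def slope_vs_terrain(data: pd.DataFrame, thin: int = 1,
                     random_factors=("day", "bird")) -> LMEResult:
    """Climb rate as a function of the ground slope beneath the bird."""
    return fit_lme(data, "vz ~ terrain_slope", random_factors, thin=thin)
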