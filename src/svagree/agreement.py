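"""Repeated-measures Bland-Altman agreement analysis with mixed models.

All models are linear mixed models estimated by REML (statsmodels
``MixedLM``), with a subject random intercept and, for the time-proxy
model, an additional LBNP-level-within-subject variance component.
Variance components are truncated at zero; fixed-effect confidence
intervals are 95% Wald intervals; p-values are two-sided.

Quantities reported:

* **bias** -- the fixed intercept of ``diff ~ 1 + (1 | subject)``,
* **limits of agreement (LOA)** -- 1.96 x total SD, where the total
  variance is the sum of the between-subject and residual variance
  components,
* **within-subject LOA** -- 1.96 x residual SD, the relevant width for a
  monitor's trending ability,
* **within-subject percentage error** -- within-subject LOA divided by
  the grand mean of the per-bin mean-of-methods, x 100,
* **sloped bias** -- ``diff ~ mean-of-methods``, with LOA constructed
  about the fitted line using the same variance-component rule,
* **SVR effect** -- ``diff ~ SVR`` (optionally with a sex interaction,
  reporting per-sex slopes),
* **time-proxy effect** -- ``diff ~ 30-s bin index`` within IHG periods,
  with LBNP level nested in subject as an extra random effect (time
  during handgrip proxies SVR, sidestepping the algebraic coupling
  between SVR, MAP and cardiac output),
* **precision** -- 1.96 x residual SD of one method's 30-s values at
  LBNP 0 rest, subject random intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf

from .errors import (ConvergenceError, InvalidArgumentError,
                     ModelSpecificationError)

__all__ = [
    "LmmFit",
    "AgreementFit",
    "CovariateFit",
    "PrecisionResult",
    "fit_random_intercept",
    "bland_altman",
    "sloped_bias",
    "svr_effect",
    "time_effect",
    "precision",
    "predicted_difference_change",
    "residual_diagnostics",
]

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class LmmFit:
    """A fitted random-intercept linear mixed model.

    ``fixed_effects`` is a frame indexed by term with columns
    ``estimate``, ``se``, ``ci_low``, ``ci_high``, ``p``.
    """

    fixed_effects: pd.DataFrame
    sigma_between: float          # SD of the subject random intercept
    sigma_level: float            # SD of level-within-subject intercept (0 if absent)
    sigma_resid: float            # residual SD
    n_obs: int
    n_subjects: int
    loglike: float                # restricted log-likelihood
    formula: str
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)  # fixed + random prediction
    cov_params: pd.DataFrame = field(repr=False, default=None)

    @property
    def total_sd(self) -> float:
        """sqrt(between-subject variance + residual variance)."""
        return float(np.sqrt(self.sigma_between**2 + self.sigma_resid**2))

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])


@dataclass
class AgreementFit:
    """Bland-Altman agreement summary from the random-intercept model."""

    bias: float                 # mL
    loa_half_width: float       # mL, 1.96 x total SD
    ws_loa_half_width: float    # mL, 1.96 x residual SD
    percentage_error: float     # %, ws LOA / grand mean of mean-of-methods x 100
    grand_mean_of_methods: float
    lmm: LmmFit


@dataclass
class CovariateFit:
    """A covariate-dependent bias model.

    ``model`` tags which one: ``sloped_bias`` (difference on mean of
    methods, slope in mL/mL), ``svr`` (mL per mmHg.min/L),
    ``svr_sex_interaction`` (per-sex SVR slopes as linear combinations of
    the interaction fit) or ``time_proxy`` (mL per 30-s bin).
    """

    model: str
    slope: float
    slope_ci: tuple[float, float]
    slope_p: float
    slope_units: str
    lmm: LmmFit
    loa_half_width: float | None = None      # about the fitted line (sloped_bias)
    ws_loa_half_width: float | None = None
    percentage_error: float | None = None
    sex_slopes: pd.DataFrame | None = None   # per-sex slope, se, ci, p


@dataclass
class PrecisionResult:
    """Method precision: 1.96 x residual SD at LBNP 0 without IHG."""

    method: str        # "us" | "pwa"
    half_width: float  # mL
    lmm: LmmFit


def _check_design(df: pd.DataFrame, fixed_terms: list[str], subject_col: str):
    if df[subject_col].nunique() < 2:
        raise ModelSpecificationError(
            "at least 2 subjects are required (between-subject variance "
            "is unidentifiable otherwise)")
    numeric = [t for t in fixed_terms if t in df.columns
               and pd.api.types.is_numeric_dtype(df[t])]
    for t in numeric:
        if np.isclose(df[t].std(ddof=0), 0.0):
            raise ModelSpecificationError(f"covariate {t!r} is constant")


def _fixed_effects_residual(df, response, fixed_formula, subject_col) -> float:
    """Largest absolute residual of the subject-fixed-effects regression,
    computed by the within transform (Frisch-Waugh), without building
    subject dummies."""
    from patsy import dmatrix

    y = df[response].to_numpy(float)
    X = np.asarray(dmatrix(fixed_formula, df, return_type="matrix"), float)
    groups = df.groupby(subject_col, observed=True)
    yd = y - groups[response].transform("mean").to_numpy(float)
    codes, _ = pd.factorize(df[subject_col])
    counts = np.bincount(codes)
    Xd = X - (np.add.reduceat(X[np.argsort(codes, kind="stable")], np.concatenate(
        ([0], np.cumsum(counts)[:-1]))) / counts[:, None])[codes]
    keep = np.linalg.norm(Xd, axis=0) > 1e-10 * np.sqrt(len(df))
    if keep.any():
        beta, *_ = np.linalg.lstsq(Xd[:, keep], yd, rcond=None)
        yd = yd - Xd[:, keep] @ beta
    return float(np.abs(yd).max())


def _degenerate_fit(df, response, fixed_formula, subject_col) -> "LmmFit | None":
    """Exact fit when the data carry no residual noise.

    If subject fixed effects reproduce the response exactly, REML
    degenerates: the residual SD is 0, subject offsets are the dummy
    coefficients, and the between-subject SD is their ddof-1 standard
    deviation.  Optimizing the profiled REML criterion numerically is
    ill-conditioned there, so this path solves it directly.  (SEs of
    non-intercept terms are reported as 0 on this path.)
    """
    scale = max(1.0, float(df[response].abs().max()))
    if _fixed_effects_residual(df, response, fixed_formula, subject_col) > 1e-8 * scale:
        return None
    fe = smf.ols(f"{response} ~ {fixed_formula} + C({subject_col})", data=df).fit()
    dummy = [c for c in fe.params.index if c.startswith(f"C({subject_col})")]
    offsets = np.concatenate(([0.0], fe.params[dummy].to_numpy()))
    centered = offsets - offsets.mean()
    keep = [c for c in fe.params.index if c not in dummy]
    est = fe.params[keep].copy()
    est["Intercept"] = est["Intercept"] + offsets.mean()
    sigma_b = float(np.std(centered, ddof=1))
    k = len(offsets)
    se = pd.Series(0.0, index=keep)
    se["Intercept"] = sigma_b / np.sqrt(k)
    fixed = pd.DataFrame({
        "estimate": est, "se": se,
        "ci_low": est - _Z95 * se, "ci_high": est + _Z95 * se,
        "p": [0.0 if abs(e) > 0 else 1.0 for e in est],
    })
    return LmmFit(
        fixed_effects=fixed, sigma_between=sigma_b, sigma_level=0.0,
        sigma_resid=0.0, n_obs=len(df), n_subjects=k,
        loglike=np.nan, formula=f"{response} ~ {fixed_formula}",
        residuals=np.zeros(len(df)), fitted=df[response].to_numpy(float),
        cov_params=pd.DataFrame(np.outer(se, se), index=keep, columns=keep))


def fit_random_intercept(df: pd.DataFrame, response: str,
                         fixed: str = "1",
                         subject_col: str = "subject_id",
                         level_col: str | None = None) -> LmmFit:
    """Fit ``response ~ fixed + (1 | subject) [+ (1 | subject:level)]`` by REML.

    ``fixed`` is a patsy right-hand-side formula (default intercept
    only).  ``level_col`` adds a variance component for ``level_col``
    nested within subject.  Raises :class:`ModelSpecificationError` for
    rank-deficient or degenerate designs and :class:`ConvergenceError`
    (with diagnostics) when the optimizer fails.
    """
    if df.empty:
        raise InvalidArgumentError("no records to fit")
    terms = [t.strip() for t in fixed.split("+")]
    _check_design(df, terms, subject_col)

    degenerate = _degenerate_fit(df, response, fixed, subject_col)
    if degenerate is not None:
        return degenerate

    vc = {"level": f"0 + C({level_col})"} if level_col else None
    model = smf.mixedlm(f"{response} ~ {fixed}", data=df, groups=df[subject_col],
                        re_formula="1", vc_formula=vc)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method, kwargs in (("lbfgs", {}), ("powell", {}), ("cg", {})):
            try:
                cand = model.fit(reml=True, method=method, maxiter=2000, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged:
                res = cand
                break
        # polish small fits for tight agreement with closed forms on
        # balanced designs; large fits are already well-conditioned and
        # the extra Newton-quality pass would dominate runtime
        if res is not None and len(df) <= 500:
            try:
                polished = model.fit(reml=True, method="bfgs", gtol=1e-12,
                                     maxiter=500, start_params=res.params_object)
                if polished.converged:
                    res = polished
            except (np.linalg.LinAlgError, ValueError):
                pass
    if res is None:
        raise ConvergenceError("mixed model did not converge",
                               diagnostics={"formula": f"{response} ~ {fixed}",
                                            "n_obs": len(df)})

    k_fe = model.k_fe
    params = res.params.iloc[:k_fe]
    bse = res.bse.iloc[:k_fe]
    ci = res.conf_int().iloc[:k_fe]
    fixed_df = pd.DataFrame({
        "estimate": params, "se": bse,
        "ci_low": ci[0], "ci_high": ci[1],
        "p": res.pvalues.iloc[:k_fe],
    })
    sigma_b = float(np.sqrt(max(0.0, float(res.cov_re.iloc[0, 0]))))
    sigma_l = float(np.sqrt(max(0.0, float(res.vcomp[0])))) if level_col else 0.0
    try:
        fitted = np.asarray(res.fittedvalues, float)
        resid = np.asarray(res.resid, float)
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance (variance component at the
        # zero boundary): fall back to the marginal fit
        fitted = np.asarray(model.exog @ res.fe_params, float)
        resid = np.asarray(model.endog, float) - fitted
    return LmmFit(
        fixed_effects=fixed_df,
        sigma_between=sigma_b, sigma_level=sigma_l,
        sigma_resid=float(np.sqrt(res.scale)),
        n_obs=len(df), n_subjects=df[subject_col].nunique(),
        loglike=float(res.llf), formula=f"{response} ~ {fixed}",
        residuals=resid, fitted=fitted,
        cov_params=res.cov_params().iloc[:k_fe, :k_fe])


def _require_columns(bins: pd.DataFrame, cols: list[str]):
    missing = [c for c in cols if c not in bins.columns]
    if missing:
        raise InvalidArgumentError(f"bins are missing columns: {missing}")


def _grand_mean_of_methods(bins: pd.DataFrame, mode: str = "grand") -> float:
    """Denominator of the percentage error.

    ``"grand"``: mean of the per-bin mean-of-methods over all analysis
    bins (default).  ``"subject_mean"``: per-subject means first, then
    their mean.
    """
    if mode == "grand":
        return float(bins["mean"].mean())
    if mode == "subject_mean":
        return float(bins.groupby("subject_id", observed=True)["mean"].mean().mean())
    raise InvalidArgumentError(f"unknown percentage-error mode: {mode!r}")


def bland_altman(bins: pd.DataFrame, pe_mode: str = "grand") -> AgreementFit:
    """Repeated-measures Bland-Altman: ``diff ~ 1 + (1 | subject)``."""
    _require_columns(bins, ["diff", "mean", "subject_id"])
    lmm = fit_random_intercept(bins, "diff", "1")
    grand = _grand_mean_of_methods(bins, pe_mode)
    ws = _Z95 * lmm.sigma_resid
    return AgreementFit(
        bias=lmm.coef("Intercept"),
        loa_half_width=_Z95 * lmm.total_sd,
        ws_loa_half_width=ws,
        percentage_error=100.0 * ws / grand,
        grand_mean_of_methods=grand,
        lmm=lmm)


def _slope_fit(lmm: LmmFit, term: str) -> tuple[float, tuple[float, float], float]:
    row = lmm.fixed_effects.loc[term]
    return (float(row["estimate"]), (float(row["ci_low"]), float(row["ci_high"])),
            float(row["p"]))


def sloped_bias(bins: pd.DataFrame, pe_mode: str = "grand") -> CovariateFit:
    """Sloped bias line: ``diff ~ mean-of-methods + (1 | subject)``.

    LOA and within-subject LOA are constructed about the fitted line with
    the same 1.96 x SD variance-component rule as the constant-bias model.
    """
    _require_columns(bins, ["diff", "mean", "subject_id"])
    lmm = fit_random_intercept(bins, "diff", "mean")
    slope, ci, p = _slope_fit(lmm, "mean")
    ws = _Z95 * lmm.sigma_resid
    grand = _grand_mean_of_methods(bins, pe_mode)
    return CovariateFit(
        model="sloped_bias", slope=slope, slope_ci=ci, slope_p=p,
        slope_units="mL/mL", lmm=lmm,
        loa_half_width=_Z95 * lmm.total_sd, ws_loa_half_width=ws,
        percentage_error=100.0 * ws / grand)


def svr_effect(bins: pd.DataFrame, with_sex_interaction: bool = False) -> CovariateFit:
    """Effect of SVR on the between-method difference.

    Without interaction: ``diff ~ svr_us + (1 | subject)``.  With
    interaction: ``diff ~ svr_us * sex + (1 | subject)``; per-sex slopes
    (and Wald CIs) are derived as linear combinations of the coefficients.
    """
    _require_columns(bins, ["diff", "svr_us", "subject_id"])
    if not with_sex_interaction:
        lmm = fit_random_intercept(bins, "diff", "svr_us")
        slope, ci, p = _slope_fit(lmm, "svr_us")
        return CovariateFit(model="svr", slope=slope, slope_ci=ci, slope_p=p,
                            slope_units="mL per mmHg.min/L", lmm=lmm)

    sexes = sorted(bins["sex"].unique())
    if len(sexes) < 2:
        raise ModelSpecificationError(
            "sex interaction requested but only one sex present")
    lmm = fit_random_intercept(bins, "diff", "svr_us * C(sex)")
    # reference level is the first sorted sex ("female" in the default cohort)
    inter_term = [t for t in lmm.fixed_effects.index
                  if t.startswith("svr_us:")][0]
    cov = lmm.cov_params
    rows = {}
    for sex in sexes:
        if sex == sexes[0]:
            est = lmm.coef("svr_us")
            var = float(cov.loc["svr_us", "svr_us"])
        else:
            est = lmm.coef("svr_us") + lmm.coef(inter_term)
            var = float(cov.loc["svr_us", "svr_us"] + cov.loc[inter_term, inter_term]
                        + 2 * cov.loc["svr_us", inter_term])
        se = np.sqrt(max(var, 0.0))
        z = est / se if se > 0 else np.inf
        rows[sex] = {"slope": est, "se": se,
                     "ci_low": est - _Z95 * se, "ci_high": est + _Z95 * se,
                     "p": 2 * sps.norm.sf(abs(z))}
    sex_slopes = pd.DataFrame(rows).T
    slope, ci, p = _slope_fit(lmm, "svr_us")
    return CovariateFit(model="svr_sex_interaction", slope=slope, slope_ci=ci,
                        slope_p=p, slope_units="mL per mmHg.min/L", lmm=lmm,
                        sex_slopes=sex_slopes)


def time_effect(bins: pd.DataFrame) -> CovariateFit:
    """Time-during-IHG proxy model on IHG bins only.

    ``diff ~ period_time_bin + (1 | subject) + (1 | subject:lbnp)``; the
    time unit is one 30-s bin, so the slope is in mL per 30 s.
    """
    _require_columns(bins, ["diff", "period_time_bin", "phase", "lbnp", "subject_id"])
    ihg = bins.loc[bins["phase"] == "ihg"].copy()
    if ihg.empty:
        raise InvalidArgumentError("no IHG bins available for the time-proxy model")
    lmm = fit_random_intercept(ihg, "diff", "period_time_bin", level_col="lbnp")
    slope, ci, p = _slope_fit(lmm, "period_time_bin")
    return CovariateFit(model="time_proxy", slope=slope, slope_ci=ci, slope_p=p,
                        slope_units="mL per 30 s", lmm=lmm)


def precision(bins: pd.DataFrame, method: str) -> PrecisionResult:
    """Method precision at LBNP 0 without IHG.

    Fits ``value ~ 1 + (1 | subject)`` on the chosen method's 30-s values
    over rest bins at LBNP 0; the half-width is 1.96 x residual SD.
    """
    if method not in ("us", "pwa"):
        raise InvalidArgumentError("method must be 'us' or 'pwa'")
    col = f"sv_{method}"
    _require_columns(bins, [col, "lbnp", "phase", "subject_id"])
    rest0 = bins.loc[(bins["lbnp"] == 0) & (bins["phase"] == "rest")]
    if rest0.empty:
        raise InvalidArgumentError("no LBNP-0 rest bins available")
    lmm = fit_random_intercept(rest0, col, "1")
    return PrecisionResult(method=method, half_width=_Z95 * lmm.sigma_resid, lmm=lmm)


def predicted_difference_change(beta_svr: float, delta_svr: float) -> float:
    """Predicted change in the between-method difference (mL) for an SVR
    excursion of ``delta_svr`` mmHg.min/L at slope ``beta_svr``."""
    if not (np.isfinite(beta_svr) and np.isfinite(delta_svr)):
        raise InvalidArgumentError("inputs must be finite")
    return float(beta_svr * delta_svr)


def residual_diagnostics(fit: LmmFit) -> pd.DataFrame:
    """Residual diagnostics table for export / plotting.

    Columns: ``fitted`` (fixed + random prediction), ``residual``,
    ``std_residual`` and ``normal_quantile`` (the theoretical normal
    quantile paired with each standardized residual by rank), suitable
    for residual-vs-fitted and QQ plots.  No automatic pass/fail.
    """
    resid = np.asarray(fit.residuals, float)
    fitted = np.asarray(fit.fitted, float)
    scale = fit.sigma_resid if fit.sigma_resid > 0 else 1.0
    std = resid / scale
    n = std.size
    ranks = sps.rankdata(std, method="average")
    theo = sps.norm.ppf((ranks - 0.5) / n)
    return pd.DataFrame({
        "fitted": fitted, "residual": resid,
        "std_residual": std, "normal_quantile": theo,
    })
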