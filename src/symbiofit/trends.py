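"""Field prevalence and development-rate trend inference.

Binomial logit GLMs of infection counts on calendar-year terms (linear and
quadratic), crop status, years since Bt-cotton introduction, Bt proportion
and environmental covariates, with likelihood-ratio tests between nested
models; plus simple linear trend fits for yearly summaries such as the
mean RADR.

Calendar year enters the reported model directly (hence intercepts in the
hundreds), but fitting uses a centered-year parameterization for numerical
conditioning and maps coefficients and their covariance back to the
calendar scale exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import GlmResult, fit_binomial_irls
from .exceptions import SeparationError, ValidationError

__all__ = [
    "years_since_bt",
    "GlmFit",
    "fit_binomial_glm",
    "LrtResult",
    "lrt",
    "LinearTrend",
    "fit_linear_trend",
]

BT_INTRO_PROPORTION = 0.10


def years_since_bt(province_bt_history: dict, sample_year: int) -> int | None:
    """Years since Bt-cotton first reached 10% of a province's cotton.

    The introduction year is the earliest year whose Bt proportion is at
    least 10% (inclusive). Returns None when the threshold was never
    reached (the province is treated as non-Bt).
    """
    if not province_bt_history:
        raise ValidationError("empty Bt-cotton history")
    if sample_year < min(province_bt_history):
        raise ValidationError(
            f"sample year {sample_year} precedes the recorded history "
            f"(first year {min(province_bt_history)})"
        )
    reached = [y for y, p in province_bt_history.items() if p >= BT_INTRO_PROPORTION]
    if not reached:
        return None
    return sample_year - min(reached)


@dataclass
class GlmFit:
    """Fitted prevalence GLM with calendar-scale reported coefficients."""

    terms: list[str]
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    deviance: float
    df_resid: int
    loglik: float
    converged: bool
    n_obs: int
    glm: GlmResult = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef_dict(self) -> dict:
        return {n: (float(b), float(s)) for n, b, s in zip(self.names, self.coef, self.se)}


def _term_column(obs: pd.DataFrame, term: str, year_centered: np.ndarray) -> np.ndarray:
    if term == "year":
        return year_centered
    if term in ("year2", "year^2"):
        return year_centered**2
    if term == "bt_crop":
        return (obs["bt_crop"].astype(str) == "Bt").to_numpy(float)
    if ":" in term:
        a, b = term.split(":", 1)
        return _term_column(obs, a, year_centered) * _term_column(obs, b, year_centered)
    if term not in obs.columns:
        raise ValidationError(f"unknown model term {term!r}: not a column of the observations")
    col = obs[term].to_numpy(float)
    if np.any(np.isnan(col)):
        raise ValidationError(f"term {term!r} contains missing values")
    return col


def _calendar_transform(terms: list[str], c: float) -> np.ndarray | None:
    """Linear map from centered-year coefficients to calendar-year ones.

    With yc = year - c: b0 + b1*yc + b2*yc^2 expands to
    (b0 - b1*c + b2*c^2) + (b1 - 2*c*b2)*year + b2*year^2.
    Returns None when no year terms are present (identity).
    """
    if "year" not in terms and "year2" not in terms:
        return None
    p = len(terms) + 1
    A = np.eye(p)
    names = ["intercept"] + terms
    i_year = names.index("year") if "year" in names else None
    i_quad = names.index("year2") if "year2" in names else None
    if i_year is not None:
        A[0, i_year] = -c
    if i_quad is not None:
        A[0, i_quad] = c * c
        if i_year is not None:
            A[i_year, i_quad] = -2.0 * c
    return A


def fit_binomial_glm(
    observations: pd.DataFrame,
    terms: list[str],
    link: str = "logit",
    continuity_correction: bool = False,
) -> GlmFit:
    """Binomial GLM of infection counts on the requested terms.

    Terms may be: "year", "year2", "bt_crop", any numeric column of the
    observations (years_since_bt, bt_proportion, rainfall_mm, temp_c,
    altitude_m, crop proportions, ...), or "a:b" interactions. Coefficients
    are reported on the calendar-year scale. Separation (fitted prevalence
    pinned at 0/1) raises rather than reporting meaningless SEs; a
    continuity correction of 0.5 successes/failures per group is available
    for degenerate tables.
    """
    req = {"n_tested", "n_positive"}
    missing = req - set(observations.columns)
    if missing:
        raise ValidationError(f"observations missing columns {sorted(missing)}")
    n = observations["n_tested"].to_numpy(float)
    y = observations["n_positive"].to_numpy(float)
    if continuity_correction:
        y = y + 0.5
        n = n + 1.0
    if len(observations) < len(terms) + 1:
        raise ValidationError("need at least as many observations as parameters")
    c = float(observations["year"].mean()) if "year" in observations.columns else 0.0
    yearc = (observations["year"].to_numpy(float) - c) if "year" in observations.columns else np.zeros(len(observations))
    cols = [np.ones(len(observations))]
    names = ["intercept"]
    for t in terms:
        cols.append(_term_column(observations, t, yearc))
        names.append(t)
    X = np.column_stack(cols)
    glm = fit_binomial_irls(X, y, n, link=link, names=names)
    if glm.separated:
        raise SeparationError(
            "complete separation: fitted prevalences at 0/1 "
            f"(model terms: {terms}); consider continuity_correction"
        )
    coef, cov = glm.coef, glm.cov
    A = _calendar_transform(terms, c)
    if A is not None:
        coef = A @ coef
        cov = A @ cov @ A.T
    return GlmFit(
        terms=list(terms),
        names=names,
        coef=coef,
        cov=cov,
        deviance=glm.deviance,
        df_resid=glm.df_resid,
        loglik=glm.loglik,
        converged=glm.converged,
        n_obs=glm.n_obs,
        glm=glm,
    )


@dataclass
class LrtResult:
    chi2: float
    df: int
    p: float


def lrt(nested: GlmFit, full: GlmFit) -> LrtResult:
    """Likelihood-ratio test between two nested prevalence GLMs."""
    if not set(nested.terms) <= set(full.terms):
        raise ValidationError("models are not nested: nested terms must be a subset")
    if nested.n_obs != full.n_obs:
        raise ValidationError("models were fitted on different observation counts")
    df = nested.df_resid - full.df_resid
    if df < 1:
        raise ValidationError("full model adds no parameters over the nested one")
    chi2 = max(nested.deviance - full.deviance, 0.0)
    return LrtResult(chi2=float(chi2), df=int(df), p=float(stats.chi2.sf(chi2, df)))


@dataclass
class LinearTrend:
    slope: float
    intercept: float
    r2: float
    F: float
    df: tuple[int, int]
    p: float
    se_slope: float


def fit_linear_trend(x: np.ndarray, y: np.ndarray) -> LinearTrend:
    """Ordinary least squares trend of a yearly summary on a single predictor.

    The F statistic is (n-2) r^2 / (1 - r^2) on (1, n-2) df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValidationError("zero variance in the predictor")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    n = len(x)
    df = (1, n - 2)
    if r2 >= 1.0:
        F = np.inf
        p = 0.0
    else:
        F = (n - 2) * r2 / (1.0 - r2)
        p = float(stats.f.sf(F, *df))
    se_slope = float(np.sqrt((rss / (n - 2)) / sxx)) if n > 2 else np.nan
    return LinearTrend(slope=slope, intercept=intercept, r2=float(r2), F=float(F), df=df, p=p, se_slope=se_slope)
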