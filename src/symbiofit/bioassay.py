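"""Dose-response inference for diet-incorporation bioassays.

Implements the full bioassay chain: the 5-mg mortality scoring rule,
maximum-likelihood probit/logit fits of grouped mortality against
log10(dose) with delta-method confidence intervals for the LC50 (inflated
by the Pearson heterogeneity factor when the fit is over-dispersed),
resistance/tolerance ratios between fitted LC50s, the pooled
strain x dose x infection GLM with a sequential likelihood-ratio deviance
table, and the regression of infected on uninfected LC50s with a test of
slope against one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import GlmResult, fit_binomial_irls, sequential_deviance_table
from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "score_mortality",
    "DoseResponseFit",
    "fit_dose_response",
    "RatioEstimate",
    "resistance_ratio",
    "GlmDevianceTable",
    "pooled_bioassay_glm",
    "SlopeTestResult",
    "lc50_regression_with_slope_test",
]

MORTALITY_MASS_THRESHOLD_MG = 5.0


def score_mortality(alive: bool, body_mass: float | None = None, threshold: float = MORTALITY_MASS_THRESHOLD_MG) -> str:
    """Score one larva as dead or alive after the exposure period.

    Larvae found dead are dead; survivors lighter than the mass threshold
    (strictly below 5 mg by default) are scored dead as well, treating
    growth arrest as toxicological death.
    """
    if not alive:
        return "dead"
    if body_mass is None:
        raise ValidationError("body mass required to score a surviving larva")
    if body_mass < 0:
        raise ValidationError(f"negative body mass {body_mass} mg")
    return "dead" if body_mass < threshold else "alive"


@dataclass
class DoseResponseFit:
    """Maximum-likelihood dose-response fit for one bioassay arm."""

    link: str
    intercept: float
    slope: float
    log10_lc50: float
    se_log10_lc50: float
    ci95_lc50: tuple[float, float]
    pearson_chi2: float
    df: int
    heterogeneity_factor: float
    n_groups: int
    converged: bool
    glm: GlmResult = field(repr=False, default=None)

    @property
    def lc50(self) -> float:
        if not self.converged:
            raise ConvergenceError("LC50 requested from an unconverged dose-response fit")
        return 10.0**self.log10_lc50


def _abbott_adjust(n_dead: np.ndarray, n_tested: np.ndarray, control_mortality: float) -> np.ndarray:
    """Abbott's correction: rescale observed mortality above the control rate."""
    p_obs = n_dead / n_tested
    p_adj = np.clip((p_obs - control_mortality) / (1.0 - control_mortality), 0.0, 1.0)
    return p_adj * n_tested


def fit_dose_response(
    records: pd.DataFrame,
    link: str = "probit",
    control_correction: bool = False,
) -> DoseResponseFit:
    """Fit mortality against log10(dose) for a single strain-by-status arm.

    Parameters
    ----------
    records : grouped bioassay table with columns dose_ug_ml, n_tested,
        n_dead; a dose-0 row, if present, is used only for Abbott's
        control-mortality correction (when requested) and excluded from
        the curve fit.
    link : "probit" (default) or "logit".
    control_correction : apply Abbott's correction using the dose-0 group.
    """
    req = {"dose_ug_ml", "n_tested", "n_dead"}
    missing = req - set(records.columns)
    if missing:
        raise ValidationError(f"bioassay records missing columns {sorted(missing)}")
    dosed = records[records["dose_ug_ml"] > 0]
    if len(dosed) < 3:
        raise ValidationError("need >= 3 positive-dose groups to fit a dose-response curve")
    if dosed["dose_ug_ml"].nunique() == 1:
        raise ValidationError("all doses identical; dose-response slope is unidentifiable")
    dose = dosed["dose_ug_ml"].to_numpy(float)
    n = dosed["n_tested"].to_numpy(float)
    y = dosed["n_dead"].to_numpy(float)
    if y.sum() == 0 or (n - y).sum() == 0:
        raise ValidationError("all-alive or all-dead data cannot identify an LC50")

    if control_correction:
        controls = records[records["dose_ug_ml"] == 0]
        if len(controls):
            c = controls["n_dead"].sum() / controls["n_tested"].sum()
            if c >= 1.0:
                raise ValidationError("control mortality of 100% leaves no signal to correct")
            y = _abbott_adjust(y, n, float(c))

    X = np.column_stack([np.ones_like(dose), np.log10(dose)])
    glm = fit_binomial_irls(X, y, n, link=link, names=["intercept", "log10_dose"])
    a, b = glm.coef
    log10_lc50 = -a / b
    df = glm.df_resid
    hf = max(1.0, glm.pearson_chi2 / df) if df > 0 else 1.0
    # delta method for -a/b with heterogeneity-inflated covariance
    grad = np.array([-1.0 / b, a / b**2])
    var = float(grad @ (glm.cov * hf) @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    ci = (10.0 ** (log10_lc50 - z * se), 10.0 ** (log10_lc50 + z * se))
    return DoseResponseFit(
        link=link,
        intercept=float(a),
        slope=float(b),
        log10_lc50=float(log10_lc50),
        se_log10_lc50=se,
        ci95_lc50=ci,
        pearson_chi2=glm.pearson_chi2,
        df=df,
        heterogeneity_factor=float(hf),
        n_groups=len(dosed),
        converged=glm.converged and not glm.separated and b > 0,
        glm=glm,
    )


@dataclass
class RatioEstimate:
    """Ratio of two fitted LC50s with a log-scale confidence interval."""

    numerator_lc50: float
    denominator_lc50: float
    ratio: float
    se_log_ratio: float  # on the log10 scale
    ci95: tuple[float, float]


def resistance_ratio(test: DoseResponseFit, reference: DoseResponseFit) -> RatioEstimate:
    """LC50 ratio test/reference; also serves as the infection tolerance ratio."""
    if not (test.converged and reference.converged):
        raise ConvergenceError("both dose-response fits must have converged")
    log_ratio = test.log10_lc50 - reference.log10_lc50
    se = float(np.hypot(test.se_log10_lc50, reference.se_log10_lc50))
    z = stats.norm.ppf(0.975)
    return RatioEstimate(
        numerator_lc50=test.lc50,
        denominator_lc50=reference.lc50,
        ratio=test.lc50 / reference.lc50,
        se_log_ratio=se,
        ci95=(10.0 ** (log_ratio - z * se), 10.0 ** (log_ratio + z * se)),
    )


@dataclass
class GlmDevianceTable:
    """Sequential likelihood-ratio table for the pooled bioassay GLM."""

    terms: list[dict]
    residual_deviance: float
    df_residual: int
    coef: dict

    def term(self, name: str) -> dict:
        for row in self.terms:
            if row["term"] == name:
                return row
        raise KeyError(name)


def pooled_bioassay_glm(records: pd.DataFrame, link: str = "logit") -> GlmDevianceTable:
    """Pooled mortality GLM across all strains and infection statuses.

    Terms enter sequentially: strain, log10(dose), strain x log10(dose),
    infection status; each term's chi-square is its deviance drop. Dose-0
    control rows are excluded.
    """
    dosed = records[records["dose_ug_ml"] > 0].reset_index(drop=True)
    strains = sorted(dosed["strain"].unique())
    statuses = set(dosed["hadv2"].unique())
    if len(strains) < 2:
        raise ValidationError("pooled GLM needs >= 2 strains (strain:dose would be aliased)")
    if statuses != {"positive", "negative"}:
        raise ValidationError("pooled GLM needs both infection statuses present")
    logd = np.log10(dosed["dose_ug_ml"].to_numpy(float))
    strain_dummies = pd.get_dummies(dosed["strain"], drop_first=True).to_numpy(float)
    hadv2 = (dosed["hadv2"] == "positive").to_numpy(float)
    blocks = [
        ("intercept", np.ones((len(dosed), 1))),
        ("strain", strain_dummies),
        ("log10_dose", logd[:, None]),
        ("strain:log10_dose", strain_dummies * logd[:, None]),
        ("hadv2", hadv2[:, None]),
    ]
    rows, full = sequential_deviance_table(
        blocks, dosed["n_dead"].to_numpy(float), dosed["n_tested"].to_numpy(float), link=link
    )
    coef = {name: (float(b), float(s)) for name, b, s in zip(full.names, full.coef, full.se)}
    return GlmDevianceTable(
        terms=rows,
        residual_deviance=full.deviance,
        df_residual=full.df_resid,
        coef=coef,
    )


@dataclass
class SlopeTestResult:
    """OLS of infected on uninfected LC50s with a slope-vs-1 t-test."""

    slope: float
    intercept: float
    r2: float
    se_slope: float
    t_vs_1: float
    df: int
    p_one_sided: float
    p_two_sided: float


def lc50_regression_with_slope_test(pairs: np.ndarray | list[tuple[float, float]]) -> SlopeTestResult:
    """Regress infected-arm LC50 on uninfected-arm LC50 across strains.

    A slope above one means the absolute LC50 benefit of infection grows
    with the resistance level of the strain.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need >= 3 (uninfected, infected) LC50 pairs")
    x, y = arr[:, 0], arr[:, 1]
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValidationError("uninfected LC50s are all identical")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    df = n - 2
    se_slope = float(np.sqrt((rss / df) / sxx)) if rss > 0 else 0.0
    if se_slope == 0:
        t = np.inf * np.sign(slope - 1.0) if slope != 1.0 else 0.0
    else:
        t = (slope - 1.0) / se_slope
    p_two = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    p_one = float(stats.t.sf(t, df)) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
    return SlopeTestResult(
        slope=slope,
        intercept=intercept,
        r2=float(r2),
        se_slope=se_slope,
        t_vs_1=float(t),
        df=df,
        p_one_sided=p_one,
        p_two_sided=p_two,
    )
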