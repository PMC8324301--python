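"""Life-table fitness analysis: net reproductive rate and rescue effects.

The net reproductive rate R0 (daughters per parental female, N_{t+1}/N_t)
is composed from cohort means of the multiplicative chain of components
that count daughters: survival 1st-to-5th instar x survival 5th-instar-to-
pupa x adult emergence x copulation x fecundity x egg hatch x proportion
female. Development durations, pupal weight, and adult longevities are
summarized alongside but do not enter the count of daughters.

Uncertainty comes from a nonparametric bootstrap over individuals. Fitness
cost is the complement of the R0 ratio between a focal and a reference
cohort, and the infection rescue effect is a paired t-test across strains
of infected vs uninfected R0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._linmod import f_block_test, ols_fit, sequential_f_table
from .exceptions import ValidationError

__all__ = [
    "R0_COMPONENTS",
    "R0Estimate",
    "compose_r0",
    "bootstrap_r0",
    "fitness_cost",
    "PairedComparison",
    "rescue_comparison",
    "PlantGrowthResult",
    "plant_growth_model",
]

#: components whose cohort means multiply into R0, in chain order
R0_COMPONENTS = (
    "surv_l1_l5",
    "surv_l5_pupa",
    "emerged",
    "copulated",
    "fecundity",
    "hatch_rate",
    "female",
)

#: components bounded in [0, 1]
_PROB_COMPONENTS = {"surv_l1_l5", "surv_l5_pupa", "emerged", "copulated", "hatch_rate", "female"}


@dataclass
class R0Estimate:
    """Net reproductive rate with optional bootstrap uncertainty."""

    r0: float
    se_boot: float | None
    n_boot: int
    seed: int | None
    component_means: dict


def _component_means(cohort: pd.DataFrame, components=R0_COMPONENTS) -> dict:
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    means = {}
    for name in components:
        if name not in cohort.columns:
            raise ValidationError(f"cohort missing component column {name!r}")
        m = float(np.nanmean(cohort[name].to_numpy(float)))
        if np.isnan(m):
            raise ValidationError(f"component {name!r} has no observed values in this cohort")
        if name in _PROB_COMPONENTS and not 0.0 <= m <= 1.0 + 1e-12:
            raise ValidationError(f"mean of {name!r} = {m} outside [0, 1]")
        if name == "fecundity" and m < 0:
            raise ValidationError("negative mean fecundity")
        means[name] = m
    return means


def compose_r0(cohort: pd.DataFrame) -> R0Estimate:
    """Point estimate of R0 from a cohort's component means."""
    means = _component_means(cohort)
    r0 = float(np.prod([means[c] for c in R0_COMPONENTS]))
    return R0Estimate(r0=r0, se_boot=None, n_boot=0, seed=None, component_means=means)


def bootstrap_r0(cohort: pd.DataFrame, n_boot: int = 1000, seed: int | None = None) -> R0Estimate:
    """R0 with a bootstrap standard error over individuals.

    Individuals are resampled with replacement within the cohort and R0 is
    recomposed per replicate; the SE is the standard deviation of the
    replicate distribution. Replicates in which a sex-specific component is
    entirely unobserved (e.g. a resample with no females) are discarded.
    """
    if len(cohort) < 2:
        raise ValidationError("bootstrap needs a cohort of >= 2 individuals")
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    point = compose_r0(cohort)
    rng = np.random.default_rng(seed)
    mats = {c: cohort[c].to_numpy(float) for c in R0_COMPONENTS}
    n = len(cohort)
    reps = np.empty(n_boot)
    reps.fill(np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        prod = 1.0
        ok = True
        for c in R0_COMPONENTS:
            vals = mats[c][idx]
            with np.errstate(all="ignore"):
                m = np.nanmean(vals)
            if np.isnan(m):
                ok = False
                break
            prod *= m
        if ok:
            reps[b] = prod
    valid = reps[~np.isnan(reps)]
    if len(valid) < 2:
        raise ValidationError("bootstrap produced < 2 valid replicates")
    se = float(valid.std(ddof=1))
    return R0Estimate(
        r0=point.r0,
        se_boot=se,
        n_boot=len(valid),
        seed=seed,
        component_means=point.component_means,
    )


def fitness_cost(r0_focal: float, r0_reference: float) -> float:
    """Fractional R0 shortfall of the focal cohort: 1 - focal/reference."""
    if r0_reference <= 0:
        raise ValidationError("reference R0 must be positive")
    return 1.0 - r0_focal / r0_reference


@dataclass
class PairedComparison:
    """Paired comparison of infected vs uninfected R0 across strains."""

    strains: list[str]
    percent_changes: list[float]
    mean_percent_change: float
    t: float
    df: int
    p: float
    mode: str  # "difference" | "log_ratio"


def rescue_comparison(
    pairs: list[tuple[str, float, float]] | pd.DataFrame,
    log_ratio: bool = False,
) -> PairedComparison:
    """Paired t-test of per-strain R0 under infection vs without.

    ``pairs`` holds (strain, R0 uninfected, R0 infected) rows. The test is
    on raw per-strain differences by default, or log ratios with
    ``log_ratio=True``; the mean percent change is reported either way.
    """
    if isinstance(pairs, pd.DataFrame):
        rows = [(r[0], float(r[1]), float(r[2])) for r in pairs.itertuples(index=False)]
    else:
        rows = [(s, float(a), float(b)) for s, a, b in pairs]
    if len(rows) < 2:
        raise ValidationError("paired comparison needs >= 2 strains")
    strains = [s for s, _, _ in rows]
    neg = np.array([a for _, a, _ in rows])
    pos = np.array([b for _, _, b in rows])
    if np.any(neg == 0):
        raise ValidationError("uninfected R0 of zero: percent change undefined")
    pct = 100.0 * (pos / neg - 1.0)
    d = np.log(pos / neg) if log_ratio else pos - neg
    n = len(d)
    sd = float(d.std(ddof=1))
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if t == 0.0 and sd == 0:
        p = 1.0
    return PairedComparison(
        strains=strains,
        percent_changes=[float(v) for v in pct],
        mean_percent_change=float(pct.mean()),
        t=t,
        df=df,
        p=p,
        mode="log_ratio" if log_ratio else "difference",
    )


@dataclass
class PlantGrowthResult:
    """Sequential ANOVA of day-9 larval weight on plant assays."""

    terms: list[dict]
    interaction_F: float
    interaction_df: tuple[int, int]
    interaction_p: float
    rss_full: float
    df_full: int


def _factor_dummies(values: pd.Series) -> np.ndarray:
    d = pd.get_dummies(values, drop_first=True)
    if d.shape[1] == 0:
        raise ValidationError(f"factor {values.name!r} has a single level")
    return d.to_numpy(float)


def plant_growth_model(data: pd.DataFrame, interactions: bool = True) -> PlantGrowthResult:
    """Linear model of larval weight on cotton variety, strain and infection.

    Main effects enter sequentially (variety, strain, infection); when
    ``interactions`` is set, the full-factorial model is also fitted and the
    entire interaction block is tested with a single F comparing the
    main-effects model against the full model.
    """
    req = {"weight", "variety", "strain", "hadv2"}
    missing = req - set(data.columns)
    if missing:
        raise ValidationError(f"plant assay table missing columns {sorted(missing)}")
    y = data["weight"].to_numpy(float)
    var_d = _factor_dummies(data["variety"])
    strain_d = _factor_dummies(data["strain"])
    inf_d = _factor_dummies(data["hadv2"])

    if interactions:
        cells = data.groupby(["variety", "strain", "hadv2"]).size()
        n_levels = data["variety"].nunique() * data["strain"].nunique() * data["hadv2"].nunique()
        if len(cells) < n_levels:
            raise ValidationError("empty factor cells: full-factorial interactions are unestimable")

    def cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.hstack([a[:, i : i + 1] * b for i in range(a.shape[1])])

    main_blocks = [
        ("intercept", np.ones((len(y), 1))),
        ("variety", var_d),
        ("strain", strain_d),
        ("hadv2", inf_d),
    ]
    main_X = np.hstack([b for _, b in main_blocks])
    main_fit = ols_fit(main_X, y)

    if interactions:
        vs = cross(var_d, strain_d)
        vi = cross(var_d, inf_d)
        si = cross(strain_d, inf_d)
        vsi = cross(cross(var_d, strain_d), inf_d)
        full_X = np.hstack([main_X, vs, vi, si, vsi])
        full_fit = ols_fit(full_X, y)
        scale = full_fit
        iF, df_num, df_den, ip = f_block_test(main_fit, full_fit)
    else:
        full_fit = main_fit
        scale = main_fit
        iF, df_num, df_den, ip = (np.nan, 0, main_fit.df_resid, np.nan)

    rows, _ = sequential_f_table(main_blocks, y, scale_fit=scale)
    return PlantGrowthResult(
        terms=rows,
        interaction_F=float(iF),
        interaction_df=(df_num, df_den),
        interaction_p=float(ip),
        rss_full=full_fit.rss,
        df_full=full_fit.df_resid,
    )
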