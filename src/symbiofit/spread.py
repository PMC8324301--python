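"""Symbiont frequency dynamics under host-fitness selection.

The per-generation recursion combines three forces acting on the infected
frequency p:

1. selection: infected hosts reproduce with relative fitness w, so
   p_s = w p / (w p + (1 - p));
2. vertical transmission with fidelity v: a fraction v of infected
   parents' offspring inherit the symbiont, p_v = v p_s;
3. horizontal transmission: uninfected offspring acquire the symbiont by
   mass action with coefficient h, p' = p_v + (1 - p_v) h p_s.

With perfect vertical fidelity and no horizontal gain (v = 1, h = 0) the
recursion is pure haploid selection and advances logit(p) by exactly ln w
per generation, giving the closed form for the number of generations to
reach a threshold frequency. A Wright-Fisher companion resamples the
expected frequency binomially in a finite population each generation.
Relative fitness can also be recovered from a prevalence time series via a
binomial logit GLM on time: the yearly logit slope divided by the number of
generations per year is ln w.

Defaults encode the study conditions: w = 1.38 (a 38% net-reproductive-rate
uplift under infection), rare introduction p0 = 0.01, near-fixation
threshold 0.99, four host generations per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ._glm import fit_binomial_irls
from .exceptions import SeparationError, ValidationError

__all__ = [
    "SpreadParams",
    "Trajectory",
    "step",
    "generations_to_threshold",
    "simulate_deterministic",
    "simulate_wf",
    "FitnessFit",
    "fit_w_from_prevalence",
]

DEFAULT_W = 1.38
DEFAULT_P0 = 0.01
DEFAULT_THRESHOLD = 0.99
DEFAULT_GENERATIONS_PER_YEAR = 4


@dataclass
class SpreadParams:
    """Parameters of the symbiont-spread recursion."""

    w: float = DEFAULT_W
    v: float = 1.0
    h: float = 0.0
    p0: float = DEFAULT_P0
    N: int = 100_000
    generations_per_year: int = DEFAULT_GENERATIONS_PER_YEAR

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValidationError("relative fitness w must be > 0")
        if not 0.0 <= self.v <= 1.0:
            raise ValidationError("vertical fidelity v must lie in [0, 1]")
        if not 0.0 <= self.h <= 1.0:
            raise ValidationError("horizontal coefficient h must lie in [0, 1]")
        if not 0.0 < self.p0 < 1.0:
            raise ValidationError("initial frequency p0 must lie in (0, 1)")
        if self.N < 2:
            raise ValidationError("population size N must be >= 2")
        if self.generations_per_year < 1:
            raise ValidationError("generations_per_year must be >= 1")


@dataclass
class Trajectory:
    """A frequency trajectory with threshold-crossing metadata."""

    frequencies: np.ndarray
    generations_to_threshold: int | None
    threshold: float
    stochastic: bool
    seed: int | None = None
    params: SpreadParams = field(default=None, repr=False)


def step(p: float, params: SpreadParams) -> float:
    """Advance the infected frequency by one host generation."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"frequency {p} outside [0, 1]")
    denom = params.w * p + (1.0 - p)
    p_s = params.w * p / denom
    p_v = params.v * p_s
    return p_v + (1.0 - p_v) * params.h * p_s


def _odds(p: float) -> float:
    return p / (1.0 - p)


def generations_to_threshold(
    p0: float = DEFAULT_P0,
    p_final: float = DEFAULT_THRESHOLD,
    w: float = DEFAULT_W,
) -> int:
    """Generations for pure selection to lift frequency p0 to p_final.

    Pure selection (v = 1, h = 0) multiplies the odds of infection by w
    each generation, so the count is ceil(ln(odds(p_final)/odds(p0))/ln w).
    """
    if not 0.0 < p0 < 1.0 or not 0.0 < p_final < 1.0:
        raise ValidationError("frequencies must lie strictly inside (0, 1)")
    if p_final < p0:
        raise ValidationError("p_final must be >= p0")
    if p_final == p0:
        return 0
    if w <= 1.0:
        raise ValidationError("threshold unreachable: w must exceed 1 for frequency gain")
    ratio = math.log(_odds(p_final) / _odds(p0)) / math.log(w)
    n = math.ceil(ratio)
    # guard against ceil landing a hair above/below the true crossing
    # because of float rounding in the odds ratio
    if _odds(p0) * w ** (n - 1) >= _odds(p_final):
        n -= 1
    return int(n)


def _first_crossing(freqs: np.ndarray, threshold: float) -> int | None:
    hit = np.nonzero(freqs >= threshold)[0]
    return int(hit[0]) if len(hit) else None


def simulate_deterministic(
    params: SpreadParams,
    T: int,
    threshold: float = DEFAULT_THRESHOLD,
) -> Trajectory:
    """Iterate the deterministic recursion for T generations."""
    if T < 1:
        raise ValidationError("T must be >= 1")
    freqs = np.empty(T + 1)
    freqs[0] = params.p0
    p = params.p0
    for t in range(1, T + 1):
        p = step(p, params)
        freqs[t] = p
    return Trajectory(
        frequencies=freqs,
        generations_to_threshold=_first_crossing(freqs, threshold),
        threshold=threshold,
        stochastic=False,
        params=params,
    )


def simulate_wf(
    params: SpreadParams,
    T: int,
    seed: int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> Trajectory:
    """Wright-Fisher simulation: binomial resampling around the recursion.

    Each generation the deterministic expectation is computed from the
    current frequency and the next frequency is Binomial(N, expected)/N.
    """
    if T < 1:
        raise ValidationError("T must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.empty(T + 1)
    freqs[0] = params.p0
    p = params.p0
    for t in range(1, T + 1):
        expected = step(p, params)
        p = rng.binomial(params.N, expected) / params.N
        freqs[t] = p
    return Trajectory(
        frequencies=freqs,
        generations_to_threshold=_first_crossing(freqs, threshold),
        threshold=threshold,
        stochastic=True,
        seed=seed,
        params=params,
    )


@dataclass
class FitnessFit:
    """Relative fitness recovered from a prevalence time series."""

    w: float
    se_w: float
    slope_per_year: float
    se_slope: float
    generations_per_year: int


def fit_w_from_prevalence(
    years: np.ndarray,
    n_tested: np.ndarray,
    n_positive: np.ndarray,
    generations_per_year: int = DEFAULT_GENERATIONS_PER_YEAR,
) -> FitnessFit:
    """Estimate relative fitness w from yearly prevalence counts.

    Fits a binomial logit GLM of positives on calendar year; under pure
    selection the yearly logit slope is (generations per year) x ln w, so
    w = exp(slope / generations_per_year) with a delta-method SE.
    """
    years = np.asarray(years, float)
    n = np.asarray(n_tested, float)
    y = np.asarray(n_positive, float)
    if len(years) < 3:
        raise ValidationError("need >= 3 time points to estimate a trend")
    if np.any(y <= 0) or np.any(y >= n):
        raise SeparationError("prevalence of 0% or 100% in a cell: logit slope unbounded")
    yc = years - years.mean()  # centering leaves the slope unchanged
    X = np.column_stack([np.ones_like(yc), yc])
    glm = fit_binomial_irls(X, y, n, link="logit", names=["intercept", "year"])
    slope = float(glm.coef[1])
    se_slope = float(glm.se[1])
    w = math.exp(slope / generations_per_year)
    se_w = w * se_slope / generations_per_year
    return FitnessFit(
        w=w,
        se_w=float(se_w),
        slope_per_year=slope,
        se_slope=se_slope,
        generations_per_year=generations_per_year,
    )
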