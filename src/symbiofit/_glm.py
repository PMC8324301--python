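"""Binomial GLM core fitted by iteratively reweighted least squares (IRLS).

All binomial regressions in the package (probit dose-response curves, the
pooled bioassay model, prevalence trends, symbiont-fitness estimation) share
this fitter. It works on grouped data (successes out of trials per row),
supports logit and probit links, and exposes the quantities bioassay and
trend inference need downstream: the coefficient covariance from the
weighted normal equations, the residual deviance, and the Pearson chi-square
for heterogeneity assessment.

Convergence is declared when the deviance changes by less than ``tol``
(relative) between iterations; the default tolerance is 1e-8 with at most
50 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .exceptions import ConvergenceError, SeparationError, ValidationError

LINKS = ("logit", "probit")

_MU_EPS = 1e-10
# |eta| beyond this on the logit scale implies fitted probabilities
# indistinguishable from 0/1 -> treat as separation.
_ETA_SEPARATION = 25.0


def _inverse_link(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "logit":
        return special.expit(eta)
    return special.ndtr(eta)


def _link(p: np.ndarray, link: str) -> np.ndarray:
    if link == "logit":
        return special.logit(p)
    return special.ndtri(p)


def _dmu_deta(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "logit":
        m = special.expit(eta)
        return m * (1.0 - m)
    return np.exp(-0.5 * eta * eta) / np.sqrt(2.0 * np.pi)


def binomial_deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    """Residual deviance of grouped binomial data against fitted means."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    mu = np.clip(np.asarray(mu, float), _MU_EPS, 1.0 - _MU_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = special.xlogy(y, y) - special.xlogy(y, n * mu)
        term2 = special.xlogy(n - y, n - y) - special.xlogy(n - y, n * (1.0 - mu))
    # xlogy(y, y) uses counts, xlogy(y, n*mu) expected counts: combine as
    # 2*sum(y log(y/(n mu)) + (n-y) log((n-y)/(n(1-mu))))
    return float(2.0 * np.sum(term1 + term2))


def binomial_loglik(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    """Binomial log-likelihood up to the data-only combinatorial constant."""
    mu = np.clip(np.asarray(mu, float), _MU_EPS, 1.0 - _MU_EPS)
    return float(np.sum(special.xlogy(y, mu) + special.xlogy(n - y, 1.0 - mu)))


@dataclass
class GlmResult:
    """Fitted binomial GLM on grouped data."""

    coef: np.ndarray
    cov: np.ndarray
    names: list[str]
    link: str
    deviance: float
    pearson_chi2: float
    df_resid: int
    loglik: float
    converged: bool
    separated: bool
    n_iter: int
    n_obs: int
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting on the gram matrix
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[j] for j in range(X.shape[1]) if diag[j] <= tol]
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased terms: {aliased or 'undetermined'}"
        )


def fit_binomial_irls(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    *,
    link: str = "logit",
    tol: float = 1e-8,
    max_iter: int = 50,
    names: list[str] | None = None,
) -> GlmResult:
    """Fit a binomial GLM by IRLS on grouped (successes, trials) data.

    Parameters
    ----------
    X : (n_groups, p) design matrix including any intercept column.
    successes, trials : per-group counts; successes may be non-integer when
        upstream corrections (e.g. control-mortality adjustment) produce
        fractional pseudo-counts.
    link : "logit" or "probit".
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(successes, float)
    n = np.asarray(trials, float)
    if link not in LINKS:
        raise ValidationError(f"unknown link {link!r}; expected one of {LINKS}")
    if X.shape[0] != y.shape[0] or y.shape[0] != n.shape[0]:
        raise ValidationError("design, successes and trials must have equal length")
    if np.any(n <= 0):
        raise ValidationError("all trial counts must be positive")
    if np.any(y < 0) or np.any(y > n):
        raise ValidationError("successes must lie in [0, trials] for every group")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    _check_rank(X, names)

    # empirical-proportion start with a half-count shrinkage
    p0 = (y + 0.5) / (n + 1.0)
    eta = _link(p0, link)
    dev = np.inf
    converged = False
    it = 0
    beta = np.zeros(X.shape[1])
    for it in range(1, max_iter + 1):
        mu = np.clip(_inverse_link(eta, link), _MU_EPS, 1.0 - _MU_EPS)
        d = np.maximum(_dmu_deta(eta, link), _MU_EPS)
        var = mu * (1.0 - mu)
        w = n * d * d / var
        z = eta + (y / n - mu) / d
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        mu = np.clip(_inverse_link(eta, link), _MU_EPS, 1.0 - _MU_EPS)
        new_dev = binomial_deviance(y, n, mu)
        if np.isfinite(new_dev) and abs(dev - new_dev) < tol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev

    mu = np.clip(_inverse_link(eta, link), _MU_EPS, 1.0 - _MU_EPS)
    d = np.maximum(_dmu_deta(eta, link), _MU_EPS)
    w = n * d * d / (mu * (1.0 - mu))
    xtwx = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rank-checked above
        raise ValidationError("singular information matrix") from exc

    pearson = float(np.sum(n * (y / n - mu) ** 2 / (mu * (1.0 - mu))))
    separated = bool(np.any(np.abs(eta) > _ETA_SEPARATION * (1.0 if link == "logit" else 0.35)))
    return GlmResult(
        coef=beta,
        cov=cov,
        names=list(names),
        link=link,
        deviance=dev,
        pearson_chi2=pearson,
        df_resid=X.shape[0] - X.shape[1],
        loglik=binomial_loglik(y, n, mu),
        converged=converged,
        separated=separated,
        n_iter=it,
        n_obs=X.shape[0],
        fitted=mu,
    )


def sequential_deviance_table(
    blocks: list[tuple[str, np.ndarray]],
    successes: np.ndarray,
    trials: np.ndarray,
    *,
    link: str = "logit",
) -> tuple[list[dict], GlmResult]:
    """Type-I (sequential) likelihood-ratio decomposition.

    ``blocks`` is an ordered list of named column blocks; the first is fit
    alone, then each subsequent block is added. Returns per-block rows with
    the deviance drop (chi2), its df, and the chi-square p-value, plus the
    full-model fit.
    """
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    names: list[str] = []
    prev: GlmResult | None = None
    fit: GlmResult | None = None
    for name, block in blocks:
        block = np.atleast_2d(np.asarray(block, float))
        if block.shape[0] != len(successes):
            block = block.T
        cols.append(block)
        names.extend(
            [name] if block.shape[1] == 1 else [f"{name}[{j}]" for j in range(block.shape[1])]
        )
        X = np.hstack(cols)
        fit = fit_binomial_irls(X, successes, trials, link=link, names=names)
        if prev is not None:
            chi2 = max(prev.deviance - fit.deviance, 0.0)
            df = block.shape[1]
            rows.append(
                {
                    "term": name,
                    "chi2": chi2,
                    "df": df,
                    "p": float(stats.chi2.sf(chi2, df)),
                }
            )
        prev = fit
    if fit is None:
        raise ValidationError("at least one design block is required")
    if not fit.converged:
        raise ConvergenceError("full model did not converge in sequential decomposition")
    if fit.separated:
        raise SeparationError("fitted probabilities at 0/1: separation in full model")
    return rows, fit
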