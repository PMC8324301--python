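"""Ordinary least squares helpers: fits, sequential (type-I) F tables.

Used by the plant-growth model, the RADR comparison model, and the simple
trend regressions. Deliberately small: design matrices are built by the
calling modules, this module only does the linear algebra and the F
reference distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError


@dataclass
class OlsFit:
    coef: np.ndarray
    rss: float
    df_resid: int
    names: list[str]

    @property
    def sigma2(self) -> float:
        return self.rss / self.df_resid


def ols_fit(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OlsFit:
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("design and response lengths differ")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError("rank-deficient OLS design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return OlsFit(
        coef=beta,
        rss=rss,
        df_resid=X.shape[0] - X.shape[1],
        names=names or [f"x{j}" for j in range(X.shape[1])],
    )


def sequential_f_table(
    blocks: list[tuple[str, np.ndarray]],
    y: np.ndarray,
    *,
    scale_fit: OlsFit | None = None,
) -> tuple[list[dict], OlsFit]:
    """Type-I ANOVA: each block's sum of squares given all earlier blocks.

    F denominators use the mean squared error of the final (fullest) model,
    or of ``scale_fit`` when the error scale should come from a larger model.
    """
    y = np.asarray(y, float)
    fits: list[OlsFit] = []
    cols: list[np.ndarray] = []
    for name, block in blocks:
        block = np.atleast_2d(np.asarray(block, float))
        if block.shape[0] != len(y):
            block = block.T
        cols.append(block)
        fits.append(ols_fit(np.hstack(cols), y))
    full = scale_fit or fits[-1]
    mse = full.sigma2
    rows: list[dict] = []
    for prev, cur, (name, block) in zip(fits, fits[1:], blocks[1:]):
        block = np.atleast_2d(np.asarray(block, float))
        df = block.shape[1] if block.shape[0] != len(y) else block.shape[1]
        df = prev.df_resid - cur.df_resid
        ss = max(prev.rss - cur.rss, 0.0)
        f = (ss / df) / mse
        rows.append(
            {
                "term": name,
                "df": df,
                "ss": ss,
                "F": f,
                "p": float(stats.f.sf(f, df, full.df_resid)),
            }
        )
    return rows, fits[-1]


def f_block_test(fit_reduced: OlsFit, fit_full: OlsFit) -> tuple[float, int, int, float]:
    """F test for the block of terms distinguishing two nested OLS fits."""
    df_num = fit_reduced.df_resid - fit_full.df_resid
    if df_num <= 0:
        raise ValidationError("models are not strictly nested")
    f = ((fit_reduced.rss - fit_full.rss) / df_num) / fit_full.sigma2
    p = float(stats.f.sf(f, df_num, fit_full.df_resid))
    return float(f), df_num, fit_full.df_resid, p
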