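"""Relative average development rate (RADR) per isofemale line.

A line's RADR is the mean larval developmental-stage rating on Cry1Ac diet
divided by the mean rating on toxin-free diet; values near one indicate
development unimpeded by the toxin. Lines are the analysis unit: RADR is
computed per line and line-level values are then compared across infection
status and year with a sequential-F linear model, or summarized per
population-by-year with standard errors and line-level infection
prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linmod import sequential_f_table
from .exceptions import ValidationError

__all__ = [
    "LineRating",
    "RadrEstimate",
    "line_radr",
    "lines_from_table",
    "radr_table",
    "compare_radr",
    "annual_radr_summary",
]

DEAD_POLICIES = ("exclude", "zero")


@dataclass
class LineRating:
    """Ratings of one isofemale line's neonates split across the two diets."""

    line_id: str
    hadv2: str
    ratings_bt: list[float]
    ratings_nonbt: list[float]
    dead_bt: int = 0
    dead_nonbt: int = 0
    population: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        for name, vals in (("ratings_bt", self.ratings_bt), ("ratings_nonbt", self.ratings_nonbt)):
            if any(v < 0 for v in vals):
                raise ValidationError(f"{name} of line {self.line_id} contains negative scores")
        if self.dead_bt < 0 or self.dead_nonbt < 0:
            raise ValidationError("dead counts must be non-negative")


@dataclass
class RadrEstimate:
    radr: float
    n_bt: int
    n_nonbt: int


def _diet_mean(ratings: list[float], dead: int, policy: str, diet: str, line_id: str) -> tuple[float, int]:
    if policy not in DEAD_POLICIES:
        raise ValidationError(f"dead_policy must be one of {DEAD_POLICIES}")
    vals = list(ratings)
    if policy == "zero":
        vals = vals + [0.0] * dead
    if not vals:
        raise ValidationError(f"line {line_id}: no scored larvae on {diet} diet")
    return float(np.mean(vals)), len(vals)


def line_radr(line: LineRating, dead_policy: str = "exclude") -> RadrEstimate:
    """RADR of one line: mean Bt-diet rating over mean non-Bt-diet rating.

    Under ``dead_policy="zero"`` larvae that died before scoring contribute
    a rating of zero to their diet's mean; under ``"exclude"`` (default)
    only scored survivors count.
    """
    mean_bt, n_bt = _diet_mean(line.ratings_bt, line.dead_bt, dead_policy, "Bt", line.line_id)
    mean_nb, n_nb = _diet_mean(line.ratings_nonbt, line.dead_nonbt, dead_policy, "non-Bt", line.line_id)
    if mean_nb <= 0:
        raise ValidationError(f"line {line.line_id}: non-Bt mean rating is zero; RADR undefined")
    return RadrEstimate(radr=mean_bt / mean_nb, n_bt=n_bt, n_nonbt=n_nb)


def lines_from_table(ratings: pd.DataFrame) -> list[LineRating]:
    """Group a long-format ratings table into per-line records."""
    req = {"line_id", "hadv2", "diet", "rating"}
    missing = req - set(ratings.columns)
    if missing:
        raise ValidationError(f"ratings table missing columns {sorted(missing)}")
    out = []
    for line_id, grp in ratings.groupby("line_id", sort=True):
        out.append(
            LineRating(
                line_id=str(line_id),
                hadv2=str(grp["hadv2"].iloc[0]),
                ratings_bt=grp.loc[grp["diet"] == "bt", "rating"].tolist(),
                ratings_nonbt=grp.loc[grp["diet"] == "non_bt", "rating"].tolist(),
                population=str(grp["population"].iloc[0]) if "population" in grp else "",
                year=int(grp["year"].iloc[0]) if "year" in grp else None,
            )
        )
    return out


def radr_table(lines: list[LineRating], dead_policy: str = "exclude") -> pd.DataFrame:
    """Per-line RADR values with metadata, one row per line."""
    rows = []
    for ln in lines:
        est = line_radr(ln, dead_policy)
        rows.append(
            {
                "line_id": ln.line_id,
                "hadv2": ln.hadv2,
                "population": ln.population,
                "year": ln.year,
                "radr": est.radr,
                "n_bt": est.n_bt,
                "n_nonbt": est.n_nonbt,
            }
        )
    return pd.DataFrame(rows)


def compare_radr(
    lines: list[LineRating] | pd.DataFrame,
    dead_policy: str = "exclude",
    include_year: bool | None = None,
) -> list[dict]:
    """Sequential-F linear model of line RADR on infection status and year.

    Returns per-term rows (term, df, F, p). Year terms are included when
    more than one year is present (or as forced by ``include_year``); with
    a single factor the status F equals the squared two-sample t.
    """
    tab = lines if isinstance(lines, pd.DataFrame) else radr_table(lines, dead_policy)
    statuses = set(tab["hadv2"].unique())
    if len(statuses) < 2:
        raise ValidationError("both infection statuses are required to compare RADR")
    y = tab["radr"].to_numpy(float)
    status = (tab["hadv2"] == "positive").to_numpy(float)
    years = tab["year"].to_numpy(float) if "year" in tab else np.zeros(len(tab))
    if include_year is None:
        include_year = len(np.unique(years[~np.isnan(years)])) > 1
    blocks = [("intercept", np.ones((len(y), 1))), ("status", status[:, None])]
    if include_year:
        yc = years - np.nanmean(years)
        blocks.append(("year", yc[:, None]))
        blocks.append(("status:year", (status * yc)[:, None]))
    rows, _ = sequential_f_table(blocks, y)
    return rows


def annual_radr_summary(
    lines: list[LineRating] | pd.DataFrame,
    dead_policy: str = "exclude",
) -> pd.DataFrame:
    """Mean RADR, SE, line count and infection prevalence per population-year.

    Groups with a single line carry SE 0 and a degenerate-group flag.
    """
    tab = lines if isinstance(lines, pd.DataFrame) else radr_table(lines, dead_policy)
    if len(tab) == 0:
        raise ValidationError("no lines to summarize")
    rows = []
    for (pop, year), grp in tab.groupby(["population", "year"], dropna=False):
        vals = grp["radr"].to_numpy(float)
        n = len(vals)
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "population": pop,
                "year": year,
                "mean_radr": float(vals.mean()),
                "se_radr": se,
                "n_lines": n,
                "prevalence_positive": float((grp["hadv2"] == "positive").mean()),
                "degenerate": n == 1,
            }
        )
    return pd.DataFrame(rows)
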