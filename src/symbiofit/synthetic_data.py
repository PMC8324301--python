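"""Seeded generators for the four assay data streams.

Each generator is a pure function of (design, seed) and returns a pandas
DataFrame matching the CSV schemas in :mod:`symbiofit.io`. The designs carry
the ground truth (dose-response curves, life-history component means,
rating means, prevalence trends) so downstream estimators can be tested for
parameter recovery.

Streams
-------
- bioassay: grouped mortality counts under a probit dose-response curve with
  an optional Abbott-style control-mortality mixture.
- lifetable: per-individual draws of the 13 life-history fitness components
  (stage survivals, development durations, pupal weight, emergence, sex,
  copulation, adult longevities, fecundity, egg hatch).
- ratings: per-line larval developmental-stage ratings on Bt and non-Bt
  diet, from which the relative average development rate (RADR) derives.
- prevalence: per-province-by-year binomial infection counts following a
  logistic time trend, with environmental covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import ValidationError

__all__ = [
    "BioassayDesign",
    "LifeTableDesign",
    "RadrDesign",
    "ProvinceHistory",
    "PrevalenceDesign",
    "gen_bioassay",
    "gen_lifetable",
    "gen_ratings",
    "gen_prevalence",
    "lifetable_design_r0",
    "substream_seeds",
]


def substream_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent generator seeds from one master seed.

    Uses numpy's SeedSequence spawning so the substreams are statistically
    independent; seed i always maps to the same substream for a given
    master seed.
    """
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


# ---------------------------------------------------------------------------
# bioassay stream
# ---------------------------------------------------------------------------


@dataclass
class BioassayDesign:
    """One strain-by-infection arm of a diet-incorporation bioassay.

    The mortality curve is pi(d) = c + (1-c) * Phi(slope * (log10 d - m))
    with m the true log10 LC50, c the control mortality, and Phi the
    standard normal CDF. Default group size is 72 larvae per concentration.
    """

    strain_name: str
    hadv2_status: str  # "positive" | "negative"
    true_log10_lc50: float
    probit_slope: float
    doses: tuple[float, ...]
    n_per_dose: int = 72
    control_mortality: float = 0.0

    def __post_init__(self) -> None:
        if self.hadv2_status not in ("positive", "negative"):
            raise ValidationError(f"hadv2_status must be positive/negative, got {self.hadv2_status!r}")
        doses = tuple(float(d) for d in self.doses)
        for i, d in enumerate(doses):
            if d <= 0:
                raise ValidationError(f"dose at position {i} is {d}; doses must be strictly positive")
        if list(doses) != sorted(doses):
            raise ValidationError("doses must be sorted ascending")
        if self.n_per_dose < 1:
            raise ValidationError("n_per_dose must be >= 1")
        if self.probit_slope <= 0:
            raise ValidationError("probit_slope must be > 0")
        if not 0.0 <= self.control_mortality < 1.0:
            raise ValidationError("control_mortality must lie in [0, 1)")
        self.doses = doses

    def mortality(self, dose: np.ndarray) -> np.ndarray:
        """True expected mortality at the given doses."""
        dose = np.asarray(dose, float)
        z = self.probit_slope * (np.log10(dose) - self.true_log10_lc50)
        c = self.control_mortality
        return c + (1.0 - c) * special.ndtr(z)


def gen_bioassay(design: BioassayDesign, seed: int) -> pd.DataFrame:
    """Simulate grouped mortality counts for one bioassay arm.

    A dose-0 control group (mortality = control_mortality) is emitted when
    the design's control mortality is positive, so Abbott correction can be
    exercised downstream.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(design.doses, float)
    pi = design.mortality(doses)
    n_dead = rng.binomial(design.n_per_dose, pi)
    rows = {
        "strain": design.strain_name,
        "hadv2": design.hadv2_status,
        "dose_ug_ml": doses,
        "n_tested": design.n_per_dose,
        "n_dead": n_dead,
    }
    out = pd.DataFrame(rows)
    if design.control_mortality > 0:
        control = pd.DataFrame(
            {
                "strain": [design.strain_name],
                "hadv2": [design.hadv2_status],
                "dose_ug_ml": [0.0],
                "n_tested": [design.n_per_dose],
                "n_dead": [rng.binomial(design.n_per_dose, design.control_mortality)],
            }
        )
        out = pd.concat([control, out], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# lifetable stream
# ---------------------------------------------------------------------------


@dataclass
class LifeTableDesign:
    """Component means for one strain-by-infection life-table cohort.

    The 13 components: two larval-stage survivals, larval duration, pupal
    weight, female and male pupal durations, adult emergence, proportion
    female, copulation rate, female and male adult longevities, fecundity,
    and egg hatch rate. Durations/weights are truncated normal above zero,
    survivals and rates Bernoulli, fecundity Poisson, hatch per-egg
    Bernoulli. Defaults: 30 larvae per replicate, 3 replicates.
    """

    strain_name: str
    hadv2_status: str
    surv_l1_l5: float = 0.90
    surv_l5_pupa: float = 0.95
    larval_duration_mean: float = 16.0
    larval_duration_sd: float = 1.2
    pupal_weight_mean: float = 320.0
    pupal_weight_sd: float = 30.0
    female_pupal_duration_mean: float = 11.0
    female_pupal_duration_sd: float = 0.8
    male_pupal_duration_mean: float = 12.0
    male_pupal_duration_sd: float = 0.8
    emergence_rate: float = 0.92
    proportion_female: float = 0.5
    copulation_rate: float = 0.90
    female_longevity_mean: float = 10.0
    female_longevity_sd: float = 1.5
    male_longevity_mean: float = 9.0
    male_longevity_sd: float = 1.5
    fecundity_mean: float = 500.0
    hatch_rate: float = 0.85
    n_per_replicate: int = 30
    n_replicates: int = 3

    def __post_init__(self) -> None:
        probs = {
            "surv_l1_l5": self.surv_l1_l5,
            "surv_l5_pupa": self.surv_l5_pupa,
            "emergence_rate": self.emergence_rate,
            "proportion_female": self.proportion_female,
            "copulation_rate": self.copulation_rate,
            "hatch_rate": self.hatch_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} = {p} outside [0, 1]")
        positives = {
            "larval_duration_mean": self.larval_duration_mean,
            "pupal_weight_mean": self.pupal_weight_mean,
            "female_pupal_duration_mean": self.female_pupal_duration_mean,
            "male_pupal_duration_mean": self.male_pupal_duration_mean,
            "female_longevity_mean": self.female_longevity_mean,
            "male_longevity_mean": self.male_longevity_mean,
            "fecundity_mean": self.fecundity_mean,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValidationError(f"{name} = {v}; must be > 0")
        if self.n_per_replicate < 1 or self.n_replicates < 1:
            raise ValidationError("replicate counts must be >= 1")


def lifetable_design_r0(design: LifeTableDesign) -> float:
    """Expected daughters per female implied by the design's means."""
    return (
        design.surv_l1_l5
        * design.surv_l5_pupa
        * design.emergence_rate
        * design.copulation_rate
        * design.fecundity_mean
        * design.hatch_rate
        * design.proportion_female
    )


def _truncnorm_positive(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def gen_lifetable(design: LifeTableDesign, seed: int) -> pd.DataFrame:
    """Simulate per-individual life-history records for one cohort.

    Components are drawn independently per individual so each column's mean
    converges to its design value; sex-specific columns (pupal duration,
    longevity, fecundity, hatch) are missing for the other sex.
    """
    rng = np.random.default_rng(seed)
    n = design.n_per_replicate * design.n_replicates
    female = rng.random(n) < design.proportion_female
    fecundity = np.where(female, rng.poisson(design.fecundity_mean, n), 0).astype(float)
    # per-egg Bernoulli hatching
    eggs = fecundity.astype(int)
    hatched = rng.binomial(np.maximum(eggs, 1), design.hatch_rate)
    hatch_frac = np.where(eggs > 0, hatched / np.maximum(eggs, 1), np.nan)
    df = pd.DataFrame(
        {
            "strain": design.strain_name,
            "hadv2": design.hadv2_status,
            "replicate": np.repeat(np.arange(1, design.n_replicates + 1), design.n_per_replicate),
            "individual_id": np.arange(1, n + 1),
            "surv_l1_l5": (rng.random(n) < design.surv_l1_l5).astype(int),
            "surv_l5_pupa": (rng.random(n) < design.surv_l5_pupa).astype(int),
            "larval_duration": _truncnorm_positive(rng, design.larval_duration_mean, design.larval_duration_sd, n),
            "pupal_weight": _truncnorm_positive(rng, design.pupal_weight_mean, design.pupal_weight_sd, n),
            "female": female.astype(int),
            "female_pupal_duration": np.where(
                female, _truncnorm_positive(rng, design.female_pupal_duration_mean, design.female_pupal_duration_sd, n), np.nan
            ),
            "male_pupal_duration": np.where(
                ~female, _truncnorm_positive(rng, design.male_pupal_duration_mean, design.male_pupal_duration_sd, n), np.nan
            ),
            "emerged": (rng.random(n) < design.emergence_rate).astype(int),
            "copulated": (rng.random(n) < design.copulation_rate).astype(int),
            "female_longevity": np.where(
                female, _truncnorm_positive(rng, design.female_longevity_mean, design.female_longevity_sd, n), np.nan
            ),
            "male_longevity": np.where(
                ~female, _truncnorm_positive(rng, design.male_longevity_mean, design.male_longevity_sd, n), np.nan
            ),
            "fecundity": np.where(female, fecundity, np.nan),
            "hatch_rate": np.where(female, hatch_frac, np.nan),
        }
    )
    return df


# ---------------------------------------------------------------------------
# ratings stream
# ---------------------------------------------------------------------------


@dataclass
class RadrDesign:
    """Isofemale-line development-rating design for RADR estimation.

    Per line, ``n_per_diet`` neonates are scored on each diet after a fixed
    exposure; ratings are truncated-normal scores clipped to
    [0, rating_scale_max]. Lines are infected with probability
    ``prevalence_positive`` and the Bt-diet mean depends on infection
    status, mirroring the faster development of infected larvae on toxin.
    Ratings are continuous by default; set ``integer_ratings`` for
    instar-style integer scores.
    """

    n_lines: int = 50
    n_per_diet: int = 24
    rating_scale_max: int = 6
    mean_rating_nonbt: float = 5.0
    mean_rating_bt_by_status: dict = field(
        default_factory=lambda: {"positive": 3.1, "negative": 2.6}
    )
    dispersion: float = 0.8
    prevalence_positive: float = 0.98
    integer_ratings: bool = False
    population: str = "field"
    year: int = 2015

    def __post_init__(self) -> None:
        if self.rating_scale_max < 1:
            raise ValidationError("rating_scale_max must be >= 1")
        if self.n_lines < 1 or self.n_per_diet < 1:
            raise ValidationError("n_lines and n_per_diet must be >= 1")
        if not 0.0 < self.mean_rating_nonbt <= self.rating_scale_max:
            raise ValidationError("mean_rating_nonbt must lie in (0, rating_scale_max]")
        for status, m in self.mean_rating_bt_by_status.items():
            if status not in ("positive", "negative"):
                raise ValidationError(f"unknown status {status!r} in mean_rating_bt_by_status")
            if not 0.0 < m <= self.rating_scale_max:
                raise ValidationError(f"Bt mean rating for {status} must lie in (0, rating_scale_max]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0.0 <= self.prevalence_positive <= 1.0:
            raise ValidationError("prevalence_positive must lie in [0, 1]")


def _draw_ratings(
    rng: np.random.Generator, mean: float, sd: float, hi: float, size: int, integer: bool
) -> np.ndarray:
    if sd == 0:
        vals = np.full(size, mean)
    else:
        vals = np.clip(rng.normal(mean, sd, size), 0.0, hi)
    if integer:
        vals = np.rint(vals)
    return vals


def gen_ratings(design: RadrDesign, seed: int) -> pd.DataFrame:
    """Simulate per-larva ratings for each line on both diets."""
    rng = np.random.default_rng(seed)
    frames = []
    hi = float(design.rating_scale_max)
    for i in range(1, design.n_lines + 1):
        status = "positive" if rng.random() < design.prevalence_positive else "negative"
        bt_mean = design.mean_rating_bt_by_status[status]
        r_bt = _draw_ratings(rng, bt_mean, design.dispersion, hi, design.n_per_diet, design.integer_ratings)
        r_nb = _draw_ratings(
            rng, design.mean_rating_nonbt, design.dispersion, hi, design.n_per_diet, design.integer_ratings
        )
        frames.append(
            pd.DataFrame(
                {
                    "line_id": f"L{i:03d}",
                    "hadv2": status,
                    "population": design.population,
                    "year": design.year,
                    "diet": ["bt"] * design.n_per_diet + ["non_bt"] * design.n_per_diet,
                    "rating": np.concatenate([r_bt, r_nb]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# prevalence stream
# ---------------------------------------------------------------------------


@dataclass
class ProvinceHistory:
    """A province's Bt-cotton deployment history."""

    name: str
    bt_grown: bool
    bt_proportion_by_year: dict = field(default_factory=dict)
    rainfall_mm: float = 600.0
    temp_c: float = 14.0
    altitude_m: float = 50.0

    def __post_init__(self) -> None:
        for y, p in self.bt_proportion_by_year.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"Bt proportion {p} for {self.name} year {y} outside [0, 1]")

    def intro_year(self, threshold: float = 0.10) -> int | None:
        """First year Bt-cotton reached the given proportion, if ever."""
        years = sorted(y for y, p in self.bt_proportion_by_year.items() if p >= threshold)
        return years[0] if years else None


@dataclass
class PrevalenceDesign:
    """Logistic prevalence-trend design across provinces and years.

    The infection probability in province i, year t is
    expit(intercept + slope*t + quadratic*t^2 + bt_effect*[province grows Bt]).
    Coefficients act on calendar year, matching the large printed intercepts
    of logistic trend fits on calendar time.
    """

    provinces: list[ProvinceHistory]
    years: tuple[int, ...]
    n_per_sample: int = 100
    logit_intercept: float = -993.1444
    logit_year_slope: float = 0.49473
    logit_year_quadratic: float = 0.0
    logit_bt_effect: float = 0.0
    covariate_sds: tuple[float, float, float] = (80.0, 1.5, 10.0)

    def __post_init__(self) -> None:
        if self.n_per_sample < 1:
            raise ValidationError("n_per_sample must be >= 1")
        if not self.provinces:
            raise ValidationError("at least one province is required")
        for prov in self.provinces:
            for year in self.years:
                p = self.expected_prevalence(prov, year)
                if not 0.0 < p < 1.0:
                    raise ValidationError(
                        f"implied prevalence {p} outside (0,1) for province {prov.name}, year {year}"
                    )

    def expected_prevalence(self, province: ProvinceHistory, year: int) -> float:
        eta = (
            self.logit_intercept
            + self.logit_year_slope * year
            + self.logit_year_quadratic * year**2
            + (self.logit_bt_effect if province.bt_grown else 0.0)
        )
        return float(special.expit(eta))


def gen_prevalence(design: PrevalenceDesign, seed: int) -> pd.DataFrame:
    """Simulate per-province-by-year infection counts and covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    sd_rain, sd_temp, sd_alt = design.covariate_sds
    for prov in design.provinces:
        intro = prov.intro_year()
        for year in design.years:
            p = design.expected_prevalence(prov, year)
            n_pos = int(rng.binomial(design.n_per_sample, p))
            rows.append(
                {
                    "location": f"{prov.name}-site",
                    "province": prov.name,
                    "year": year,
                    "n_tested": design.n_per_sample,
                    "n_positive": n_pos,
                    "bt_crop": "Bt" if prov.bt_grown else "non-Bt",
                    "bt_intro_year": intro if intro is not None else np.nan,
                    "bt_proportion": prov.bt_proportion_by_year.get(year, 0.0),
                    "rainfall_mm": rng.normal(prov.rainfall_mm, sd_rain),
                    "temp_c": rng.normal(prov.temp_c, sd_temp),
                    "altitude_m": max(rng.normal(prov.altitude_m, sd_alt), 0.0),
                }
            )
    return pd.DataFrame(rows)
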