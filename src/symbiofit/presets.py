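"""Named study-arm presets for the synthetic generators.

The presets encode the study conditions: a Cry1Ac-susceptible reference
strain, resistant strains with resistance ratios up to 240-fold, a ~1.5x
tolerance uplift in infected susceptible larvae, a 38% net-reproductive-rate
uplift under infection, field RADR component means of 0.62 (infected) vs
0.52 (uninfected) at 98% line-level prevalence, and a two-county logistic
prevalence trend on calendar year. Presets are convenient starting points
for simulation, not fitted estimates.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .synthetic_data import (
    BioassayDesign,
    LifeTableDesign,
    PrevalenceDesign,
    ProvinceHistory,
    RadrDesign,
)

#: reference LC50 of the susceptible strain (ug Cry1Ac / mL diet)
SUSCEPTIBLE_LC50 = 0.4

#: resistance ratios relative to the susceptible strain, per strain
RESISTANCE_RATIOS = {
    "LF": 1.0,
    "96S": 1.5,
    "LF5": 5.0,
    "LF60": 60.0,
    "LF240": 240.0,
}

#: LC50 uplift in infected larvae: 1.5x for susceptible strains, and a
#: mid-band 1.8x for resistant strains (enhanced tolerance 30-130%)
TOLERANCE_RATIOS = {
    "LF": 1.5,
    "96S": 1.5,
    "LF5": 1.8,
    "LF60": 1.8,
    "LF240": 1.8,
}


def geometric_doses(center: float, span_decades: float = 2.5, n: int = 6) -> tuple[float, ...]:
    """Geometric dose ladder centered on ``center`` spanning the decades."""
    lo = math.log10(center) - span_decades / 2.0
    hi = math.log10(center) + span_decades / 2.0
    return tuple(float(10.0**x) for x in np.linspace(lo, hi, n))


def bioassay_arm_designs(
    strain: str,
    *,
    slope: float = 2.0,
    n_per_dose: int = 72,
    control_mortality: float = 0.0,
) -> tuple[BioassayDesign, BioassayDesign]:
    """(uninfected, infected) bioassay designs for a preset strain."""
    lc50_neg = SUSCEPTIBLE_LC50 * RESISTANCE_RATIOS[strain]
    lc50_pos = lc50_neg * TOLERANCE_RATIOS[strain]
    center = math.sqrt(lc50_neg * lc50_pos)
    doses = geometric_doses(center)
    neg = BioassayDesign(
        strain_name=strain,
        hadv2_status="negative",
        true_log10_lc50=math.log10(lc50_neg),
        probit_slope=slope,
        doses=doses,
        n_per_dose=n_per_dose,
        control_mortality=control_mortality,
    )
    pos = replace(neg, hadv2_status="positive", true_log10_lc50=math.log10(lc50_pos))
    return neg, pos


#: multiplicative R0 cost of resistance (uninfected), relative to LF
FITNESS_COSTS = {"LF": 0.0, "LF5": 0.30, "LF60": 0.30, "LF240": 0.60}

#: R0 uplift of infection within each strain
RESCUE_UPLIFT = 1.38


def lifetable_arm_designs(strain: str) -> tuple[LifeTableDesign, LifeTableDesign]:
    """(uninfected, infected) life-table designs for a preset strain.

    The resistance cost is carried by fecundity and the early-larval
    survival; the infection uplift is carried by fecundity alone so the
    design R0 ratio is exactly RESCUE_UPLIFT.
    """
    cost = FITNESS_COSTS[strain]
    base = LifeTableDesign(strain_name=strain, hadv2_status="negative")
    surv_scale = 1.0 - 0.3 * cost
    fec_scale = (1.0 - cost) / surv_scale
    neg = replace(
        base,
        surv_l1_l5=base.surv_l1_l5 * surv_scale,
        fecundity_mean=base.fecundity_mean * fec_scale,
    )
    pos = replace(neg, hadv2_status="positive", fecundity_mean=neg.fecundity_mean * RESCUE_UPLIFT)
    return neg, pos


#: field isofemale-line rating design (Bt means by infection status give
#: per-line RADR components 0.62 infected / 0.52 uninfected)
FIELD_RADR_DESIGN = RadrDesign(
    n_lines=50,
    n_per_diet=24,
    rating_scale_max=6,
    mean_rating_nonbt=5.0,
    mean_rating_bt_by_status={"positive": 3.1, "negative": 2.6},
    dispersion=0.8,
    prevalence_positive=0.98,
)


def field_prevalence_design(n_per_sample: int = 100) -> PrevalenceDesign:
    """Two-county 2007-2016 logistic prevalence trend on calendar year."""
    bt_history = {y: min(0.05 + 0.1 * (y - 1997), 0.95) for y in range(1997, 2017)}
    provinces = [
        ProvinceHistory("Xiajin", True, bt_history, rainfall_mm=600, temp_c=13.5, altitude_m=30),
        ProvinceHistory("Anci", True, bt_history, rainfall_mm=550, temp_c=12.5, altitude_m=20),
    ]
    return PrevalenceDesign(
        provinces=provinces,
        years=tuple(range(2007, 2017)),
        n_per_sample=n_per_sample,
        logit_intercept=-993.1444,
        logit_year_slope=0.49473,
    )
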