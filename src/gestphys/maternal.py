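"""Preferred empirical models for the pregnant mother.

All quantities are functions of gestational age ``t`` in weeks (time since
the last menstrual period; conception is at roughly 2 weeks).  Volumes are in
litres unless noted, blood flows in L/h, hematocrit and glomerular filtration
in percent and mL/min respectively.  "Maternal mass" includes the products of
conception (fetus, placenta and amniotic fluid).

Where a quantity has both a preferred model and a documented alternative
(e.g. the kidney-flow cubic vs. its linear-transition form, or the quadratic
hematocrit vs. the plasma/RBC "ratio model"), the preferred form is the
default and the alternative stays callable through a ``method`` switch.

Composite quantities (rest-of-body volume and flow) are assembled lazily from
the component models, so the mass-balance and flow-conservation identities
hold to machine precision by construction.
"""

from __future__ import annotations

import numpy as np

from . import fetal
from .families import make_spec

__all__ = [
    "DENSITY_KG_PER_L",
    "FEMALE_PERCENT_OF_BODY_MASS",
    "TRANSITION_PERCENTS",
    "maternal_mass",
    "maternal_adipose",
    "maternal_blood_volumes",
    "maternal_hematocrit",
    "conceptus_volumes",
    "static_maternal_volumes",
    "maternal_fat_free_volume",
    "maternal_rest_of_body_volume",
    "maternal_cardiac_output",
    "maternal_transition_flow",
    "maternal_kidney_flow",
    "maternal_placenta_flow",
    "maternal_rest_of_body_flow",
    "maternal_gfr",
]

#: Tissue densities (kg/L).  Fat-free maternal mass is taken as 1.1 kg/L
#: throughout pregnancy.
DENSITY_KG_PER_L = {
    "adip": 0.95,
    "bran": 1.04,
    "thyr": 1.05,
    "kidn": 1.05,
    "gutx": 1.045,
    "livr": 1.05,
    "lung": 1.05,
    "artb": 1.06,
    "venb": 1.06,
    "plac": 1.02,
    "amnf": 1.01,
    "ffmx": 1.1,
}

#: Reference percent of total body mass for a non-pregnant woman.
FEMALE_PERCENT_OF_BODY_MASS = {
    "adip": 37.5,
    "bran": 2.17,
    "thyr": 0.0283,
    "kidn": 0.458,
    "gutx": 1.90,
    "livr": 2.33,
    "lung": 1.58,
}

#: Linear-transition percentages of cardiac output: (percent at 0 weeks,
#: percent at 40 weeks).  "Near term" is fixed at 40 weeks.
TRANSITION_PERCENTS = {
    "adip": (8.5, 7.8),
    "bran": (12.0, 8.8),
    "kidn": (17.0, 16.6),
    "gutx": (17.0, 12.5),
    "livr": (27.0, 20.0),
    "thyr": (1.5, 1.1),
    "utpl": (0.4, 12.0),  # uteroplacental share, used by the flawed Eq-21 form
}

NEAR_TERM_WEEKS = 40.0

# preferred closed forms ----------------------------------------------------

_MASS = make_spec("cubic", (61.103, -0.010614, 0.029161, -5.0203e-4))
_ADIPOSE_MASS = make_spec("linear", (17.067, 0.14937))
_PLASMA = make_spec("modified_logistic", (1.2406, 0.31338, 17.813, 2.4958))
_RBC_LOGISTIC = make_spec("modified_logistic", (0.32704, 0.62555, 21.452, 1.5169))
_PLACENTA_VOL = make_spec("cubic_growth", (-1.7646, 0.91775, -0.011543))
_AMNIOTIC_VOL = make_spec("logistic", (822.34, 0.26988, 20.150))
_CARDIAC_OUTPUT = make_spec("cubic", (301.78, 3.2512, 0.15947, -0.0047059))
_KIDNEY_FLOW = make_spec("cubic", (53.248, 3.6447, -0.15357, 0.0016968))
_HEMATOCRIT = make_spec("quadratic", (39.192, -0.10562, -7.1045e-4))
_GFR = make_spec("quadratic", (113.73, 3.5784, -0.067272))

PLACENTA_FLOW_PER_ML = 0.059176  # L/h per mL of placenta, anchored to 39 L/h at term
PLACENTA_FLOW_ONSET_WEEKS = 3.6  # uteroplacental circulation established


def maternal_mass(t):
    """Total body mass (kg) of an average pregnant woman, conceptus included."""
    return _MASS(t)


def maternal_adipose(t):
    """Adipose tissue mass (kg) and volume (L); density 0.950 kg/L."""
    mass = _ADIPOSE_MASS(t)
    return {"mass": mass, "volume": mass / DENSITY_KG_PER_L["adip"]}


def maternal_hematocrit(t, method: str = "quadratic"):
    """Maternal hematocrit in percent.

    ``quadratic`` is the preferred fit to the curated hematocrit data;
    ``ratio`` derives hematocrit from the plasma and RBC volume models
    (100·V_rbc/(V_plas+V_rbc)), which runs consistently lower because the
    two volume models were calibrated independently.
    """
    if method == "quadratic":
        return _HEMATOCRIT(t)
    if method == "ratio":
        plas = _PLASMA(t)
        rbc = _RBC_LOGISTIC(t)
        return 100.0 * rbc / (plas + rbc)
    raise ValueError(f"unknown hematocrit method {method!r}")


def maternal_blood_volumes(t, rbc_method: str = "hematocrit_based"):
    """Plasma and red-blood-cell volumes (L).

    The preferred RBC model (``hematocrit_based``) is V_rbc = H/(1−H)·V_plas
    with the quadratic hematocrit as a fraction, which keeps plasma volume,
    RBC volume and hematocrit mutually consistent.  ``modified_logistic``
    gives the independently calibrated RBC fit instead.
    """
    plasma = _PLASMA(t)
    if rbc_method == "hematocrit_based":
        h = maternal_hematocrit(t) / 100.0
        rbc = h / (1.0 - h) * plasma
    elif rbc_method == "modified_logistic":
        rbc = _RBC_LOGISTIC(t)
    else:
        raise ValueError(f"unknown rbc_method {rbc_method!r}")
    return {"plasma": plasma, "rbc": rbc}


def conceptus_volumes(t, gated: bool = False):
    """Placenta and amniotic-fluid volumes (mL).

    The raw fitted curves are defined for all t, but the products of
    conception do not exist before a gestational age of 2 weeks; with
    ``gated=True`` both volumes are clamped to 0 there.  The placenta cubic
    is negative below about 1.97 weeks regardless.
    """
    plac = _PLACENTA_VOL(t)
    amnf = _AMNIOTIC_VOL(t)
    if gated:
        pre = np.asarray(t, dtype=float) < 2.0
        plac = np.where(pre, 0.0, plac)
        amnf = np.where(pre, 0.0, amnf)
        if np.ndim(t) == 0:
            plac, amnf = float(plac), float(amnf)
    return {"placenta": plac, "amniotic_fluid": amnf}


def static_maternal_volumes() -> dict[str, float]:
    """Volumes (L) of maternal compartments treated as constant.

    Non-pregnant body mass × reference female percent-of-body-mass ÷ tissue
    density, for brain, thyroid, kidneys, gut, liver and lungs.
    """
    w0 = maternal_mass(0.0)
    return {
        code: w0 * FEMALE_PERCENT_OF_BODY_MASS[code] / 100.0 / DENSITY_KG_PER_L[code]
        for code in ("bran", "thyr", "kidn", "gutx", "livr", "lung")
    }


def maternal_fat_free_volume(t):
    """Fat-free maternal volume (L) by mass balance, piecewise at 2 weeks.

    Before conception the fat-free mass is total mass minus adipose; from 2
    weeks the conceptus mass (fetal g, plus placenta and amniotic volumes
    scaled by their densities, all converted g → kg) is subtracted as well.
    The whole balance is divided by the 1.1 kg/L fat-free density.
    """
    t_arr = np.asarray(t, dtype=float)
    lean = maternal_mass(t_arr) - maternal_adipose(t_arr)["mass"]
    cv = conceptus_volumes(t_arr)
    conceptus_kg = (
        fetal.fetal_mass(t_arr)
        + DENSITY_KG_PER_L["plac"] * cv["placenta"]
        + DENSITY_KG_PER_L["amnf"] * cv["amniotic_fluid"]
    ) / 1000.0
    out = np.where(t_arr < 2.0, lean, lean - conceptus_kg) / DENSITY_KG_PER_L["ffmx"]
    return float(out) if np.ndim(t) == 0 else out


def maternal_rest_of_body_volume(t, rbc_method: str = "modified_logistic"):
    """Rest-of-body volume (L): fat-free volume minus plasma, RBC and the six
    static compartment volumes.

    The RBC term defaults to the independently calibrated modified logistic,
    as in the original mass balance; switching to ``hematocrit_based`` moves
    the result by less than 0.1 L.
    """
    blood = maternal_blood_volumes(t, rbc_method=rbc_method)
    statics = sum(static_maternal_volumes().values())
    return maternal_fat_free_volume(t) - (blood["plasma"] + blood["rbc"] + statics)


def maternal_cardiac_output(t):
    """Cardiac output (L/h); also the total arterial and venous flow."""
    return _CARDIAC_OUTPUT(t)


def maternal_transition_flow(compartment: str, t):
    """Linear-transition flow (L/h): a percent of cardiac output interpolated
    linearly between the non-pregnant and 40-week values."""
    try:
        p0, p40 = TRANSITION_PERCENTS[compartment]
    except KeyError:
        raise KeyError(
            f"no transition percentages for compartment {compartment!r}"
        ) from None
    t_arr = np.asarray(t, dtype=float)
    frac = (p0 + (p40 - p0) / NEAR_TERM_WEEKS * t_arr) / 100.0
    out = frac * maternal_cardiac_output(t_arr)
    return float(out) if np.ndim(t) == 0 else out


def maternal_kidney_flow(t, method: str = "cubic"):
    """Blood flow to the kidneys (L/h); the cubic fit to curated data is
    preferred over the generic linear-transition form."""
    if method == "cubic":
        return _KIDNEY_FLOW(t)
    if method == "transition":
        return maternal_transition_flow("kidn", t)
    raise ValueError(f"unknown kidney-flow method {method!r}")


def maternal_placenta_flow(t, method: str = "proportional_to_volume"):
    """Blood flow to the placenta (L/h); zero before 3.6 weeks.

    The preferred model is proportional to placenta volume with the constant
    chosen so the flow is 39 L/h at 40 weeks.  The ``linear_transition``
    variant ramps a uteroplacental percent of cardiac output and an 80%
    placental share; it underpredicts near term and is kept for comparison
    only.
    """
    t_arr = np.asarray(t, dtype=float)
    if method == "proportional_to_volume":
        flow = PLACENTA_FLOW_PER_ML * _PLACENTA_VOL(t_arr)
    elif method == "linear_transition":
        p0, p40 = TRANSITION_PERCENTS["utpl"]
        utpl = (p0 + (p40 - p0) / NEAR_TERM_WEEKS * t_arr) / 100.0
        ramp = (0.8 / (NEAR_TERM_WEEKS - PLACENTA_FLOW_ONSET_WEEKS)) * (
            t_arr - PLACENTA_FLOW_ONSET_WEEKS
        )
        flow = ramp * utpl * maternal_cardiac_output(t_arr)
    else:
        raise ValueError(f"unknown placenta-flow method {method!r}")
    out = np.where(t_arr < PLACENTA_FLOW_ONSET_WEEKS, 0.0, flow)
    return float(out) if np.ndim(t) == 0 else out


def maternal_rest_of_body_flow(t):
    """Rest-of-body flow (L/h) by conservation: cardiac output minus the five
    linear-transition flows, the kidney cubic and the placenta flow."""
    named = (
        maternal_transition_flow("adip", t)
        + maternal_transition_flow("bran", t)
        + maternal_kidney_flow(t)
        + maternal_transition_flow("gutx", t)
        + maternal_transition_flow("livr", t)
        + maternal_transition_flow("thyr", t)
        + maternal_placenta_flow(t)
    )
    return maternal_cardiac_output(t) - named


def maternal_gfr(t, method: str = "quadratic"):
    """Glomerular filtration rate (mL/min).

    ``quadratic`` is the preferred fit; ``allometric`` scales the 125 mL/min
    value for a 70 kg human by (W^m/70)^0.75.
    """
    if method == "quadratic":
        return _GFR(t)
    if method == "allometric":
        return 125.0 * (maternal_mass(t) / 70.0) ** 0.75
    raise ValueError(f"unknown GFR method {method!r}")
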