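"""Registry binding quantity symbols to preferred models, units and validity.

Each entry pairs a symbol (e.g. ``Q_plac^m`` for maternal blood flow to the
placenta, ``Q_DA^f`` for fetal ductus arteriosus flow) with the callable
evaluating its preferred model, its native units, the four-letter compartment
code, and the validity window used to flag evaluations:

* ``pre_conception`` — before 2 weeks gestational age (3.6 weeks for maternal
  placental flow) the products of conception do not exist;
* ``extrapolated`` — inside the existence window but before the first
  calibration observation (9 weeks for the conceptus volume curves);
* ``pre_recommended`` — fetal flow and rest-of-body models are recommended
  only from 13 weeks because first-trimester data are sparse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import fetal, maternal

__all__ = ["QuantityDescriptor", "REGISTRY", "maternal_symbols", "fetal_symbols"]

VALID = "valid"
EXTRAPOLATED = "extrapolated"
PRE_CONCEPTION = "pre_conception"
PRE_RECOMMENDED = "pre_recommended"


@dataclass(frozen=True)
class QuantityDescriptor:
    symbol: str
    units: str
    compartment: str | None
    subject: str  # "maternal" | "fetal"
    preferred_equation: int
    fn: Callable
    pre_conception_before: float | None = None
    extrapolated_before: float | None = None
    recommended_from: float | None = None

    def __call__(self, t, **options):
        return self.fn(np.asarray(t, dtype=float), **options)

    def flags(self, t) -> np.ndarray:
        """Per-point validity flag for a scalar or array of ages."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, VALID, dtype=object)
        if self.extrapolated_before is not None:
            out[t < self.extrapolated_before] = EXTRAPOLATED
        if self.recommended_from is not None:
            out[t < self.recommended_from] = PRE_RECOMMENDED
        if self.pre_conception_before is not None:
            out[t < self.pre_conception_before] = PRE_CONCEPTION
        return out


def _d(symbol, units, compartment, subject, eq, fn, **kw):
    return QuantityDescriptor(symbol, units, compartment, subject, eq, fn, **kw)


def _organ_mass(code):
    return lambda t, **opt: fetal.fetal_organ_mass(code, t, **opt)


def _organ_volume(code):
    return lambda t, **opt: fetal.fetal_organ_volume(code, t, **opt)


_ENTRIES = [
    # maternal --------------------------------------------------------------
    _d("W^m", "kg", None, "maternal", 1, lambda t, **o: maternal.maternal_mass(t)),
    _d("W_adip^m", "kg", "adip", "maternal", 3,
       lambda t, **o: maternal.maternal_adipose(t)["mass"]),
    _d("V_adip^m", "L", "adip", "maternal", 4,
       lambda t, **o: maternal.maternal_adipose(t)["volume"]),
    _d("V_plas^m", "L", "plas", "maternal", 5,
       lambda t, **o: maternal.maternal_blood_volumes(t, **o)["plasma"]),
    _d("V_rbcs^m", "L", "rbcs", "maternal", 7,
       lambda t, **o: maternal.maternal_blood_volumes(t, **o)["rbc"]),
    _d("V_plac^m", "mL", "plac", "maternal", 8,
       lambda t, **o: maternal.conceptus_volumes(t, **o)["placenta"],
       pre_conception_before=2.0, extrapolated_before=9.0),
    _d("V_amnf^m", "mL", "amnf", "maternal", 9,
       lambda t, **o: maternal.conceptus_volumes(t, **o)["amniotic_fluid"],
       pre_conception_before=2.0, extrapolated_before=9.0),
    _d("V_rest^m", "L", "rest", "maternal", 12,
       lambda t, **o: maternal.maternal_rest_of_body_volume(t, **o)),
    _d("Q_artb^m", "L/h", "artb", "maternal", 13,
       lambda t, **o: maternal.maternal_cardiac_output(t)),
    _d("Q_adip^m", "L/h", "adip", "maternal", 14,
       lambda t, **o: maternal.maternal_transition_flow("adip", t)),
    _d("Q_bran^m", "L/h", "bran", "maternal", 15,
       lambda t, **o: maternal.maternal_transition_flow("bran", t)),
    _d("Q_kidn^m", "L/h", "kidn", "maternal", 17,
       lambda t, **o: maternal.maternal_kidney_flow(t, **o)),
    _d("Q_gutx^m", "L/h", "gutx", "maternal", 18,
       lambda t, **o: maternal.maternal_transition_flow("gutx", t)),
    _d("Q_livr^m", "L/h", "livr", "maternal", 19,
       lambda t, **o: maternal.maternal_transition_flow("livr", t)),
    _d("Q_thyr^m", "L/h", "thyr", "maternal", 20,
       lambda t, **o: maternal.maternal_transition_flow("thyr", t)),
    _d("Q_plac^m", "L/h", "plac", "maternal", 22,
       lambda t, **o: maternal.maternal_placenta_flow(t, **o),
       pre_conception_before=3.6),
    _d("Q_rest^m", "L/h", "rest", "maternal", 23,
       lambda t, **o: maternal.maternal_rest_of_body_flow(t)),
    _d("H^m", "percent", None, "maternal", 24,
       lambda t, **o: maternal.maternal_hematocrit(t, **o)),
    _d("k_kidn^m", "mL/min", "kidn", "maternal", 26,
       lambda t, **o: maternal.maternal_gfr(t, **o)),
    # fetal -----------------------------------------------------------------
    _d("W^f", "g", None, "fetal", 2, lambda t, **o: fetal.fetal_mass(t),
       pre_conception_before=2.0),
    *[
        entry
        for code, w_eq, v_eq in (
            ("bran", 29, 30), ("livr", 32, 33), ("kidn", 35, 36),
            ("lung", 37, 38), ("thyr", 39, 40), ("gutx", 41, 42),
        )
        for entry in (
            _d(f"W_{code}^f", "g", code, "fetal", w_eq, _organ_mass(code),
               pre_conception_before=2.0),
            _d(f"V_{code}^f", "mL", code, "fetal", v_eq, _organ_volume(code),
               pre_conception_before=2.0),
        )
    ],
    _d("V_rest^f", "mL", "rest", "fetal", 43,
       lambda t, **o: fetal.fetal_rest_of_body_volume(t),
       pre_conception_before=2.0, recommended_from=13.0),
    _d("Q_rvtl^f", "mL/min", "rvtl", "fetal", 44,
       lambda t, **o: fetal.fetal_heart_flows(t)["rvtl"],
       pre_conception_before=2.0, recommended_from=13.0),
    _d("Q_lvtl^f", "mL/min", "lvtl", "fetal", 45,
       lambda t, **o: fetal.fetal_heart_flows(t)["lvtl"],
       pre_conception_before=2.0, recommended_from=13.0),
    _d("Q_DA^f", "mL/min", None, "fetal", 46,
       lambda t, **o: fetal.fetal_heart_flows(t)["DA"],
       pre_conception_before=2.0, recommended_from=13.0),
    _d("Q_artb^f", "mL/min", "artb", "fetal", 47,
       lambda t, **o: fetal.fetal_heart_flows(t)["artb"],
       pre_conception_before=2.0, recommended_from=13.0),
    _d("Q_lung^f", "mL/min", "lung", "fetal", 48,
       lambda t, **o: fetal.fetal_heart_flows(t)["lung"],
       pre_conception_before=2.0, recommended_from=13.0),
    _d("Q_FO^f", "mL/min", None, "fetal", 49,
       lambda t, **o: fetal.fetal_heart_flows(t)["FO"],
       pre_conception_before=2.0, recommended_from=13.0),
    _d("Q_plac^f", "mL/min", "plac", "fetal", 50,
       lambda t, **o: fetal.fetal_placental_flows(t)["plac"],
       pre_conception_before=2.0, recommended_from=13.0),
    _d("Q_DV^f", "mL/min", None, "fetal", 51,
       lambda t, **o: fetal.fetal_placental_flows(t)["DV"],
       pre_conception_before=2.0, recommended_from=13.0),
    *[
        _d(f"Q_{code}^f", "mL/min", code, "fetal", eq,
           (lambda c: lambda t, **o: fetal.fetal_organ_flows(t)[c])(code),
           pre_conception_before=2.0, recommended_from=13.0)
        for code, eq in (
            ("gutx", 52), ("kidn", 53), ("bran", 54), ("livr", 55), ("thyr", 56),
        )
    ],
    _d("Q_rest^f", "mL/min", "rest", "fetal", 57,
       lambda t, **o: fetal.fetal_rest_of_body_flow(t),
       pre_conception_before=2.0, recommended_from=13.0),
    _d("H^f", "percent", None, "fetal", 59,
       lambda t, **o: fetal.fetal_hematocrit(t, **o),
       pre_conception_before=2.0),
]

REGISTRY: dict[str, QuantityDescriptor] = {e.symbol: e for e in _ENTRIES}
assert len(REGISTRY) == len(_ENTRIES), "duplicate registry symbol"


def maternal_symbols() -> list[str]:
    return [s for s, d in REGISTRY.items() if d.subject == "maternal"]


def fetal_symbols() -> list[str]:
    return [s for s, d in REGISTRY.items() if d.subject == "fetal"]
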