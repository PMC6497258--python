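"""Machine-checkable consistency suite for the model repository.

These are the structural identities and windows the composite models are
supposed to satisfy: flow conservation in both circulations, the fetal shunt
algebra, ordering of placental vs ductus venosus flow after 12 weeks,
positivity of the derived flows and volumes, and mutual consistency of the
maternal plasma/RBC/hematocrit models.
"""

from __future__ import annotations

import numpy as np

from . import fetal, maternal

__all__ = ["run_checks"]

REL_TOL = 1e-12


def _rel_err(a, b):
    scale = np.maximum(np.abs(a), np.abs(b))
    return np.max(np.abs(a - b) / np.where(scale > 0, scale, 1.0))


def run_checks() -> dict[str, dict]:
    """Run every invariant; return {name: {"passed": bool, "detail": str}}."""
    grid = np.round(np.arange(0.0, 42.0 + 1e-9, 0.1), 10)
    grid_13 = grid[grid >= 13.0]
    grid_12x = grid[grid > 12.0]
    results = {}

    def record(name, passed, detail):
        results[name] = {"passed": bool(passed), "detail": detail}

    # maternal flow conservation
    total = maternal.maternal_cardiac_output(grid)
    parts = (
        maternal.maternal_transition_flow("adip", grid)
        + maternal.maternal_transition_flow("bran", grid)
        + maternal.maternal_kidney_flow(grid)
        + maternal.maternal_transition_flow("gutx", grid)
        + maternal.maternal_transition_flow("livr", grid)
        + maternal.maternal_transition_flow("thyr", grid)
        + maternal.maternal_placenta_flow(grid)
        + maternal.maternal_rest_of_body_flow(grid)
    )
    err = _rel_err(total, parts)
    record("maternal_flow_conservation", err < REL_TOL, f"max rel err {err:.2e}")

    # plasma / RBC / hematocrit consistency
    blood = maternal.maternal_blood_volumes(grid)
    h_back = 100.0 * blood["rbc"] / (blood["plasma"] + blood["rbc"])
    err = _rel_err(h_back, maternal.maternal_hematocrit(grid))
    record("maternal_hematocrit_consistency", err < REL_TOL, f"max rel err {err:.2e}")

    # rest-of-body volume window
    v_rest = maternal.maternal_rest_of_body_volume(grid)
    v_rest_40 = v_rest[grid <= 40.0]
    record(
        "maternal_rest_volume_window",
        np.all(v_rest > 0) and v_rest_40.min() > 30.0 and v_rest_40.max() < 35.0,
        f"range on [0,40]: {v_rest_40.min():.2f}..{v_rest_40.max():.2f} L",
    )

    # fetal shunt algebra and flow conservation
    hf = fetal.fetal_heart_flows(grid)
    err = max(
        _rel_err(hf["FO"] + hf["rvtl"], hf["artb"]),
        _rel_err(hf["lung"] + hf["DA"], hf["rvtl"]),
    )
    record("fetal_shunt_algebra", err < REL_TOL, f"max rel err {err:.2e}")

    named = fetal.fetal_placental_flows(grid)["plac"] + sum(
        fetal.fetal_organ_flows(grid).values()
    ) + fetal.fetal_rest_of_body_flow(grid)
    err = _rel_err(hf["artb"], named)
    record("fetal_flow_conservation", err < REL_TOL, f"max rel err {err:.2e}")

    # placental vs ductus venosus ordering after 12 weeks
    pf = fetal.fetal_placental_flows(grid_12x)
    record(
        "fetal_dv_below_placenta_after_12wk",
        np.all(pf["DV"] < pf["plac"]),
        f"min margin {np.min(pf['plac'] - pf['DV']):.3f} mL/min",
    )

    # derived flow positivity on the recommended window
    hf13 = fetal.fetal_heart_flows(grid_13)
    rest13 = fetal.fetal_rest_of_body_flow(grid_13)
    record(
        "fetal_derived_flow_positivity",
        np.all(hf13["lung"] > 0) and np.all(hf13["FO"] > 0) and np.all(rest13 > 0),
        "lung, foramen ovale and rest-of-body flows on [13, 42]",
    )

    # fetal rest-of-body volume positive and increasing from 13 weeks
    v = fetal.fetal_rest_of_body_volume(grid_13)
    record(
        "fetal_rest_volume_monotone",
        np.all(v > 0) and np.all(np.diff(v) > 0),
        f"range {v.min():.1f}..{v.max():.1f} mL",
    )

    return results
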