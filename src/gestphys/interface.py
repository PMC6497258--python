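"""Registry-driven evaluation tables, age conventions, and file I/O.

A :class:`PhysiologyTable` holds an inclusive gestational-age grid with one
column per registry symbol, parallel per-cell validity flags, and the native
units of each column.  CSV export writes a ``# units: ...`` comment line above
the header; JSON export keeps values and flags side by side.  Round trips are
lossless to 15 significant digits, and a unit mismatch on read is an error,
never a silent rescale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import FitResult, SummaryDataset, SummaryPoint
from .families import AGE_WEEKS, ModelSpec, get_family
from .registry import PRE_CONCEPTION, PRE_RECOMMENDED, VALID, REGISTRY

__all__ = [
    "PhysiologyTable",
    "evaluate_table",
    "convert_age",
    "read_table_csv",
    "read_table_json",
    "read_summary_csv",
    "write_summary_csv",
    "write_fit_json",
    "read_fit_json",
]

logger = logging.getLogger("gestphys")

GESTATIONAL = "gestational"
FETAL = "fetal"
FETAL_AGE_OFFSET_WEEKS = 2.0  # gestational age = fetal age + 2 weeks

_FLOAT_FMT = "%.15g"


def convert_age(value, from_: str = GESTATIONAL, to: str = GESTATIONAL):
    """Convert between gestational age (since last menstrual period) and
    fetal age (since fertilisation); the two differ by exactly 2 weeks."""
    for kind in (from_, to):
        if kind not in (GESTATIONAL, FETAL):
            raise ValueError(f"unknown age convention {kind!r}")
    shift = {
        (GESTATIONAL, GESTATIONAL): 0.0,
        (FETAL, FETAL): 0.0,
        (FETAL, GESTATIONAL): FETAL_AGE_OFFSET_WEEKS,
        (GESTATIONAL, FETAL): -FETAL_AGE_OFFSET_WEEKS,
    }[(from_, to)]
    out = np.asarray(value, dtype=float) + shift
    if np.any(out < 0):
        raise ValueError("age conversion yields a negative age")
    return float(out) if np.ndim(value) == 0 else out


@dataclass
class PhysiologyTable:
    """Evaluated quantities over a gestational-age grid with validity flags."""

    values: pd.DataFrame  # index: age (weeks); columns: registry symbols
    flags: pd.DataFrame  # same shape, flag strings
    units: dict[str, str]

    def __post_init__(self):
        ages = self.values.index.to_numpy(dtype=float)
        if len(ages) > 1 and not np.all(np.diff(ages) > 0):
            raise ValueError("age grid must be strictly increasing")
        for col in self.values.columns:
            if col not in self.units:
                raise ValueError(f"missing units for column {col!r}")

    @property
    def ages(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# units: "
                + ", ".join(f"{c}={self.units[c]}" for c in self.values.columns)
                + "\n"
            )
            self.values.rename_axis("age_weeks").to_csv(fh, float_format=_FLOAT_FMT)

    def to_json(self, path) -> None:
        payload = {
            "age_weeks": [float(a) for a in self.ages],
            "columns": {
                str(c): {
                    "units": self.units[c],
                    "values": [
                        None if not np.isfinite(v) else float(v)
                        for v in self.values[c].to_numpy()
                    ],
                    "flags": [str(f) for f in self.flags[c].to_numpy()],
                }
                for c in self.values.columns
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def evaluate_table(
    symbols="all",
    start: float = 0.0,
    stop: float = 42.0,
    step: float = 0.1,
    strict: bool = False,
    overrides: dict | None = None,
) -> PhysiologyTable:
    """Evaluate registry quantities on the inclusive grid start..stop.

    In strict mode, cells flagged ``pre_conception`` or ``pre_recommended``
    are blanked (NaN) instead of carrying an extrapolated model value.
    ``overrides`` maps symbols to keyword options of the underlying operation
    (e.g. ``{"H^m": {"method": "ratio"}}``).
    """
    if not (0.0 <= start < stop <= 42.0):
        raise ValueError("need 0 <= start < stop <= 42")
    if step <= 0:
        raise ValueError("step must be positive")
    if symbols == "all":
        symbols = list(REGISTRY)
    unknown = [s for s in symbols if s not in REGISTRY]
    if unknown:
        raise KeyError(f"unknown registry symbols: {unknown}")
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    grid[-1] = stop

    values, flags, units = {}, {}, {}
    for sym in symbols:
        desc = REGISTRY[sym]
        opts = (overrides or {}).get(sym, {})
        col = np.asarray(desc(grid, **opts), dtype=float)
        fl = desc.flags(grid)
        gated = [f for f in np.unique(fl) if f != VALID]
        if gated:
            logger.info("%s: grid includes %s ages", sym, "/".join(map(str, gated)))
        if strict:
            col = np.where(np.isin(fl, (PRE_CONCEPTION, PRE_RECOMMENDED)), np.nan, col)
        values[sym] = col
        flags[sym] = fl
        units[sym] = desc.units
    index = pd.Index(grid, name="age_weeks")
    return PhysiologyTable(
        values=pd.DataFrame(values, index=index),
        flags=pd.DataFrame(flags, index=index),
        units=units,
    )


def read_table_csv(path) -> PhysiologyTable:
    """Read a table written by :meth:`PhysiologyTable.to_csv`.

    Flags are reconstructed from the registry validity windows; a column with
    units different from the registry's is rejected.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# units:"):
            raise ValueError("missing '# units:' comment line")
        units = dict(
            item.strip().split("=", 1) for item in header[len("# units:"):].split(", ")
        )
        df = pd.read_csv(fh, index_col="age_weeks")
    for col in df.columns:
        if col in REGISTRY and REGISTRY[col].units != units.get(col):
            raise ValueError(
                f"unit mismatch for {col}: file says {units.get(col)!r}, "
                f"registry says {REGISTRY[col].units!r}"
            )
    grid = df.index.to_numpy(dtype=float)
    flags = pd.DataFrame(
        {
            c: REGISTRY[c].flags(grid) if c in REGISTRY else np.full(len(grid), VALID, object)
            for c in df.columns
        },
        index=df.index,
    )
    return PhysiologyTable(values=df, flags=flags, units=units)


def read_table_json(path) -> PhysiologyTable:
    with open(path) as fh:
        payload = json.load(fh)
    index = pd.Index(np.asarray(payload["age_weeks"], dtype=float), name="age_weeks")
    values, flags, units = {}, {}, {}
    for col, entry in payload["columns"].items():
        units[col] = entry["units"]
        values[col] = [np.nan if v is None else v for v in entry["values"]]
        flags[col] = entry["flags"]
    return PhysiologyTable(
        values=pd.DataFrame(values, index=index),
        flags=pd.DataFrame(flags, index=index),
        units=units,
    )


# ---------------------------------------------------------------------------
# summary-dataset CSV dialect: covariate,mean,sd,n with empty cells = missing

def read_summary_csv(path, covariate_kind: str = AGE_WEEKS) -> SummaryDataset:
    df = pd.read_csv(path, comment="#")
    required = ["covariate", "mean", "sd", "n"]
    if list(df.columns) != required:
        raise ValueError(f"summary CSV must have columns {required}, got {list(df.columns)}")
    points = []
    for row in df.itertuples(index=False):
        sd = None if pd.isna(row.sd) else float(row.sd)
        n = None if pd.isna(row.n) else int(row.n)
        points.append(SummaryPoint(float(row.covariate), float(row.mean), sd=sd, n=n))
    return SummaryDataset(tuple(points), covariate_kind=covariate_kind)


def write_summary_csv(dataset: SummaryDataset, path) -> None:
    df = pd.DataFrame(
        {
            "covariate": dataset.covariate,
            "mean": dataset.mean,
            "sd": [p.sd for p in dataset.points],
            "n": [p.n for p in dataset.points],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_fit_json(fit: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=1)


def read_fit_json(path) -> FitResult:
    with open(path) as fh:
        d = json.load(fh)
    spec = ModelSpec(get_family(d["family"]), tuple(d["theta"]), d["covariate_kind"])
    return FitResult(
        spec=spec,
        loglik=d["loglik"],
        k=d["k"],
        aic=d["aic"],
        converged=d["converged"],
        n_starts=d["n_starts"],
        seed=d["seed"],
    )
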