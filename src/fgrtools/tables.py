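"""Delimited-table interchange: schemas, validation, readers and writers.

All stage inputs/outputs are UTF-8 comma-separated tables with a header
row.  Each schema lists required columns with a type and an optional
row-level constraint; validation reports violations with their file line
number (header = line 1) and loads the remaining rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .synthetic import (
    FetusRecord,
    LitterRecord,
    PlasmaSample,
    VelocityTrace,
)

logger = logging.getLogger("fgrtools")


class SchemaError(ValueError):
    """Raised when a table is structurally invalid (e.g. missing column)."""


@dataclass
class Column:
    name: str
    dtype: str  # "str" | "float" | "int"
    required: bool = True
    check: Callable[[float], bool] | None = None
    check_desc: str = ""


@dataclass
class RowError:
    line: int  # 1-based file line (header is line 1)
    column: str
    message: str


SCHEMAS: dict[str, list[Column]] = {
    "litters": [
        Column("litter_id", "str"),
        Column("treatment", "str"),
        Column("litter_size", "int", check=lambda v: v >= 1,
               check_desc="litter_size >= 1"),
        Column("gestational_day", "float", required=False),
    ],
    "fetuses": [
        Column("fetus_id", "str"),
        Column("litter_id", "str"),
        Column("genotype", "str"),
        Column("treatment", "str"),
        Column("fetal_weight", "float", check=lambda v: v > 0,
               check_desc="fetal_weight > 0"),
        Column("placental_weight", "float", check=lambda v: v > 0,
               check_desc="placental_weight > 0"),
        Column("crown_rump", "float", required=False,
               check=lambda v: v > 0, check_desc="crown_rump > 0"),
        Column("abdominal_circ", "float", required=False,
               check=lambda v: v > 0, check_desc="abdominal_circ > 0"),
        Column("head_circ", "float", required=False,
               check=lambda v: v > 0, check_desc="head_circ > 0"),
        Column("tail_tip_fraction", "float", required=False,
               check=lambda v: 0 <= v < 0.2,
               check_desc="tail_tip_fraction in [0, 0.2)"),
        Column("dpm_accumulated", "float", required=False,
               check=lambda v: v >= 0, check_desc="dpm_accumulated >= 0"),
        Column("sample_time_x", "float", required=False,
               check=lambda v: v > 0, check_desc="sample_time_x > 0"),
    ],
    "plasma": [
        Column("dam_id", "str"),
        Column("time_min", "float", check=lambda v: v >= 0,
               check_desc="time_min >= 0"),
        Column("dpm_per_ul", "float", check=lambda v: v >= 0,
               check_desc="dpm_per_ul >= 0"),
    ],
    "traces": [
        Column("trace_id", "str"),
        Column("time_s", "float", check=lambda v: v >= 0,
               check_desc="time_s >= 0"),
        Column("velocity_mm_s", "float"),
    ],
}


@dataclass
class ValidatedTable:
    frame: pd.DataFrame
    n_rows: int
    errors: list[RowError] = field(default_factory=list)


def validate_table(path: str, schema_name: str) -> ValidatedTable:
    """Read and validate a delimited table against a named schema.

    Missing required columns raise :class:`SchemaError`; row-level
    violations (unparseable cells, constraint failures) are reported with
    their line number and the offending rows dropped.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c.name for c in schema if c.required and c.name not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    errors: list[RowError] = []
    bad = np.zeros(len(df), dtype=bool)
    out = pd.DataFrame(index=df.index)
    for col in schema:
        if col.name not in df.columns:
            continue
        raw = df[col.name]
        if col.dtype == "str":
            out[col.name] = raw
            continue
        vals = pd.to_numeric(raw.mask(raw == "", np.nan), errors="coerce")
        optional_blank = (raw == "") & (not col.required)
        unparseable = vals.isna() & (raw != "")
        for idx in df.index[unparseable]:
            errors.append(RowError(idx + 2, col.name,
                                   f"unparseable value {raw[idx]!r}"))
        bad |= unparseable.to_numpy()
        if col.required:
            blank = raw == ""
            for idx in df.index[blank]:
                errors.append(RowError(idx + 2, col.name, "missing value"))
            bad |= blank.to_numpy()
        if col.check is not None:
            ok = vals.notna()
            viol = ok & ~vals.map(lambda v: bool(col.check(v)) if pd.notna(v) else True)
            for idx in df.index[viol]:
                errors.append(RowError(idx + 2, col.name,
                                       f"constraint failed: {col.check_desc}"))
            bad |= viol.to_numpy()
        if col.dtype == "int":
            out[col.name] = vals.round().astype("Int64")
        else:
            out[col.name] = vals
        out.loc[optional_blank, col.name] = np.nan
    clean = out[~bad].reset_index(drop=True)
    if errors:
        logger.warning(
            "validate_table[%s]: %d row(s) rejected of %d", schema_name,
            int(bad.sum()), len(df),
        )
    return ValidatedTable(frame=clean, n_rows=len(clean), errors=errors)


# ---------------------------------------------------------------------------
# record <-> frame conversions and writers


def litters_to_frame(litters: Iterable[LitterRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(l) for l in litters])


def fetuses_to_frame(fetuses: Iterable[FetusRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fetuses])


def plasma_to_frame(samples: Iterable[PlasmaSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"dam_id": s.dam_id, "time_min": s.time, "dpm_per_ul": s.concentration}
            for s in samples
        ]
    )


def traces_to_frame(traces: Iterable[VelocityTrace]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "trace_id": tr.trace_id,
                "time_s": tr.times,
                "velocity_mm_s": tr.velocities,
            }
        )
        for tr in traces
    ]
    return pd.concat(frames, ignore_index=True)


def frame_to_fetuses(df: pd.DataFrame) -> list[FetusRecord]:
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(
            FetusRecord(
                fetus_id=str(d["fetus_id"]),
                litter_id=str(d["litter_id"]),
                genotype=str(d["genotype"]),
                treatment=str(d["treatment"]),
                fetal_weight=float(d["fetal_weight"]),
                placental_weight=float(d["placental_weight"]),
                crown_rump=_opt(d.get("crown_rump")),
                abdominal_circ=_opt(d.get("abdominal_circ")),
                head_circ=_opt(d.get("head_circ")),
                tail_tip_fraction=_opt(d.get("tail_tip_fraction")),
                dpm_accumulated=_opt(d.get("dpm_accumulated")),
                sample_time_x=_opt(d.get("sample_time_x")),
            )
        )
    return recs


def frame_to_plasma(df: pd.DataFrame) -> list[PlasmaSample]:
    return [
        PlasmaSample(str(r.dam_id), float(r.time_min), float(r.dpm_per_ul))
        for r in df.itertuples(index=False)
    ]


def frame_to_traces(df: pd.DataFrame) -> list[VelocityTrace]:
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            VelocityTrace(
                trace_id=str(tid),
                vessel="umbilical_artery",
                times=grp["time_s"].to_numpy(dtype=float),
                velocities=grp["velocity_mm_s"].to_numpy(dtype=float),
            )
        )
    return traces


def _opt(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def write_table(df: pd.DataFrame, path: str, float_fmt: str = "%.10g") -> None:
    df.to_csv(path, index=False, float_format=float_fmt)
    logger.info("wrote %s (%d rows)", path, len(df))
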