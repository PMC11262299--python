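"""CSV schemas, readers and writers for the pipeline interchange files.

All files are UTF-8 CSV with a mandatory header row and decimal points.
Readers validate against the named schemas and raise
:class:`~thermoperf.errors.ValidationError` with row/column coordinates;
:func:`validate` returns a report instead of raising, for the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinematics import SwimTrial
from .respirometry import RMRRecord, RespTrace
from .tpc import SpeedObservation, ToleranceRecord

__all__ = [
    "SCHEMAS",
    "ValidationReport",
    "validate",
    "read_speeds",
    "read_tolerance",
    "read_trials",
    "read_rmr",
    "read_traces",
    "write_speeds",
    "write_tolerance",
    "write_trials",
    "write_rmr",
    "write_traces",
]

#: required columns per schema name
SCHEMAS: dict[str, tuple[str, ...]] = {
    "speeds": ("individual_id", "species", "sex", "body_mass_g",
               "treatment_c", "max_speed_cm_s"),
    "tolerance": ("individual_id", "species", "ct_min_c", "ct_max_c"),
    "trials": ("individual_id", "species", "treatment_c", "frame_rate",
               "segment_length_cm"),
    "rmr": ("individual_id", "species", "treatment_c", "body_mass_g",
            "vco2_ml_min"),
    "traces": ("individual_id", "species", "treatment_c", "body_mass_g",
               "time_s", "fe_co2"),
}

_NUMERIC = {
    "speeds": ("body_mass_g", "treatment_c", "max_speed_cm_s"),
    "tolerance": ("ct_min_c", "ct_max_c"),
    "trials": ("treatment_c", "frame_rate", "segment_length_cm"),
    "rmr": ("treatment_c", "body_mass_g", "vco2_ml_min"),
    "traces": ("treatment_c", "body_mass_g", "time_s", "fe_co2"),
}


@dataclass
class ValidationReport:
    path: str
    schema: str
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            raise ValidationError(
                f"{self.path} failed {self.schema} validation:\n  "
                + "\n  ".join(self.errors)
            )


def validate(path: str | Path, schema: str) -> ValidationReport:
    """Check a CSV against a named schema; returns a report, never raises."""
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    report = ValidationReport(path=str(path), schema=schema)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        report.errors.append(f"unreadable CSV: {exc}")
        return report
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        report.errors.append(f"missing column(s): {', '.join(missing)}")
        return report
    for col in _NUMERIC[schema]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:5])
            report.errors.append(f"column {col}: non-numeric values at row(s) {rows}")
    if schema == "speeds":
        df_num = pd.to_numeric(df["max_speed_cm_s"], errors="coerce")
        neg = df_num < 0
        if neg.any():
            report.errors.append(
                f"column max_speed_cm_s: negative at row(s) "
                f"{', '.join(str(i) for i in df.index[neg][:5])}"
            )
    if schema == "tolerance":
        lo = pd.to_numeric(df["ct_min_c"], errors="coerce")
        hi = pd.to_numeric(df["ct_max_c"], errors="coerce")
        bad = (lo >= hi) & lo.notna() & hi.notna()
        if bad.any():
            report.errors.append(
                f"ct_min_c >= ct_max_c at row(s) "
                f"{', '.join(str(i) for i in df.index[bad][:5])}"
            )
    if schema == "traces" and report.ok:
        for (ind, trt), grp in df.groupby(["individual_id", "treatment_c"]):
            t = pd.to_numeric(grp["time_s"], errors="coerce").to_numpy()
            dt = np.diff(t)
            if len(dt) and (dt[0] <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
                report.errors.append(
                    f"non-uniform time grid for individual {ind} at {trt} C"
                )
    return report


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _checked(path, schema) -> pd.DataFrame:
    validate(path, schema).raise_if_failed()
    return pd.read_csv(path)


def read_speeds(path: str | Path) -> list[SpeedObservation]:
    df = _checked(path, "speeds")
    return [
        SpeedObservation(
            individual_id=str(r.individual_id),
            species=str(r.species),
            sex=str(r.sex),
            body_mass=float(r.body_mass_g),
            treatment_temp=float(r.treatment_c),
            max_speed=float(r.max_speed_cm_s),
        )
        for r in df.itertuples()
    ]


def read_tolerance(path: str | Path) -> list[ToleranceRecord]:
    df = _checked(path, "tolerance")
    return [
        ToleranceRecord(
            individual_id=str(r.individual_id),
            species=str(r.species),
            ct_min=None if pd.isna(r.ct_min_c) else float(r.ct_min_c),
            ct_max=None if pd.isna(r.ct_max_c) else float(r.ct_max_c),
        )
        for r in df.itertuples()
    ]


def read_trials(path: str | Path) -> list[SwimTrial]:
    """Read swim trials in wide (``segment_1..k`` columns) or long
    (``segment_index``/``frames``) dialect."""
    df = _checked(path, "trials")
    trials: list[SwimTrial] = []
    if "segment_index" in df.columns and "frames" in df.columns:
        keys = ["individual_id", "species", "treatment_c", "frame_rate",
                "segment_length_cm"]
        for vals, grp in df.groupby(keys, sort=False):
            grp = grp.sort_values("segment_index")
            meta = dict(zip(keys, vals))
            trials.append(_make_trial(meta, grp["frames"].tolist(), grp))
    else:
        seg_cols = [
            c for c in df.columns
            if c.startswith("segment_") and c.split("_", 1)[1].isdigit()
        ]
        if not seg_cols:
            raise ValidationError(
                f"{path}: need segment_<i> columns (wide) or "
                "segment_index/frames columns (long)"
            )
        seg_cols.sort(key=lambda c: int(c.split("_")[1]))
        for _, row in df.iterrows():
            frames = [row[c] for c in seg_cols if pd.notna(row[c])]
            trials.append(_make_trial(row, frames, row))
    return trials


def _make_trial(meta, frames, extra) -> SwimTrial:
    get = meta.get if hasattr(meta, "get") else meta.__getitem__
    def opt(name, default=None):
        try:
            v = get(name)
        except (KeyError, AttributeError):
            return default
        if isinstance(extra, pd.DataFrame):
            pass
        return default if (v is None or (np.isscalar(v) and pd.isna(v))) else v
    sex = opt("sex", "unknown")
    mass = opt("body_mass_g")
    return SwimTrial(
        individual_id=str(get("individual_id")),
        species=str(get("species")),
        treatment_temp=float(get("treatment_c")),
        frame_rate=float(get("frame_rate")),
        segment_length=float(get("segment_length_cm")),
        segment_frames=tuple(int(f) for f in frames),
        sex=str(sex),
        body_mass=None if mass is None else float(mass),
    )


def read_rmr(path: str | Path) -> list[RMRRecord]:
    df = _checked(path, "rmr")
    return [
        RMRRecord(
            individual_id=str(r.individual_id),
            species=str(r.species),
            treatment_temp=float(r.treatment_c),
            body_mass=float(r.body_mass_g),
            vco2=float(r.vco2_ml_min),
            sex=str(getattr(r, "sex", "unknown")),
        )
        for r in df.itertuples()
    ]


def read_traces(
    path: str | Path, flow_ml_min: float = 100.0, fi_co2: float = 0.0
) -> list[RespTrace]:
    """Read long-format traces; flow and incurrent fraction come from the
    metadata arguments (or a sidecar file parsed by the CLI)."""
    df = _checked(path, "traces")
    out = []
    for (ind, trt), grp in df.groupby(["individual_id", "treatment_c"], sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            RespTrace(
                individual_id=str(ind),
                species=str(grp["species"].iloc[0]),
                treatment_temp=float(trt),
                body_mass=float(grp["body_mass_g"].iloc[0]),
                sample_times=grp["time_s"].to_numpy(dtype=float),
                fe_co2=grp["fe_co2"].to_numpy(dtype=float),
                fi_co2=fi_co2,
                flow_rate=flow_ml_min,
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers (fixed formats so identical data gives identical bytes)
# ---------------------------------------------------------------------------


def _write(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_speeds(obs: Iterable[SpeedObservation], path: str | Path) -> None:
    _write(
        pd.DataFrame(
            [
                {
                    "individual_id": o.individual_id,
                    "species": o.species,
                    "sex": o.sex,
                    "body_mass_g": o.body_mass,
                    "treatment_c": o.treatment_temp,
                    "max_speed_cm_s": o.max_speed,
                }
                for o in obs
            ]
        ),
        path,
    )


def write_tolerance(records: Iterable[ToleranceRecord], path: str | Path) -> None:
    _write(
        pd.DataFrame(
            [
                {
                    "individual_id": r.individual_id,
                    "species": r.species,
                    "ct_min_c": r.ct_min,
                    "ct_max_c": r.ct_max,
                }
                for r in records
            ]
        ),
        path,
    )


def write_trials(trials: Iterable[SwimTrial], path: str | Path) -> None:
    rows = []
    for t in trials:
        for idx, frames in enumerate(t.segment_frames, start=1):
            rows.append(
                {
                    "individual_id": t.individual_id,
                    "species": t.species,
                    "sex": t.sex,
                    "body_mass_g": t.body_mass,
                    "treatment_c": t.treatment_temp,
                    "frame_rate": t.frame_rate,
                    "segment_length_cm": t.segment_length,
                    "segment_index": idx,
                    "frames": frames,
                }
            )
    _write(pd.DataFrame(rows), path)


def write_rmr(records: Iterable[RMRRecord], path: str | Path) -> None:
    _write(
        pd.DataFrame(
            [
                {
                    "individual_id": r.individual_id,
                    "species": r.species,
                    "sex": r.sex,
                    "treatment_c": r.treatment_temp,
                    "body_mass_g": r.body_mass,
                    "vco2_ml_min": r.vco2,
                }
                for r in records
            ]
        ),
        path,
    )


def write_traces(traces: Iterable[RespTrace], path: str | Path) -> None:
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": t.individual_id,
                    "species": t.species,
                    "treatment_c": t.treatment_temp,
                    "body_mass_g": t.body_mass,
                    "time_s": t.sample_times,
                    "fe_co2": t.fe_co2,
                }
            )
        )
    _write(pd.concat(frames, ignore_index=True), path)
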