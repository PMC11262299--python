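"""Open-flow respirometry: CO2 traces -> VCO2 -> RMR -> Q10.

A trace is the fractional CO2 concentration in the excurrent air sampled on
a uniform time grid while scrubbed (CO2-free) air is pushed through the
animal chamber at a known flow rate.  The resting rate is taken from the
*lowest* mean over any contiguous window (default 100 s), which discards
handling transients, and converted to ml CO2/min by

    VCO2 = flow_rate * (FeCO2 - FiCO2)

Thermal sensitivity between two temperatures is the Q10 coefficient

    Q10 = (RMR2 / RMR1) ** (10 / (T2 - T1)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError

__all__ = [
    "RespTrace",
    "RMRRecord",
    "Q10Result",
    "stable_mean",
    "vco2",
    "rmr_from_trace",
    "q10",
    "q10_table",
    "CONSECUTIVE_PAIRS",
]

#: treatment grid of the study design (degC); q10_table derives its column
#: labels from whatever treatments are present, so this is informational.
DEFAULT_TREATMENTS = (15.0, 25.0, 30.0, 33.0, 36.0)
CONSECUTIVE_PAIRS = ((15, 25), (25, 30), (30, 33), (33, 36))


@dataclass(frozen=True)
class RespTrace:
    """One respirometry trial: excurrent CO2 fraction on a uniform grid."""

    individual_id: str
    species: str
    treatment_temp: float
    body_mass: float
    sample_times: np.ndarray
    fe_co2: np.ndarray
    fi_co2: float = 0.0
    flow_rate: float = 100.0

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        y = np.asarray(self.fe_co2, dtype=float)
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "fe_co2", y)
        if t.shape != y.shape or t.ndim != 1 or t.size < 2:
            raise ValidationError(
                f"{self.individual_id}: trace needs matching 1-D time/CO2 arrays"
            )
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValidationError(
                f"{self.individual_id}: sample times must be a uniform "
                "increasing grid"
            )
        if np.any(y < 0) or np.any(y >= 1) or not 0 <= self.fi_co2 < 1:
            raise ValidationError(
                f"{self.individual_id}: CO2 fractions must lie in [0, 1)"
            )
        if self.flow_rate <= 0:
            raise ValidationError(f"{self.individual_id}: flow_rate must be > 0")

    @property
    def dt(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])

    @property
    def duration(self) -> float:
        return float(self.sample_times[-1] - self.sample_times[0])


@dataclass(frozen=True)
class RMRRecord:
    """Resting metabolic rate of one individual at one treatment (ml CO2/min)."""

    individual_id: str
    species: str
    treatment_temp: float
    body_mass: float
    vco2: float
    sex: str = "unknown"


@dataclass(frozen=True)
class Q10Result:
    """Thermal sensitivity between two temperatures; recomputable from fields."""

    t1: float
    t2: float
    rmr1: float
    rmr2: float
    q10: float

    def __post_init__(self):
        if not self.t2 > self.t1:
            raise ValidationError("Q10Result requires t2 > t1")
        if not self.q10 > 0:
            raise ValidationError("q10 must be > 0")


def stable_mean(trace: RespTrace, window: float = 100.0) -> float:
    """Lowest mean CO2 fraction over any contiguous window of ``window`` s.

    Windows advance by one sample.  The window length in samples is
    ``round(window / dt)`` and must fit inside the trace.
    """
    w = int(round(window / trace.dt))
    if w < 1:
        raise ValidationError(f"window {window}s shorter than one sample")
    y = trace.fe_co2
    if w > y.size:
        raise ValidationError(
            f"{trace.individual_id}: trace ({trace.duration:.0f}s) shorter "
            f"than the {window:.0f}s window"
        )
    csum = np.concatenate([[0.0], np.cumsum(y)])
    means = (csum[w:] - csum[:-w]) / w
    return float(means.min())


def vco2(flow_rate: float, fe_co2: float, fi_co2: float = 0.0) -> float:
    """CO2 production rate: flow_rate * (fe_co2 - fi_co2), ml CO2/min.

    A negative result (excurrent below incurrent, e.g. baseline drift) warns
    but is returned, so instrument problems stay diagnosable downstream.
    """
    for name, frac in (("fe_co2", fe_co2), ("fi_co2", fi_co2)):
        if not 0 <= frac < 1:
            raise ValidationError(f"{name} must be in [0, 1), got {frac}")
    rate = flow_rate * (fe_co2 - fi_co2)
    if rate < 0:
        warnings.warn(
            f"negative VCO2 ({rate:.4g} ml/min): excurrent CO2 below incurrent",
            stacklevel=2,
        )
    return rate


def rmr_from_trace(trace: RespTrace, window: float = 100.0) -> RMRRecord:
    """Reduce a trace to an RMR record via the minimal-window rule."""
    rate = vco2(trace.flow_rate, stable_mean(trace, window), trace.fi_co2)
    return RMRRecord(
        individual_id=trace.individual_id,
        species=trace.species,
        treatment_temp=trace.treatment_temp,
        body_mass=trace.body_mass,
        vco2=rate,
    )


def q10(rmr1: float, t1: float, rmr2: float, t2: float) -> Q10Result:
    """Q10 between two (temperature, rate) pairs; canonicalized so t2 > t1."""
    if rmr1 <= 0 or rmr2 <= 0:
        raise ComputationError("Q10 requires positive metabolic rates")
    if t1 == t2:
        raise ComputationError("Q10 undefined for equal temperatures")
    if t1 > t2:
        t1, t2, rmr1, rmr2 = t2, t1, rmr2, rmr1
    value = (rmr2 / rmr1) ** (10.0 / (t2 - t1))
    return Q10Result(t1=t1, t2=t2, rmr1=rmr1, rmr2=rmr2, q10=value)


def q10_table(
    records: Iterable[RMRRecord],
    pairs: Sequence[tuple[float, float]] = CONSECUTIVE_PAIRS,
) -> pd.DataFrame:
    """Per-species Q10 across treatment pairs plus the overall interval.

    Each cell applies :func:`q10` to the per-treatment arithmetic mean RMR.
    Pairs whose treatments are absent for a species produce NaN cells, not
    failures (partial designs are expected).  The overall column spans the
    species' observed minimum to maximum treatment.

    Returns a DataFrame indexed by species with columns like ``"15-25"`` and
    ``"overall"``.
    """
    df = pd.DataFrame(
        [
            (r.species, float(r.treatment_temp), r.vco2)
            for r in records
        ],
        columns=["species", "treatment", "vco2"],
    )
    if df.empty:
        raise ValidationError("no RMR records")
    means = df.groupby(["species", "treatment"])["vco2"].mean()

    rows = {}
    for species, by_t in means.groupby(level=0):
        temps = sorted(by_t.index.get_level_values(1))
        if len(temps) < 2:
            raise ComputationError(
                f"{species}: need >= 2 treatments for Q10, have {len(temps)}"
            )
        row = {}
        for t1, t2 in pairs:
            label = f"{t1:g}-{t2:g}"
            if float(t1) in temps and float(t2) in temps:
                row[label] = q10(
                    means[(species, float(t1))], t1,
                    means[(species, float(t2))], t2,
                ).q10
            else:
                row[label] = math.nan
        t_lo, t_hi = temps[0], temps[-1]
        row["overall"] = q10(
            means[(species, t_lo)], t_lo, means[(species, t_hi)], t_hi
        ).q10
        rows[species] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species"
    return out
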