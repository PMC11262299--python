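"""Thermal performance curve construction, selection and derived metrics.

The workflow mirrors standard practice in thermal ecophysiology:

1. summarize per-individual critical thermal limits (:class:`ToleranceRecord`
   -> :class:`ToleranceSummary`), giving the tolerance breadth TTB;
2. fit one or more unimodal curve families to (temperature, performance)
   points anchored at zero performance at the mean CTmin and CTmax
   (:func:`fit_family`);
3. keep fits with R^2 above a floor and pick the lowest-AICc one
   (:func:`select_tpc`);
4. extract the optimum To, maximum performance Vmax, the 80% performance
   breadth B80 and the thermal safety margin TSM (:func:`derive_metrics`).

Temperatures are degrees Celsius throughout; performance is cm/s for
swimming speed data.  No unit conversion is attempted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .errors import (
    AmbiguousCurveError,
    ComputationError,
    InvalidMetricsError,
    MissingDataError,
    SelectionError,
    UndefinedAICcError,
    ValidationError,
)
from .families import FAMILIES, CurveFamily, get_family

logger = logging.getLogger(__name__)

__all__ = [
    "ToleranceRecord",
    "ToleranceSummary",
    "SpeedObservation",
    "TPCFitResult",
    "ThermalMetrics",
    "summarize_tolerance",
    "ttb",
    "thermal_safety_margin",
    "aicc",
    "clamped_curve",
    "fit_family",
    "fit_all_families",
    "select_tpc",
    "derive_metrics",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToleranceRecord:
    """One individual's critical thermal limits.

    ``ct_min``/``ct_max`` are the body temperatures (degC) at which the
    righting response is lost during controlled cooling/heating; either may
    be absent.  Ramp rates, when recorded, must be positive.
    """

    individual_id: str
    species: str
    ct_min: float | None = None
    ct_max: float | None = None
    cooling_rate: float | None = None
    heating_rate: float | None = None

    def __post_init__(self):
        if self.ct_min is not None and self.ct_max is not None:
            if not self.ct_min < self.ct_max:
                raise ValidationError(
                    f"{self.individual_id}: ct_min ({self.ct_min}) must be "
                    f"below ct_max ({self.ct_max})"
                )
        for name in ("cooling_rate", "heating_rate"):
            rate = getattr(self, name)
            if rate is not None and not rate > 0:
                raise ValidationError(f"{self.individual_id}: {name} must be > 0")


@dataclass(frozen=True)
class ToleranceSummary:
    """Species-level tolerance means/SDs and the derived breadth TTB."""

    species: str
    ct_min_mean: float
    ct_max_mean: float
    ct_min_sd: float = 0.0
    ct_max_sd: float = 0.0
    n: int = 1

    def __post_init__(self):
        if self.ct_min_mean is None or self.ct_max_mean is None:
            raise MissingDataError(f"{self.species}: both tolerance means required")
        # equality allowed (degenerate breadth 0); fitting requires a proper
        # interval and checks separately
        if self.ct_min_mean > self.ct_max_mean:
            raise ValidationError(
                f"{self.species}: ct_min_mean must not exceed ct_max_mean"
            )
        if self.ct_min_sd < 0 or self.ct_max_sd < 0:
            raise ValidationError(f"{self.species}: SDs must be >= 0")
        if self.n < 1:
            raise ValidationError(f"{self.species}: n must be >= 1")

    @property
    def ttb(self) -> float:
        return self.ct_max_mean - self.ct_min_mean


@dataclass(frozen=True)
class SpeedObservation:
    """One individual x treatment maximum swimming speed with covariates."""

    individual_id: str
    species: str
    treatment_temp: float
    max_speed: float
    sex: str = "unknown"
    body_mass: float | None = None

    def __post_init__(self):
        if self.max_speed < 0:
            raise ValidationError(
                f"{self.individual_id}: max_speed must be >= 0, got {self.max_speed}"
            )


@dataclass(frozen=True)
class TPCFitResult:
    """One fitted curve family with its goodness-of-fit diagnostics."""

    species: str
    family: str
    params: tuple[float, ...]
    rss: float
    r2: float
    aicc: float
    n_fit_points: int
    n_reported: int
    converged: bool
    anchors: "ToleranceSummary" = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def curve(self, temps):
        """Evaluate the clamped fitted curve at ``temps``."""
        return clamped_curve(
            get_family(self.family),
            self.params,
            temps,
            self.anchors.ct_min_mean,
            self.anchors.ct_max_mean,
        )


@dataclass(frozen=True)
class ThermalMetrics:
    """Derived thermal metrics of a selected TPC.

    ``b80_low``/``b80_high`` bound the interval where performance stays at or
    above ``level`` (default 80%) of the maximum; ``tsm = ct_max - t_o`` and
    ``ttb = ct_max - ct_min`` use the tolerance-summary means.
    """

    species: str
    v_max: float
    t_o: float
    b80_low: float
    b80_high: float
    tsm: float
    ttb: float
    level: float = 0.8
    boundary_warning: bool = False

    def __post_init__(self):
        if not self.b80_low < self.t_o < self.b80_high:
            raise InvalidMetricsError(
                f"{self.species}: expected b80_low < t_o < b80_high, got "
                f"{self.b80_low}, {self.t_o}, {self.b80_high}"
            )


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------


def summarize_tolerance(records: Sequence[ToleranceRecord]) -> ToleranceSummary:
    """Aggregate per-individual tolerance records into a species summary.

    Uses sample means and SDs (ddof=1; SD is 0 for a single record).  All
    records must share one species label.
    """
    if not records:
        raise MissingDataError("no tolerance records")
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValidationError(f"records span multiple species: {sorted(species)}")
    mins = np.array([r.ct_min for r in records if r.ct_min is not None], float)
    maxs = np.array([r.ct_max for r in records if r.ct_max is not None], float)
    if mins.size == 0 or maxs.size == 0:
        raise MissingDataError("need at least one ct_min and one ct_max")
    return ToleranceSummary(
        species=species.pop(),
        ct_min_mean=float(mins.mean()),
        ct_max_mean=float(maxs.mean()),
        ct_min_sd=float(mins.std(ddof=1)) if mins.size > 1 else 0.0,
        ct_max_sd=float(maxs.std(ddof=1)) if maxs.size > 1 else 0.0,
        n=int(max(mins.size, maxs.size)),
    )


def ttb(summary: ToleranceSummary) -> float:
    """Thermal tolerance breadth: mean CTmax minus mean CTmin (degC)."""
    if summary.ct_min_mean is None or summary.ct_max_mean is None:
        raise MissingDataError("both tolerance means required for TTB")
    return summary.ct_max_mean - summary.ct_min_mean


def thermal_safety_margin(ct_max: float, t_o: float) -> float:
    """Thermal safety margin: CTmax minus the performance optimum To (degC)."""
    if t_o > ct_max:
        raise InvalidMetricsError(
            f"optimum t_o={t_o} exceeds ct_max={ct_max}: fit outside tolerance"
        )
    return ct_max - t_o


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample Akaike criterion for least-squares fits.

    ``AICc = n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1)``.  Requires ``rss > 0`` and
    ``n > k + 1`` (the correction denominator must be positive).
    """
    if n <= k + 1:
        raise UndefinedAICcError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    if not rss > 0:
        raise UndefinedAICcError(f"AICc needs rss > 0, got {rss}")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Curve evaluation and fitting
# ---------------------------------------------------------------------------


def clamped_curve(family: CurveFamily, params, temps, t_lo: float, t_hi: float):
    """Evaluate ``family`` clamped to the tolerance interval.

    Returns 0 at and beyond both anchors and clips negative raw values to 0
    inside the interval.  Scalar input yields a scalar.
    """
    temps_arr = np.asarray(temps, dtype=float)
    raw = family(temps_arr, params)
    out = np.where(
        (temps_arr > t_lo) & (temps_arr < t_hi), np.maximum(raw, 0.0), 0.0
    )
    if np.ndim(temps) == 0:
        return float(out)
    return out


def _lhs_starts(lower, upper, n_starts, seed):
    sampler = qmc.LatinHypercube(d=len(lower), seed=seed)
    unit = sampler.random(n=n_starts)
    return qmc.scale(unit, lower, upper)


def fit_family(
    obs,
    family: CurveFamily | str,
    anchors: ToleranceSummary,
    n_reported: int,
    *,
    species: str | None = None,
    anchor_weight: float = 1.0,
    n_starts: int = 20,
    seed: int = 0,
    rss_tol: float = 1e-10,
) -> TPCFitResult:
    """Fit one curve family to anchored (temperature, performance) points.

    Parameters
    ----------
    obs:
        Sequence of ``(temperature, performance)`` pairs (treatment means by
        default, or individual observations).
    family:
        A :class:`~thermoperf.families.CurveFamily` or registry name.
    anchors:
        Tolerance summary supplying the two zero-performance anchor points
        ``(ct_min_mean, 0)`` and ``(ct_max_mean, 0)``.
    n_reported:
        Sample size entered into AICc (number of individuals behind the
        points, which may exceed the number of fitted points).
    anchor_weight:
        Least-squares weight of the two anchor points (data points have
        weight 1).
    n_starts:
        Number of Latin-hypercube multi-start initializations.

    Returns
    -------
    TPCFitResult
        With honest ``converged`` flag; non-convergence is reported, never
        masked.
    """
    if isinstance(family, str):
        family = get_family(family)
    pts = np.asarray(obs, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("obs must be (temperature, performance) pairs")
    t_lo, t_hi = anchors.ct_min_mean, anchors.ct_max_mean
    if not t_lo < t_hi:
        raise ValidationError("fitting requires ct_min_mean < ct_max_mean")

    temps = np.concatenate([pts[:, 0], [t_lo, t_hi]])
    perf = np.concatenate([pts[:, 1], [0.0, 0.0]])
    wts = np.concatenate([np.ones(len(pts)), [anchor_weight, anchor_weight]])
    swts = np.sqrt(wts)

    if len(temps) < family.n_params + 2:
        raise ValidationError(
            f"{family.name}: need >= {family.n_params + 2} anchored points, "
            f"have {len(temps)}"
        )

    tss = float(np.sum(wts * (perf - np.average(perf, weights=wts)) ** 2))
    if tss == 0:
        raise ComputationError("degenerate data: zero total sum of squares")

    lower, upper = family.bounds_fn(pts[:, 0], pts[:, 1], t_lo, t_hi)
    starts = _lhs_starts(lower, upper, n_starts, seed)

    def resid(p):
        return swts * (family(temps, p) - perf)

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lower, upper), method="trf", ftol=rss_tol,
                xtol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - pathological start
            continue
        rss = float(2 * sol.cost)
        if np.isfinite(rss) and (best is None or rss < best[0] - 0.0):
            best = (rss, sol)

    if best is None:
        raise ComputationError(f"{family.name}: all {n_starts} starts failed")
    rss, sol = best
    converged = bool(sol.success and np.isfinite(rss))
    r2 = 1.0 - rss / tss
    try:
        crit = aicc(rss, n_reported, family.n_params)
    except UndefinedAICcError:
        raise
    return TPCFitResult(
        species=species or anchors.species,
        family=family.name,
        params=tuple(float(v) for v in sol.x),
        rss=rss,
        r2=float(r2),
        aicc=float(crit),
        n_fit_points=len(temps),
        n_reported=n_reported,
        converged=converged,
        anchors=anchors,
    )


def fit_all_families(
    obs,
    anchors: ToleranceSummary,
    n_reported: int,
    families: Sequence[str] | None = None,
    **kwargs,
) -> list[TPCFitResult]:
    """Fit every requested family (default: all registered) to one dataset."""
    names = list(families) if families is not None else sorted(FAMILIES)
    out = []
    for name in names:
        try:
            out.append(fit_family(obs, name, anchors, n_reported, **kwargs))
        except ComputationError as exc:
            logger.warning("family %s failed to fit: %s", name, exc)
    if not out:
        raise ComputationError("no family produced a fit")
    return out


def select_tpc(results: Sequence[TPCFitResult], r2_floor: float = 0.9) -> TPCFitResult:
    """Pick the best TPC: lowest AICc among converged fits with r2 > floor.

    Ties are broken by fewer parameters, then by family name order, so the
    result does not depend on the input ordering.
    """
    if not results:
        raise SelectionError("empty candidate list")
    eligible = [r for r in results if r.converged and r.r2 > r2_floor]
    if not eligible:
        best_r2 = max((r.r2 for r in results if r.converged), default=float("nan"))
        raise SelectionError(
            f"no converged fit exceeded the r2 floor {r2_floor} "
            f"(best r2 = {best_r2:.4f})",
            best_r2=best_r2,
        )
    return min(eligible, key=lambda r: (r.aicc, r.n_params, r.family))


# ---------------------------------------------------------------------------
# Derived metrics
# ---------------------------------------------------------------------------


def derive_metrics(
    fit: TPCFitResult,
    anchors: ToleranceSummary | None = None,
    level: float = 0.8,
    grid_step: float = 0.01,
) -> ThermalMetrics:
    """Extract Vmax, To, B-level breadth, TSM and TTB from a fitted TPC.

    The optimum is located on a ``grid_step`` grid over the tolerance
    interval and refined by bounded scalar optimization; breadth endpoints
    solve ``curve(T) = level * v_max`` by bracketed root finding on each side
    of the optimum.  A side without a crossing (the curve stays above the
    level all the way to the anchor) reports the anchor with
    ``boundary_warning=True``.

    Raises
    ------
    AmbiguousCurveError
        If the clamped curve has more than one interior local maximum above
        ``level * v_max``.
    """
    anchors = anchors or fit.anchors
    if not fit.converged:
        raise InvalidMetricsError(f"{fit.species}: cannot derive metrics from "
                                  "a non-converged fit")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    family = get_family(fit.family)
    t_lo, t_hi = anchors.ct_min_mean, anchors.ct_max_mean

    grid = np.arange(t_lo, t_hi + grid_step, grid_step)
    vals = clamped_curve(family, fit.params, grid, t_lo, t_hi)
    i_max = int(np.argmax(vals))

    # refine the optimum inside the bracketing grid cells
    lo = grid[max(i_max - 1, 0)]
    hi = grid[min(i_max + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -clamped_curve(family, fit.params, float(t), t_lo, t_hi),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    t_o = float(res.x)
    v_max = float(-res.fun)
    if v_max <= 0:
        raise InvalidMetricsError(f"{fit.species}: fitted curve is nonpositive "
                                  "over the tolerance interval")

    threshold = level * v_max
    interior = vals[1:-1]
    peaks = (
        (interior > vals[:-2]) & (interior >= vals[2:]) & (interior > threshold)
    )
    # count runs of plateau peaks once
    n_peaks = int(np.sum(peaks & ~np.r_[False, peaks[:-1]]))
    if n_peaks > 1:
        raise AmbiguousCurveError(
            f"{fit.species}/{fit.family}: {n_peaks} local maxima above "
            f"{level:.0%} of v_max"
        )

    def shifted(t):
        return clamped_curve(family, fit.params, float(t), t_lo, t_hi) - threshold

    boundary_warning = False
    eps = min(grid_step, (t_hi - t_lo) * 1e-6)

    if shifted(t_lo + eps) >= 0:
        b_low = t_lo
        boundary_warning = True
        warnings.warn(
            f"{fit.species}: curve above {level:.0%} level at CTmin; "
            "reporting the boundary", stacklevel=2)
    else:
        b_low = float(optimize.brentq(shifted, t_lo + eps, t_o, xtol=1e-6))

    if shifted(t_hi - eps) >= 0:
        b_high = t_hi
        boundary_warning = True
        warnings.warn(
            f"{fit.species}: curve above {level:.0%} level at CTmax; "
            "reporting the boundary", stacklevel=2)
    else:
        b_high = float(optimize.brentq(shifted, t_o, t_hi - eps, xtol=1e-6))

    return ThermalMetrics(
        species=fit.species,
        v_max=v_max,
        t_o=t_o,
        b80_low=b_low,
        b80_high=b_high,
        tsm=thermal_safety_margin(t_hi, t_o),
        ttb=ttb(anchors),
        level=level,
        boundary_warning=boundary_warning,
    )
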