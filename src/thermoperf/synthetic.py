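"""Seeded generators for every pipeline input.

Three default :class:`SpeciesProfile` objects mimic the study system: a
terrestrial rattlesnake (high optimum, low metabolic thermal sensitivity), a
small fossorial snake (slowest swimmer) and a semiaquatic active forager
(fastest swimmer, highest mass-adjusted metabolism).  Tolerance means/SDs
and metabolic-model coefficients follow the reference parameterization in
``DEFAULT_PROFILES``; the TPC parameters are self-consistent fixed points of
the anchored curve fit (see ``scripts/solve_tpc_params.py`` for the original
metric-matching solve and the module notes below).

Design notes
------------
* The three curve families cannot simultaneously hold an 80% breadth of
  ~13 degC *and* fall to zero at the tolerance anchors, so default curve
  parameters are chosen as fixed points of the anchored fit: refitting a
  profile's own noiseless treatment means recovers the same curve.  This
  keeps optimum-recovery simulations unbiased.  Peak speeds and the optimum
  ordering across species match the reference table; breadths are narrower.
* All generators are pure functions of (profile, seed): identical inputs
  give identical outputs.
* Individual swim-speed heterogeneity is lognormal (sd 0.1 log-units);
  observation noise is Gaussian with sd ``speed_noise_sd * v_max``.
* Respirometry traces are plateau + single-exponential settle-in transient
  (time constant 120 s) + Gaussian noise, so the minimal-window rule
  recovers the plateau.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .families import get_family
from .kinematics import SwimTrial
from .respirometry import RMRRecord, RespTrace
from .tpc import SpeedObservation, ToleranceRecord, ToleranceSummary, clamped_curve

__all__ = [
    "SpeciesProfile",
    "DEFAULT_TREATMENTS",
    "make_default_profiles",
    "simulate_tolerance",
    "simulate_speeds",
    "simulate_swims",
    "simulate_rmr",
    "simulate_traces",
]

DEFAULT_TREATMENTS = (15.0, 25.0, 30.0, 33.0, 36.0)

#: reference thermal-performance characteristics used to parameterize the
#: default profiles (tolerance means/SDs, optimum, peak speed, 80% breadth).
#: ``scripts/solve_tpc_params.py`` solves the curve constants from these.
REFERENCE_METRICS: dict[str, dict[str, float | tuple[float, float]]] = {
    "Crotalus polystictus": {
        "ct_min": 5.9, "ct_min_sd": 0.27, "ct_max": 43.1, "ct_max_sd": 0.92,
        "t_o": 36.7, "v_max": 42.0, "b80": (26.3, 39.2),
    },
    "Conopsis lineata": {
        "ct_min": 9.3, "ct_min_sd": 1.67, "ct_max": 41.2, "ct_max_sd": 1.42,
        "t_o": 27.8, "v_max": 29.3, "b80": (20.1, 34.3),
    },
    "Thamnophis melanogaster": {
        "ct_min": 8.5, "ct_min_sd": 1.14, "ct_max": 41.6, "ct_max_sd": 1.34,
        "t_o": 28.6, "v_max": 71.7, "b80": (20.7, 34.9),
    },
}

#: minimum swim speed used when building frame counts, so five 30 cm
#: segments always fit in the 120 s trial cap
_SPEED_FLOOR = 1.5


@dataclass(frozen=True)
class SpeciesProfile:
    """Everything needed to simulate one species through the whole pipeline."""

    species: str
    n_individuals: int
    # body mass law, log10 grams
    log10_mass_mean: float
    log10_mass_sd: float
    # critical thermal limits, degC
    ct_min_mean: float
    ct_min_sd: float
    ct_max_mean: float
    ct_max_sd: float
    # thermal performance curve
    tpc_family: str
    tpc_params: tuple[float, ...]
    speed_noise_sd: float = 0.10  # fraction of v_max
    indiv_speed_sd: float = 0.10  # lognormal sd of the individual factor
    # metabolic model, log10 scale
    rmr_intercept: float = -1.0
    rmr_offsets: Mapping[float, float] = field(default_factory=dict)
    rmr_mass_slope: float = 0.7
    random_intercept_sd: float = 0.10
    residual_sd: float = 0.08
    # respirometry trace shape
    flow_rate: float = 100.0
    trace_noise_sd: float = 0.02  # fraction of the plateau
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.4, "F": 0.4, "juvenile": 0.2}
    )

    def __post_init__(self):
        for name in ("log10_mass_sd", "ct_min_sd", "ct_max_sd", "speed_noise_sd",
                     "indiv_speed_sd", "random_intercept_sd", "residual_sd",
                     "trace_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.species}: {name} must be >= 0")
        if not self.ct_min_mean < self.ct_max_mean:
            raise ValidationError(f"{self.species}: ct_min_mean >= ct_max_mean")
        offs = [self.rmr_offsets[t] for t in sorted(self.rmr_offsets)]
        if any(b < a for a, b in zip(offs, offs[1:])):
            raise ValidationError(
                f"{self.species}: treatment offsets must be nondecreasing"
            )
        if self.n_individuals < 1:
            raise ValidationError(f"{self.species}: n_individuals must be >= 1")

    # -- derived helpers ----------------------------------------------------

    def tolerance_summary(self) -> ToleranceSummary:
        return ToleranceSummary(
            species=self.species,
            ct_min_mean=self.ct_min_mean,
            ct_max_mean=self.ct_max_mean,
            ct_min_sd=self.ct_min_sd,
            ct_max_sd=self.ct_max_sd,
            n=self.n_individuals,
        )

    def curve(self, temps):
        """Clamped generating TPC evaluated at ``temps``."""
        return clamped_curve(
            get_family(self.tpc_family), self.tpc_params, temps,
            self.ct_min_mean, self.ct_max_mean,
        )

    def tpc_optimum(self, grid_step: float = 0.001) -> tuple[float, float]:
        """(t_o, v_max) of the generating curve by dense grid search."""
        grid = np.arange(self.ct_min_mean, self.ct_max_mean + grid_step, grid_step)
        vals = self.curve(grid)
        i = int(np.argmax(vals))
        return float(grid[i]), float(vals[i])

    def log10_rmr(self, treatment: float, log10_mass, u=0.0):
        """Expected log10 VCO2 for a treatment, mass and random intercept."""
        try:
            off = self.rmr_offsets[float(treatment)]
        except KeyError:
            raise ValidationError(
                f"{self.species}: no RMR offset for treatment {treatment}"
            ) from None
        return self.rmr_intercept + off + self.rmr_mass_slope * np.asarray(log10_mass) + u


def make_default_profiles() -> list[SpeciesProfile]:
    """The three reference species profiles.

    Tolerance means/SDs and metabolic coefficients are the reference-table
    values; TPC parameters are anchored-fit fixed points (module notes).
    """
    rattlesnake = SpeciesProfile(
        species="Crotalus polystictus",
        n_individuals=33,
        log10_mass_mean=2.0, log10_mass_sd=0.3,
        ct_min_mean=5.9, ct_min_sd=0.27,
        ct_max_mean=43.1, ct_max_sd=0.92,
        tpc_family="emg_peak",
        tpc_params=(284.930979, 36.494236, 1.783047, 0.348836),
        rmr_intercept=-0.944,
        rmr_offsets={15.0: 0.0, 25.0: 0.182, 30.0: 0.252, 33.0: 0.371, 36.0: 0.381},
        rmr_mass_slope=0.760,
        sex_probs={"M": 12 / 33, "F": 14 / 33, "juvenile": 7 / 33},
    )
    fossorial = SpeciesProfile(
        species="Conopsis lineata",
        n_individuals=31,
        log10_mass_mean=1.0, log10_mass_sd=0.3,
        ct_min_mean=9.3, ct_min_sd=1.67,
        ct_max_mean=41.2, ct_max_sd=1.42,
        tpc_family="asym_logistic_peak",
        tpc_params=(29.3, 2.568989, 29.610077, 0.641435),
        rmr_intercept=-0.931,
        rmr_offsets={15.0: 0.0, 25.0: 0.399, 30.0: 0.536, 33.0: 0.608, 36.0: 0.709},
        rmr_mass_slope=0.610,
        sex_probs={"M": 11 / 26, "F": 13 / 26, "juvenile": 2 / 26},
    )
    gartersnake = SpeciesProfile(
        species="Thamnophis melanogaster",
        n_individuals=38,
        log10_mass_mean=1.4, log10_mass_sd=0.3,
        ct_min_mean=8.5, ct_min_sd=1.14,
        ct_max_mean=41.6, ct_max_sd=1.34,
        tpc_family="gumbel_peak",
        tpc_params=(71.7, 30.083293, 5.185201),
        rmr_intercept=-0.965,
        rmr_offsets={15.0: 0.0, 25.0: 0.358, 30.0: 0.581, 33.0: 0.659, 36.0: 0.774},
        rmr_mass_slope=0.674,
        sex_probs={"M": 12 / 38, "F": 15 / 38, "juvenile": 11 / 38},
    )
    return [rattlesnake, fossorial, gartersnake]


# ---------------------------------------------------------------------------
# seeding helpers
# ---------------------------------------------------------------------------


def _rng(profile: SpeciesProfile, seed: int, stream: str) -> np.random.Generator:
    # distinct, reproducible stream per (seed, species, generator)
    tag = zlib.crc32(f"{profile.species}/{stream}".encode())
    return np.random.default_rng([seed, tag])


def _short_id(species: str) -> str:
    parts = species.split()
    return "".join(p[0].lower() for p in parts[:2]) or species[:2].lower()


def _individuals(profile: SpeciesProfile, rng: np.random.Generator, n: int):
    """(ids, sexes, masses) for one simulated cohort."""
    code = _short_id(profile.species)
    ids = [f"{code}{i + 1:03d}" for i in range(n)]
    sexes = rng.choice(
        list(profile.sex_probs), size=n, p=list(profile.sex_probs.values())
    )
    masses = 10.0 ** rng.normal(profile.log10_mass_mean, profile.log10_mass_sd, n)
    return ids, sexes, masses


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_tolerance(
    profile: SpeciesProfile, seed: int, n: int | None = None
) -> list[ToleranceRecord]:
    """Per-individual CT draws from normal(mean, sd), resampled until
    ct_min < ct_max."""
    n = n or profile.n_individuals
    rng = _rng(profile, seed, "tolerance")
    code = _short_id(profile.species)
    out = []
    for i in range(n):
        while True:
            lo = rng.normal(profile.ct_min_mean, profile.ct_min_sd)
            hi = rng.normal(profile.ct_max_mean, profile.ct_max_sd)
            if lo < hi:
                break
        out.append(
            ToleranceRecord(
                individual_id=f"{code}{i + 1:03d}",
                species=profile.species,
                ct_min=float(lo),
                ct_max=float(hi),
                cooling_rate=1.0,
                heating_rate=1.5,
            )
        )
    return out


def _true_speeds(profile, treatments, rng, n):
    """(ids, sexes, masses, speed matrix n x n_treatments) before obs noise."""
    ids, sexes, masses = _individuals(profile, rng, n)
    factors = np.exp(rng.normal(0.0, profile.indiv_speed_sd, n))
    base = profile.curve(np.asarray(treatments, float))
    return ids, sexes, masses, factors[:, None] * base[None, :]


def simulate_speeds(
    profile: SpeciesProfile,
    treatments: Sequence[float] = DEFAULT_TREATMENTS,
    seed: int = 0,
    n: int | None = None,
) -> list[SpeedObservation]:
    """Per-individual maximum swimming speed observations.

    observed = clamped_curve(T) * lognormal individual factor
               + N(0, speed_noise_sd * v_max), floored at 0.
    """
    n = n or profile.n_individuals
    rng = _rng(profile, seed, "speeds")
    ids, sexes, masses, truth = _true_speeds(profile, treatments, rng, n)
    _, v_max = profile.tpc_optimum(grid_step=0.01)
    obs = np.maximum(
        truth + rng.normal(0.0, profile.speed_noise_sd * v_max, truth.shape), 0.0
    )
    out = []
    for i in range(n):
        for j, t in enumerate(treatments):
            out.append(
                SpeedObservation(
                    individual_id=ids[i],
                    species=profile.species,
                    treatment_temp=float(t),
                    max_speed=float(obs[i, j]),
                    sex=str(sexes[i]),
                    body_mass=float(masses[i]),
                )
            )
    return out


def simulate_swims(
    profile: SpeciesProfile,
    treatments: Sequence[float] = DEFAULT_TREATMENTS,
    seed: int = 0,
    n: int | None = None,
    n_segments: int = 5,
    segment_noise_sd: float = 0.03,
    frame_rate: float = 60.0,
    segment_length: float = 30.0,
) -> list[SwimTrial]:
    """Filmed swim trials: per-segment frame counts around the trial speed.

    Segment speed_j = trial speed * exp(N(0, segment_noise_sd)); frames are
    rounded (and floored at 1).  Speeds are floored at 1.5 cm/s so five
    segments always fit the 120 s cap.
    """
    n = n or profile.n_individuals
    rng = _rng(profile, seed, "swims")
    ids, sexes, masses, truth = _true_speeds(profile, treatments, rng, n)
    _, v_max = profile.tpc_optimum(grid_step=0.01)
    obs = truth + rng.normal(0.0, profile.speed_noise_sd * v_max, truth.shape)
    obs = np.maximum(obs, _SPEED_FLOOR)
    trials = []
    for i in range(n):
        for j, t in enumerate(treatments):
            seg_speed = obs[i, j] * np.exp(
                rng.normal(0.0, segment_noise_sd, n_segments)
            )
            frames = np.maximum(
                np.round(segment_length / seg_speed * frame_rate), 1
            ).astype(int)
            trials.append(
                SwimTrial(
                    individual_id=ids[i],
                    treatment_temp=float(t),
                    segment_frames=tuple(int(f) for f in frames),
                    frame_rate=frame_rate,
                    segment_length=segment_length,
                    species=profile.species,
                    sex=str(sexes[i]),
                    body_mass=float(masses[i]),
                )
            )
    return trials


def _rmr_matrix(profile, treatments, rng, n):
    ids, sexes, masses = _individuals(profile, rng, n)
    u = rng.normal(0.0, profile.random_intercept_sd, n)
    log_rmr = np.empty((n, len(treatments)))
    for j, t in enumerate(treatments):
        eps = rng.normal(0.0, profile.residual_sd, n)
        log_rmr[:, j] = profile.log10_rmr(float(t), np.log10(masses), u) + eps
    return ids, sexes, masses, 10.0 ** log_rmr


def simulate_rmr(
    profile: SpeciesProfile,
    treatments: Sequence[float] = DEFAULT_TREATMENTS,
    seed: int = 0,
    n: int | None = None,
    include_33: bool = True,
) -> list[RMRRecord]:
    """Resting metabolic rate records straight from the mixed model.

    ``include_33=False`` drops the 33 degC treatment, mirroring a cohort
    measured without that trial.
    """
    n = n or profile.n_individuals
    treatments = [t for t in treatments if include_33 or float(t) != 33.0]
    rng = _rng(profile, seed, "rmr")
    ids, sexes, masses, rmr = _rmr_matrix(profile, treatments, rng, n)
    return [
        RMRRecord(
            individual_id=ids[i],
            species=profile.species,
            treatment_temp=float(t),
            body_mass=float(masses[i]),
            vco2=float(rmr[i, j]),
            sex=str(sexes[i]),
        )
        for i in range(n)
        for j, t in enumerate(treatments)
    ]


def simulate_traces(
    profile: SpeciesProfile,
    treatments: Sequence[float] = DEFAULT_TREATMENTS,
    seed: int = 0,
    n: int | None = None,
    duration_s: float = 1800.0,
    dt: float = 1.0,
    transient_amp: float = 1.0,
    transient_tau: float = 120.0,
    include_33: bool = True,
) -> list[RespTrace]:
    """Respirometry traces whose minimal-window mean recovers the plateau.

    fe_co2(t) = plateau * (1 + transient_amp * exp(-t / transient_tau))
                + N(0, trace_noise_sd * plateau),
    with plateau = generating VCO2 / flow_rate.
    """
    n = n or profile.n_individuals
    treatments = [t for t in treatments if include_33 or float(t) != 33.0]
    rng = _rng(profile, seed, "traces")
    ids, sexes, masses, rmr = _rmr_matrix(profile, treatments, rng, n)
    times = np.arange(0.0, duration_s, dt)
    decay = transient_amp * np.exp(-times / transient_tau)
    out = []
    for i in range(n):
        for j, t in enumerate(treatments):
            plateau = rmr[i, j] / profile.flow_rate
            fe = plateau * (1.0 + decay) + rng.normal(
                0.0, profile.trace_noise_sd * plateau, times.size
            )
            out.append(
                RespTrace(
                    individual_id=ids[i],
                    species=profile.species,
                    treatment_temp=float(t),
                    body_mass=float(masses[i]),
                    sample_times=times.copy(),
                    fe_co2=np.clip(fe, 0.0, None),
                    fi_co2=0.0,
                    flow_rate=profile.flow_rate,
                )
            )
    return out
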