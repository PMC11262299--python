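"""Swim-trial kinematics: frame counts -> segment speeds -> trial maximum.

Trials are filmed over a lane with marks every ``segment_length`` cm at
``frame_rate`` frames per second; the analyst records the number of frames
the animal needs to cross each segment.  Speeds are cm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .errors import InvalidFrameCountError, ValidationError
from .tpc import SpeedObservation

__all__ = ["SwimTrial", "segment_speed", "trial_max_speed"]

#: protocol target: animals should cross at least this many marks
MIN_SEGMENTS = 5


@dataclass(frozen=True)
class SwimTrial:
    """One filmed swim of one individual at one treatment temperature."""

    individual_id: str
    treatment_temp: float
    segment_frames: tuple[int, ...]
    frame_rate: float = 60.0
    segment_length: float = 30.0
    duration_cap: float = 120.0
    species: str = ""
    sex: str = "unknown"
    body_mass: float | None = None

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValidationError(f"{self.individual_id}: frame_rate must be > 0")
        if self.segment_length <= 0:
            raise ValidationError(f"{self.individual_id}: segment_length must be > 0")
        for f in self.segment_frames:
            if isinstance(f, float) and not f.is_integer():
                raise InvalidFrameCountError(
                    f"{self.individual_id}: fractional frame count {f}"
                )
            if int(f) <= 0:
                raise InvalidFrameCountError(
                    f"{self.individual_id}: frame count must be > 0, got {f}"
                )
        object.__setattr__(
            self, "segment_frames", tuple(int(f) for f in self.segment_frames)
        )
        total_s = sum(self.segment_frames) / self.frame_rate
        if total_s > self.duration_cap:
            raise ValidationError(
                f"{self.individual_id}: implied trial time {total_s:.1f}s exceeds "
                f"the {self.duration_cap:.0f}s cap"
            )


def segment_speed(frames: int, frame_rate: float = 60.0,
                  segment_length: float = 30.0) -> float:
    """Speed over one segment: segment_length / (frames / frame_rate), cm/s."""
    if isinstance(frames, float) and not float(frames).is_integer():
        raise InvalidFrameCountError(f"fractional frame count {frames}")
    if frames <= 0:
        raise InvalidFrameCountError(f"frame count must be > 0, got {frames}")
    return segment_length / (frames / frame_rate)


def trial_max_speed(trial: SwimTrial) -> SpeedObservation:
    """Maximum segment speed of a trial, with covariates carried through.

    Warns (does not fail) when fewer than :data:`MIN_SEGMENTS` segments were
    recorded, since the protocol targets at least five marks.
    """
    if not trial.segment_frames:
        raise ValidationError(f"{trial.individual_id}: trial has no segments")
    if len(trial.segment_frames) < MIN_SEGMENTS:
        warnings.warn(
            f"{trial.individual_id}: only {len(trial.segment_frames)} segments "
            f"(protocol targets {MIN_SEGMENTS})",
            stacklevel=2,
        )
    speeds = [
        segment_speed(f, trial.frame_rate, trial.segment_length)
        for f in trial.segment_frames
    ]
    return SpeedObservation(
        individual_id=trial.individual_id,
        species=trial.species,
        treatment_temp=trial.treatment_temp,
        max_speed=max(speeds),
        sex=trial.sex,
        body_mass=trial.body_mass,
    )
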