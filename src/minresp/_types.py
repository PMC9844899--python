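"""Core domain types shared across the pipeline.

Timestamps are seconds from the start of the recording. Speakers are
``"patient"`` / ``"therapist"``; pause patterns are the four
speaker-switching codes (P_P, P_T, T_P, T_T) plus BOUNDARY for pauses at
a session edge that lack a neighbouring utterance on one side.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

PATIENT = "patient"
THERAPIST = "therapist"
SPEAKERS = (PATIENT, THERAPIST)

WITHDRAWAL = "withdrawal"
CONFRONTATION = "confrontation"
RUPTURE_TYPES = (WITHDRAWAL, CONFRONTATION)

PATTERNS = ("P_P", "P_T", "T_P", "T_T")
BOUNDARY = "BOUNDARY"


@dataclass(frozen=True)
class SpeakerTurn:
    start: float
    end: float
    speaker: str

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(f"turn end {self.end} must exceed start {self.start}")
        if self.speaker not in SPEAKERS:
            raise ValueError(f"unknown speaker {self.speaker!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PauseEpisode:
    start: float
    end: float
    pattern: Optional[str] = None

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(f"pause end {self.end} must exceed start {self.start}")
        if self.pattern is not None and self.pattern not in PATTERNS + (BOUNDARY,):
            raise ValueError(f"unknown pattern {self.pattern!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def with_pattern(self, pattern: str) -> "PauseEpisode":
        return replace(self, pattern=pattern)


@dataclass(frozen=True)
class RuptureEpisode:
    start: float
    end: float
    dominant_type: str
    minimal_response: bool = False
    other_markers: frozenset = field(default_factory=frozenset)
    significance: Optional[int] = None

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(f"rupture end {self.end} must exceed start {self.start}")
        if self.dominant_type not in RUPTURE_TYPES:
            raise ValueError(f"unknown rupture type {self.dominant_type!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Complete per-session annotation: who spoke when, where the pauses
    are (with their switching pattern pre-assigned by the generator), and
    the planted rupture episodes."""

    dyad_id: str
    session_id: str
    session_length: float
    turns: list  # of SpeakerTurn
    pauses: list  # of PauseEpisode
    ruptures: list  # of RuptureEpisode

    def validate(self) -> None:
        events = sorted(
            [(t.start, t.end, "turn") for t in self.turns]
            + [(p.start, p.end, "pause") for p in self.pauses]
        )
        prev_end = 0.0
        for start, end, _ in events:
            if start < prev_end - 1e-9:
                raise ValueError("turns/pauses overlap")
            prev_end = end
        for r in self.ruptures:
            if r.start < -1e-9 or r.end > self.session_length + 1e-9:
                raise ValueError("rupture outside session")


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate
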