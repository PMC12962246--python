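"""MSVP trial design and face-stream scheduling.

The Moving Serial Visual Presentation (MSVP) paradigm shows a stream of 13
face images.  A new face appears at the screen centre every 300 ms (the SOA)
and drifts horizontally for 600 ms, so at most two faces are visible at any
moment and successive faces move in opposite directions.  One *critical* face
(target, personally familiar, or one of two frequency-matched controls) is
embedded at stream position 5-8; all analyses are time-locked to its onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

CONDITIONS: Tuple[str, ...] = ("target", "familiar", "control1", "control2")

#: Conditions pooled as the reference level in group contrasts.
CONTROL_CONDITIONS: Tuple[str, ...] = ("control1", "control2")

#: Default horizontal midpoint of a 1920-px display, in screen pixels.
DEFAULT_SCREEN_MIDPOINT_PX = 960.0


@dataclass(frozen=True)
class MSVPDesign:
    """Constants of the MSVP trial schedule.

    Defaults encode the study design: 13 faces at 300-ms SOA, each visible
    for 600 ms while travelling 60 px, the critical face at position 5-8,
    48 trials per condition (192 per participant), a 1000-ms pre-stream
    fixation and a 2000-ms post-stream fixation tail.
    """

    n_faces: int = 13
    soa_ms: int = 300
    face_duration_ms: int = 600
    move_amplitude_px: float = 60.0
    pre_stream_fixation_ms: int = 1000
    post_stream_fixation_ms: int = 2000
    critical_positions: Tuple[int, ...] = (5, 6, 7, 8)
    trials_per_condition: int = 48
    conditions: Tuple[str, ...] = CONDITIONS
    gaze_mode: str = "constrained"

    def __post_init__(self) -> None:
        if self.gaze_mode not in ("constrained", "free"):
            raise ValueError(f"gaze_mode must be 'constrained' or 'free', got {self.gaze_mode!r}")
        if self.n_faces < max(self.critical_positions):
            raise ValueError("critical_positions must lie within the stream")
        if self.soa_ms <= 0 or self.face_duration_ms <= 0:
            raise ValueError("soa_ms and face_duration_ms must be positive")

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions)

    @property
    def stream_duration_ms(self) -> int:
        """Face-1 onset to face-13 offset: (n-1) x SOA + face duration."""
        return (self.n_faces - 1) * self.soa_ms + self.face_duration_ms

    @property
    def trial_duration_ms(self) -> int:
        return (
            self.pre_stream_fixation_ms
            + self.stream_duration_ms
            + self.post_stream_fixation_ms
        )

    def critical_onset_ms(self, critical_position: int) -> int:
        """Onset of the critical face, in ms from trial start."""
        if critical_position not in self.critical_positions:
            raise ValueError(
                f"critical_position {critical_position} outside the allowed "
                f"positions {self.critical_positions}"
            )
        return self.pre_stream_fixation_ms + (critical_position - 1) * self.soa_ms

    def to_dict(self) -> dict:
        d = asdict(self)
        d["critical_positions"] = list(self.critical_positions)
        d["conditions"] = list(self.conditions)
        return d


@dataclass(frozen=True)
class FaceEvent:
    """One face in the stream: 1-based position, onset/offset and drift direction."""

    position: int
    onset_ms: int
    offset_ms: int
    direction: int  # +1 rightward, -1 leftward


@dataclass(frozen=True)
class Schedule:
    """Full face timeline of one trial, with the critical face singled out."""

    faces: Tuple[FaceEvent, ...]
    critical: FaceEvent

    @property
    def critical_onset_ms(self) -> int:
        return self.critical.onset_ms

    @property
    def critical_offset_ms(self) -> int:
        return self.critical.offset_ms

    @property
    def critical_direction(self) -> int:
        return self.critical.direction


def build_schedule(
    design: MSVPDesign,
    critical_position: int,
    first_direction: int = 1,
) -> Schedule:
    """Lay out the face stream of a single trial.

    Face k (1-based) appears ``pre_stream_fixation_ms + (k-1) * soa_ms`` after
    trial start and stays visible for ``face_duration_ms``; drift directions
    alternate starting from ``first_direction``.

    Parameters
    ----------
    design
        Trial-schedule constants.
    critical_position
        1-based stream position of the critical face; must be one of
        ``design.critical_positions``.
    first_direction
        Drift direction of face 1 (+1 right, -1 left).  The original studies
        do not fix it; the simulator randomises it per trial.
    """
    if first_direction not in (1, -1):
        raise ValueError("first_direction must be +1 or -1")
    onset0 = design.critical_onset_ms(critical_position)  # validates position
    faces = []
    for k in range(1, design.n_faces + 1):
        onset = design.pre_stream_fixation_ms + (k - 1) * design.soa_ms
        faces.append(
            FaceEvent(
                position=k,
                onset_ms=onset,
                offset_ms=onset + design.face_duration_ms,
                direction=first_direction * (-1) ** (k - 1),
            )
        )
    critical = faces[critical_position - 1]
    assert critical.onset_ms == onset0
    return Schedule(faces=tuple(faces), critical=critical)
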