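"""Validated behavioral records: instantaneous scans and communication events.

Two primitive observations drive everything downstream:

* :class:`ScanRecord` — one instantaneous sample of a focal individual taken on a
  2-minute tick within an 18-minute follow: who is in the focal's party (the temporary
  fission-fusion subgroup), who of those is within 10 m, and whether the focal is
  grooming (given / received / mutual) and with whom.
* :class:`CommEvent` — one timestamped communication act (a gesture case or a call)
  with a signaller, one or more recipients, and a functional category drawn from the
  ethogram. Pant-hoot calls are broadcast signals: every individual within 10 m of the
  signaller is a recipient, so a single event can carry several recipients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

# Functional categories of the gesture ethogram. Pant-hoot variants are gesture-
# accompanied calls; pant-grunt is the one-to-one submissive call directed up the
# dominance hierarchy.
GESTURE_FUNCTIONS: tuple[str, ...] = (
    "Threat to dominate",
    "Food sharing",
    "Other threat",
    "Travel",
    "Copulation",
    "Reassurance",
    "Greeting",
    "Gesture to mutually groom",
    "Gesture to receive groom",
    "Gesture to give groom",
    "Play",
)

PANT_HOOT_FUNCTIONS: tuple[str, ...] = (
    "Synchronized low-intensity pant-hoot",
    "Solo high-intensity pant-hoot",
    "Synchronized high-intensity pant-hoot",
)

PANT_GRUNT = "Pant-grunt"

#: Full controlled vocabulary for :attr:`CommEvent.category`.
EVENT_CATEGORIES: tuple[str, ...] = GESTURE_FUNCTIONS + PANT_HOOT_FUNCTIONS + (PANT_GRUNT,)

#: Categories whose dyadic counts come from assembled gesture sequences.
SEQUENCE_FUNCTIONS: tuple[str, ...] = GESTURE_FUNCTIONS

GROOMING_CATEGORIES: tuple[str, ...] = ("given", "received", "mutual")
GROOMING_STATES: tuple[str, ...] = ("none",) + GROOMING_CATEGORIES

#: Number of intentionality criteria scored per gesture case.
N_INTENTIONALITY_FLAGS = 5


class RecordValidationError(ValueError):
    """A record violates a structural invariant; the message names the field/row."""


@dataclass
class ScanRecord:
    """One 2-min instantaneous sample of a focal individual."""

    focal_id: str
    follow_id: str
    scan_index: int  # 1..9 within the follow
    timestamp: datetime
    party_ids: frozenset[str]
    within10_ids: frozenset[str]
    grooming: str = "none"
    grooming_partner: str | None = None

    def __post_init__(self) -> None:
        self.party_ids = frozenset(self.party_ids)
        self.within10_ids = frozenset(self.within10_ids)
        if not 1 <= self.scan_index <= 9:
            raise RecordValidationError(
                f"scan_index {self.scan_index} outside 1..9 (follow {self.follow_id})"
            )
        if self.focal_id in self.party_ids:
            raise RecordValidationError(
                f"focal {self.focal_id} listed in its own party (follow {self.follow_id})"
            )
        if not self.within10_ids <= self.party_ids:
            extra = sorted(self.within10_ids - self.party_ids)
            raise RecordValidationError(
                f"within-10-m individuals {extra} not in party "
                f"(focal {self.focal_id}, follow {self.follow_id}, scan {self.scan_index})"
            )
        if self.grooming not in GROOMING_STATES:
            raise RecordValidationError(f"unknown grooming state {self.grooming!r}")
        if self.grooming == "none":
            if self.grooming_partner is not None:
                raise RecordValidationError("grooming partner given without grooming state")
        else:
            if self.grooming_partner is None:
                raise RecordValidationError(
                    f"grooming state {self.grooming!r} without a partner "
                    f"(focal {self.focal_id}, follow {self.follow_id}, scan {self.scan_index})"
                )
            if self.grooming_partner not in self.within10_ids:
                raise RecordValidationError(
                    f"grooming partner {self.grooming_partner} not within 10 m "
                    f"(focal {self.focal_id}, follow {self.follow_id}, scan {self.scan_index})"
                )


@dataclass
class CommEvent:
    """One timestamped communication act (gesture case or call)."""

    event_id: str
    timestamp: datetime
    signaller_id: str
    recipient_ids: frozenset[str]
    category: str
    gesture_type: str | None = None
    goal: str | None = None
    context: str | None = None
    response: str | None = None
    intentionality_flags: tuple[bool, ...] = field(
        default_factory=lambda: (False,) * N_INTENTIONALITY_FLAGS
    )

    def __post_init__(self) -> None:
        self.recipient_ids = frozenset(self.recipient_ids)
        self.intentionality_flags = tuple(bool(f) for f in self.intentionality_flags)
        if not self.recipient_ids:
            raise RecordValidationError(f"event {self.event_id}: empty recipient set")
        if self.signaller_id in self.recipient_ids:
            raise RecordValidationError(
                f"event {self.event_id}: signaller {self.signaller_id} among recipients"
            )
        if self.category not in EVENT_CATEGORIES:
            raise RecordValidationError(
                f"event {self.event_id}: category {self.category!r} not in the ethogram "
                f"vocabulary"
            )
        if len(self.intentionality_flags) != N_INTENTIONALITY_FLAGS:
            raise RecordValidationError(
                f"event {self.event_id}: expected {N_INTENTIONALITY_FLAGS} "
                f"intentionality flags, got {len(self.intentionality_flags)}"
            )

    @property
    def is_gesture(self) -> bool:
        return self.category in GESTURE_FUNCTIONS
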