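"""Core domain containers for conversation corpora and turn transitions.

A :class:`Conversation` is a time-ordered list of speaker-attributed
vocalization intervals (:class:`Turn`).  A :class:`Transition` is the signed
offset-to-onset latency between two consecutive turns of different speakers:
negative values mean the next speaker started in overlap, positive values
mean a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

#: Controlled vocabulary for turn annotation labels.
#:
#: ``question`` / ``response`` type a transition as QR; the remaining labels
#: mark transitions for exclusion from analysis (minimal listener
#: backchannels, turns cut off by interruption, transitions spanning an
#: extended silence, stretches where overlapping talk makes the speaker
#: order unclear, and turns that begin with laughter).
LABEL_VOCABULARY = frozenset(
    {
        "question",
        "response",
        "backchannel",
        "interrupted_prior",
        "extended_silence",
        "unclear_overlap",
        "laughter_start",
    }
)

#: Exclusion categories in fixed precedence order.
EXCLUSION_ORDER = (
    "backchannel",
    "interrupted_prior",
    "extended_silence",
    "unclear_overlap",
    "laughter_start",
)


@dataclass(frozen=True)
class Turn:
    """One speaker's vocalization interval, in milliseconds."""

    conversation_id: str
    speaker_id: str
    onset_ms: float
    offset_ms: float
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValueError(
                f"turn offset ({self.offset_ms}) must exceed onset "
                f"({self.onset_ms}) for speaker {self.speaker_id!r}"
            )
        unknown = set(self.labels) - LABEL_VOCABULARY
        if unknown:
            raise ValueError(
                f"unknown labels {sorted(unknown)}; "
                f"vocabulary is {sorted(LABEL_VOCABULARY)}"
            )

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class Conversation:
    """A dyadic or triadic conversation as a time-ordered sequence of turns."""

    conversation_id: str
    group_size: int
    turns: list[Turn]

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError("group_size must be at least 2")
        self.turns = sorted(
            self.turns, key=lambda t: (t.onset_ms, t.speaker_id)
        )
        speakers = {t.speaker_id for t in self.turns}
        if self.turns and len(speakers) != self.group_size:
            raise ValueError(
                f"conversation {self.conversation_id!r}: {len(speakers)} "
                f"distinct speakers but group_size={self.group_size}"
            )

    @property
    def speakers(self) -> list[str]:
        return sorted({t.speaker_id for t in self.turns})


@dataclass
class Corpus:
    """A collection of conversations."""

    conversations: list[Conversation]

    def __iter__(self) -> Iterator[Conversation]:
        return iter(self.conversations)

    def __len__(self) -> int:
        return len(self.conversations)

    def by_group_size(self, group_size: int) -> list[Conversation]:
        return [c for c in self.conversations if c.group_size == group_size]


@dataclass
class Transition:
    """Signed latency between consecutive turns of different speakers.

    ``transition_ms = next.onset_ms - prior.offset_ms``; negative values are
    overlaps, positive values gaps, zero a perfect no-gap-no-overlap latch
    (counted as non-overlap).
    """

    conversation_id: str
    group_size: int
    prior_turn: Turn
    next_turn: Turn
    transition_ms: float
    type: str = "nonQR"  # "QR" or "nonQR"
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.prior_turn.speaker_id == self.next_turn.speaker_id:
            raise ValueError("prior and next turn must have different speakers")

    @property
    def overlap(self) -> bool:
        return self.transition_ms < 0


def check_vocabulary(labels: Sequence[str]) -> frozenset[str]:
    """Validate and freeze a label collection against the vocabulary."""
    fs = frozenset(labels)
    unknown = fs - LABEL_VOCABULARY
    if unknown:
        raise ValueError(
            f"unknown labels {sorted(unknown)}; "
            f"vocabulary is {sorted(LABEL_VOCABULARY)}"
        )
    return fs
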