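"""Turn-transition measurement, classification, exclusion and outlier filtering.

Transition times are measured from the offset of vocalization of one turn to
the onset of vocalization of the next turn by a different speaker: negative
values are overlaps, positive values gaps.  QR transitions are
question-response pairs (by annotation label); all other speaker changes are
non-QR.  Exclusion categories (backchannels, interrupted turns, extended
silences, unclear overlap, laughter starts) are applied with a fixed
precedence, and outliers are removed per group-size stratum with the
1.5 x IQR rule, QR and non-QR pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from turntimes.types import (
    Conversation,
    Corpus,
    EXCLUSION_ORDER,
    Transition,
)

logger = logging.getLogger(__name__)


def measure_transitions(conversation: Conversation) -> list[Transition]:
    """Offset-to-onset transitions between consecutive different-speaker turns.

    For each turn, the next turn is the earliest-onset turn beginning after
    that turn's onset whose speaker differs (onset ties broken by
    speaker_id).  ``transition_ms = next.onset_ms - prior.offset_ms``; a
    conversation with fewer than two turns yields an empty list.
    """
    turns = conversation.turns
    out: list[Transition] = []
    for i, prior in enumerate(turns):
        nxt = None
        for cand in turns[i + 1 :]:
            if cand.speaker_id != prior.speaker_id:
                nxt = cand
                break
        if nxt is None:
            continue
        t = Transition(
            conversation_id=conversation.conversation_id,
            group_size=conversation.group_size,
            prior_turn=prior,
            next_turn=nxt,
            transition_ms=nxt.onset_ms - prior.offset_ms,
        )
        t.type = classify_type(t)
        out.append(t)
    return out


def classify_type(transition: Transition) -> str:
    """QR iff the prior turn is a question and the next turn its response."""
    if (
        "question" in transition.prior_turn.labels
        and "response" in transition.next_turn.labels
    ):
        return "QR"
    return "nonQR"


def apply_exclusions(
    transitions: list[Transition],
) -> tuple[list[Transition], list[Transition]]:
    """Split transitions into kept and excluded, with the first matching reason.

    Categories, in fixed precedence: next turn is a backchannel; prior turn
    was cut off by interruption; the transition spans an extended silence
    (label on the next turn); either turn sits in unclear overlapping talk;
    the next turn starts with laughter.  QR typing is orthogonal and never a
    reason for exclusion.  Excluded transitions get ``excluded_reason`` set.
    """
    kept: list[Transition] = []
    excluded: list[Transition] = []
    for t in transitions:
        reason = None
        for cat in EXCLUSION_ORDER:
            if cat == "backchannel" and "backchannel" in t.next_turn.labels:
                reason = cat
            elif (
                cat == "interrupted_prior"
                and "interrupted_prior" in t.prior_turn.labels
            ):
                reason = cat
            elif (
                cat == "extended_silence"
                and "extended_silence" in t.next_turn.labels
            ):
                reason = cat
            elif cat == "unclear_overlap" and (
                "unclear_overlap" in t.prior_turn.labels
                or "unclear_overlap" in t.next_turn.labels
            ):
                reason = cat
            elif (
                cat == "laughter_start"
                and "laughter_start" in t.next_turn.labels
            ):
                reason = cat
            if reason is not None:
                break
        if reason is None:
            kept.append(t)
        else:
            t.excluded_reason = reason
            excluded.append(t)
    return kept, excluded


@dataclass
class FilterReport:
    """Bookkeeping for the grouped IQR outlier filter."""

    factor: float
    bounds: pd.DataFrame  # per group_size: q25, q75, lower, upper, n, n_outliers
    n_input: int
    n_kept: int
    n_outliers: int
    unfiltered_strata: list[int] = field(default_factory=list)


def iqr_outlier_filter(
    transitions: list[Transition], factor: float = 1.5
) -> tuple[list[Transition], list[Transition], FilterReport]:
    """Remove per-group-size IQR outliers, QR and non-QR pooled.

    Within each group-size stratum, quartiles are computed by linear
    interpolation between order statistics (R type-7 convention, the default
    of the common analysis environments); values strictly above
    q0.75 + factor x IQR or strictly below q0.25 - factor x IQR are removed.
    Strata with fewer than 4 values are kept unfiltered with a warning.
    """
    kept: list[Transition] = []
    outliers: list[Transition] = []
    rows = []
    unfiltered: list[int] = []
    by_group: dict[int, list[Transition]] = {}
    for t in transitions:
        by_group.setdefault(t.group_size, []).append(t)

    for g in sorted(by_group):
        ts = by_group[g]
        vals = np.array([t.transition_ms for t in ts])
        if len(vals) < 4:
            logger.warning(
                "group_size %d stratum has %d < 4 transitions; kept unfiltered",
                g,
                len(vals),
            )
            kept.extend(ts)
            unfiltered.append(g)
            rows.append(
                {
                    "group_size": g,
                    "q25": np.nan,
                    "q75": np.nan,
                    "lower": -np.inf,
                    "upper": np.inf,
                    "n": len(vals),
                    "n_outliers": 0,
                }
            )
            continue
        q25, q75 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
        iqr = q75 - q25
        lo, hi = q25 - factor * iqr, q75 + factor * iqr
        n_out = 0
        for t, v in zip(ts, vals):
            if v > hi or v < lo:  # strict inequalities
                outliers.append(t)
                n_out += 1
            else:
                kept.append(t)
        rows.append(
            {
                "group_size": g,
                "q25": float(q25),
                "q75": float(q75),
                "lower": float(lo),
                "upper": float(hi),
                "n": len(vals),
                "n_outliers": n_out,
            }
        )

    report = FilterReport(
        factor=factor,
        bounds=pd.DataFrame(rows),
        n_input=len(transitions),
        n_kept=len(kept),
        n_outliers=len(outliers),
        unfiltered_strata=unfiltered,
    )
    return kept, outliers, report


def transitions_to_frame(transitions: list[Transition]) -> pd.DataFrame:
    """Tabulate transitions (one row each) for statistics and serialization."""
    return pd.DataFrame(
        [
            {
                "conversation_id": t.conversation_id,
                "group_size": t.group_size,
                "prior_speaker": t.prior_turn.speaker_id,
                "next_speaker": t.next_turn.speaker_id,
                "transition_ms": t.transition_ms,
                "type": t.type,
                "overlap": t.overlap,
                "excluded_reason": t.excluded_reason,
            }
            for t in transitions
        ],
        columns=[
            "conversation_id", "group_size", "prior_speaker", "next_speaker",
            "transition_ms", "type", "overlap", "excluded_reason",
        ],
    )


def extract_corpus_transitions(
    corpus: Corpus, iqr_factor: float = 1.5
) -> tuple[list[Transition], list[Transition], list[Transition], FilterReport]:
    """Full measurement pipeline over a corpus.

    Measures all transitions, applies the exclusion categories, then the
    grouped IQR filter on the kept transitions.  Returns
    ``(kept, excluded, iqr_outliers, filter_report)``.
    """
    measured: list[Transition] = []
    for conv in corpus:
        measured.extend(measure_transitions(conv))
    kept, excluded = apply_exclusions(measured)
    kept, outliers, report = iqr_outlier_filter(kept, factor=iqr_factor)
    return kept, excluded, outliers, report
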