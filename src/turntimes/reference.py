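"""Published corpus tallies and the bookkeeping arithmetic around them.

A reference dyadic/triadic conversation corpus reports, per group of 12
conversations, the number of question-response (QR) and non-QR transitions
entering analysis, and the number of transition-time outliers removed by
the grouped 1.5 x IQR rule.  These tallies anchor the pipeline's ledger
arithmetic: per-conversation means, the outlier percentage, and the number
of observations entering the mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Transition counts per (group kind, transition type) in the reference corpus.
REFERENCE_COUNTS: dict[tuple[str, str], int] = {
    ("dyad", "QR"): 459,
    ("dyad", "nonQR"): 290,
    ("triad", "QR"): 497,
    ("triad", "nonQR"): 259,
}

#: Conversations per group in the reference corpus.
CONVERSATIONS_PER_GROUP = 12

#: Transition-time outliers removed by the grouped IQR filter.
REFERENCE_N_OUTLIERS = 90


def mean_per_conversation(
    group: str, transition_type: str, n_conversations: int = CONVERSATIONS_PER_GROUP
) -> float:
    """Mean number of transitions per conversation for one stratum."""
    return REFERENCE_COUNTS[(group, transition_type)] / n_conversations


@dataclass(frozen=True)
class OutlierLedger:
    n_total: int
    n_outliers: int

    @property
    def percent_outliers(self) -> float:
        return 100.0 * self.n_outliers / self.n_total

    @property
    def n_model_obs(self) -> int:
        return self.n_total - self.n_outliers


def outlier_ledger(
    counts: dict[tuple[str, str], int] | None = None,
    n_outliers: int = REFERENCE_N_OUTLIERS,
) -> OutlierLedger:
    """Total transitions, outlier percentage and model observation count."""
    counts = REFERENCE_COUNTS if counts is None else counts
    return OutlierLedger(n_total=sum(counts.values()), n_outliers=n_outliers)
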