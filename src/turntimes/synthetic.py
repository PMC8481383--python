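"""Synthetic response-time datasets and conversation corpora with known truth.

Two generators:

* :func:`gen_rt_dataset` draws trial-level response latencies for a
  participants x conditions x trials design.  Unimodal right-skewed
  conditions use an ex-Gaussian (Gaussian + exponential tail), bimodal
  conditions a two-Gaussian mixture whose early component may sit *before*
  the question's offset (negative latencies).  Participants differ by a
  single additive shift (random intercept).

* :func:`gen_conversation_corpus` lays dyadic/triadic conversations on a
  single timeline: each next turn starts at the prior turn's offset plus a
  signed draw (negative = overlap), with tunable per-stratum overlap
  probabilities, question-response (QR) rates, injectable exclusion-category
  events and a per-speaker random intercept on transition times.  The
  returned :class:`GroundTruth` carries the injected effects and an exact
  per-transition ledger for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from turntimes.types import (
    Conversation,
    Corpus,
    EXCLUSION_ORDER,
    Turn,
)

DISPLAYS = ("monochrome", "multicolor")
RESPONSES = ("affirmative", "negative")
TRANSITION_TYPES = ("QR", "nonQR")


# --------------------------------------------------------------------------
# Response-time distributions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExGaussian:
    """Ex-Gaussian latency distribution: N(mu, sigma) + Exp(tau), in ms.

    Mean = mu + tau; variance = sigma^2 + tau^2.  The standard unimodal,
    right-skewed response-time model.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("ExGaussian.sigma must be > 0")
        if self.tau <= 0:
            raise ValueError("ExGaussian.tau must be > 0")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def sd(self) -> float:
        return math.hypot(self.sigma, self.tau)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, n) + rng.exponential(self.tau, n)


@dataclass(frozen=True)
class GaussianMixtureRT:
    """Two-Gaussian mixture for bimodal latency distributions, in ms.

    ``weight_early`` is the probability of the early component, whose mean
    may be negative (responses launched before the question's offset).
    """

    weight_early: float
    early_mu: float
    early_sd: float
    late_mu: float
    late_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_early <= 1.0:
            raise ValueError("GaussianMixtureRT.weight_early must be in [0, 1]")
        if self.early_sd <= 0 or self.late_sd <= 0:
            raise ValueError("GaussianMixtureRT component sds must be > 0")

    @property
    def mean(self) -> float:
        w = self.weight_early
        return w * self.early_mu + (1 - w) * self.late_mu

    @property
    def sd(self) -> float:
        w, m = self.weight_early, self.mean
        var = w * (self.early_sd**2 + (self.early_mu - m) ** 2) + (1 - w) * (
            self.late_sd**2 + (self.late_mu - m) ** 2
        )
        return math.sqrt(var)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        early = rng.random(n) < self.weight_early
        out = np.where(
            early,
            rng.normal(self.early_mu, self.early_sd, n),
            rng.normal(self.late_mu, self.late_sd, n),
        )
        return out


RTDistribution = Union[ExGaussian, GaussianMixtureRT]


# --------------------------------------------------------------------------
# RT dataset generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RTGenSpec:
    """Specification for a synthetic response-time dataset.

    ``conditions`` maps (display, response) cells to latency distributions.
    ``participant_sd`` is the sd (ms) of the per-participant additive shift,
    drawn once per participant; ``error_rate`` flags trials incorrect at
    random (incorrect trials keep a latency from the same distribution —
    exclusion acts on the flag, not the value).
    """

    n_participants: int
    trials_per_condition: int
    conditions: Mapping[tuple[str, str], RTDistribution]
    error_rate: float = 0.03
    participant_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("RTGenSpec.n_participants must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("RTGenSpec.trials_per_condition must be >= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("RTGenSpec.error_rate must be in [0, 1]")
        if self.participant_sd < 0:
            raise ValueError("RTGenSpec.participant_sd must be >= 0")
        if not self.conditions:
            raise ValueError("RTGenSpec.conditions must be non-empty")
        for (display, response) in self.conditions:
            if display not in DISPLAYS or response not in RESPONSES:
                raise ValueError(
                    f"RTGenSpec.conditions: unknown condition "
                    f"({display!r}, {response!r})"
                )


def table1_like_spec(
    n_participants: int = 20,
    trials_per_condition: int = 32,
    seed: int = 0,
) -> RTGenSpec:
    """A four-condition spec emulating a picture-question answering task.

    Multi-color displays (response plannable only after the noun) get
    unimodal right-skewed ex-Gaussians; monochrome displays (response
    plannable from the adjective onward) get bimodal mixtures whose early
    component precedes the question offset.  Parameters are chosen so the
    marginal mean/sd per cell (including the 40 ms participant shift)
    approximate the published cells: multi-color negative 417 (177),
    multi-color affirmative 344 (172), monochrome negative 200 (249),
    monochrome affirmative 234 (241).
    """
    conditions: dict[tuple[str, str], RTDistribution] = {
        ("multicolor", "negative"): ExGaussian(mu=262.0, sigma=75.5, tau=155.0),
        ("multicolor", "affirmative"): ExGaussian(mu=194.0, sigma=74.0, tau=150.0),
        ("monochrome", "negative"): GaussianMixtureRT(
            weight_early=0.35, early_mu=-80.0, early_sd=90.0,
            late_mu=350.0, late_sd=154.0,
        ),
        ("monochrome", "affirmative"): GaussianMixtureRT(
            weight_early=0.30, early_mu=-60.0, early_sd=90.0,
            late_mu=360.0, late_sd=156.0,
        ),
    }
    return RTGenSpec(
        n_participants=n_participants,
        trials_per_condition=trials_per_condition,
        conditions=conditions,
        seed=seed,
    )


def gen_rt_dataset(spec: RTGenSpec) -> pd.DataFrame:
    """Generate one RT record per participant x condition x trial.

    Returns a DataFrame with columns ``participant_id, display, response,
    rt_ms, correct``.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"p{i:02d}" for i in range(1, spec.n_participants + 1)]
    shifts = rng.normal(0.0, spec.participant_sd, spec.n_participants)
    frames = []
    n = spec.trials_per_condition
    for pid, shift in zip(ids, shifts):
        for (display, response), dist in spec.conditions.items():
            rt = dist.sample(rng, n) + shift
            correct = rng.random(n) >= spec.error_rate
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "display": display,
                        "response": response,
                        "rt_ms": rt,
                        "correct": correct,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Conversation corpus generator
# --------------------------------------------------------------------------

def _trunc_normal(
    rng: np.random.Generator, loc: float, scale: float, lo: float, hi: float
) -> float:
    """One draw from N(loc, scale) truncated to (lo, hi), by inverse CDF."""
    a = ndtr((lo - loc) / scale)
    b = ndtr((hi - loc) / scale)
    u = a + rng.random() * (b - a)
    # guard the open interval against floating-point saturation
    u = min(max(u, 1e-12), 1.0 - 1e-12)
    return loc + scale * ndtri(u)


def _trunc_normal_mean(loc: float, scale: float, lo: float, hi: float) -> float:
    """Closed-form mean of N(loc, scale) truncated to (lo, hi)."""
    a = (lo - loc) / scale
    b = (hi - loc) / scale
    phi = lambda x: math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)
    z = ndtr(b) - ndtr(a)
    return loc + scale * (phi(a) - phi(b)) / z


@dataclass(frozen=True)
class CorpusGenSpec:
    """Specification for a synthetic dyadic/triadic conversation corpus.

    Transition times are signed offset-to-onset latencies: with probability
    ``overlap_prob[(group_size, type)]`` the next turn starts in overlap and
    its latency is drawn from ``overlap_dist`` truncated to
    (-max_overlap_ms, 0); otherwise from ``gap_dist`` truncated to
    (0, inf).  The responder's random intercept shifts the location of
    either draw.  Exclusion-category events are injected per transition as a
    single categorical draw at ``exclusion_rates``.
    """

    n_conversations: Mapping[int, int] = field(
        default_factory=lambda: {2: 12, 3: 12}
    )
    minutes: float = 5.0
    qr_rate: float = 0.30
    overlap_prob: Mapping[tuple[int, str], float] = field(
        default_factory=lambda: {
            (2, "QR"): 0.32, (2, "nonQR"): 0.24,
            (3, "QR"): 0.35, (3, "nonQR"): 0.38,
        }
    )
    gap_dist: Mapping[tuple[int, str], tuple[float, float]] = field(
        default_factory=lambda: {
            (2, "QR"): (390.0, 150.0), (2, "nonQR"): (390.0, 150.0),
            (3, "QR"): (335.0, 150.0), (3, "nonQR"): (335.0, 150.0),
        }
    )
    overlap_dist: Mapping[tuple[int, str], tuple[float, float]] = field(
        default_factory=lambda: {
            (2, "QR"): (-270.0, 150.0), (2, "nonQR"): (-270.0, 150.0),
            (3, "QR"): (-270.0, 150.0), (3, "nonQR"): (-270.0, 150.0),
        }
    )
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "backchannel": 0.10,
            "interrupted_prior": 0.03,
            "extended_silence": 0.03,
            "unclear_overlap": 0.02,
            "laughter_start": 0.04,
        }
    )
    speaker_intercept_sd: float = 75.0
    turn_duration_ms: tuple[float, float] = (4000.0, 1000.0)
    min_turn_duration_ms: float = 1300.0
    max_overlap_ms: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_conversations or sum(self.n_conversations.values()) < 1:
            raise ValueError(
                "CorpusGenSpec.n_conversations must request >= 1 conversation"
            )
        for g in self.n_conversations:
            if g < 2:
                raise ValueError("CorpusGenSpec group sizes must be >= 2")
        if not 0.0 <= self.qr_rate <= 1.0:
            raise ValueError("CorpusGenSpec.qr_rate must be in [0, 1]")
        for key, p in self.overlap_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"CorpusGenSpec.overlap_prob[{key}] must be in [0, 1]"
                )
        for cat, p in self.exclusion_rates.items():
            if cat not in EXCLUSION_ORDER:
                raise ValueError(
                    f"CorpusGenSpec.exclusion_rates: unknown category {cat!r}"
                )
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"CorpusGenSpec.exclusion_rates[{cat}] must be in [0, 1]"
                )
        if sum(self.exclusion_rates.values()) > 1.0 + 1e-12:
            raise ValueError("CorpusGenSpec.exclusion_rates must sum to <= 1")
        if self.speaker_intercept_sd < 0:
            raise ValueError("CorpusGenSpec.speaker_intercept_sd must be >= 0")
        if self.max_overlap_ms <= 0:
            raise ValueError("CorpusGenSpec.max_overlap_ms must be > 0")
        # deep overlap must never reach back past the prior speaker's own
        # previous offset, or per-speaker interval tiers would overlap
        if self.min_turn_duration_ms <= 2 * self.max_overlap_ms:
            raise ValueError(
                "CorpusGenSpec.min_turn_duration_ms must exceed "
                "2 * max_overlap_ms to keep per-speaker tiers disjoint"
            )


@dataclass
class GroundTruth:
    """Injected effects and exact per-transition ledger of a generated corpus.

    ``ledger`` has one row per generated transition with its stratum, sign,
    injected exclusion category and exact latency — the oracle for
    measurement, exclusion and count-conservation tests.
    """

    spec: CorpusGenSpec
    ledger: pd.DataFrame
    speaker_intercepts: dict[str, float]

    def injected_gap_diff(self, transition_type: str) -> float:
        """Nominal dyad - triad difference in gap-distribution location (ms)."""
        return (
            self.spec.gap_dist[(2, transition_type)][0]
            - self.spec.gap_dist[(3, transition_type)][0]
        )

    def expected_gap_diff(self, transition_type: str, n_quad: int = 61) -> float:
        """Exact dyad - triad difference in expected *gap* latency (ms).

        Averages the truncated-normal mean over the speaker-intercept
        distribution by Gauss-Hermite quadrature, so the value accounts for
        the >= 0 truncation of gap draws.
        """
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        sd_b = self.spec.speaker_intercept_sd

        def mean_for(group: int) -> float:
            mu, sd = self.spec.gap_dist[(group, transition_type)]
            vals = [
                _trunc_normal_mean(mu + sd_b * x, sd, 0.0, math.inf)
                for x in nodes
            ]
            return float(np.dot(weights, vals) / math.sqrt(2 * math.pi))

        return mean_for(2) - mean_for(3)

    def injected_overlap_diff(self, transition_type: str) -> float:
        """Dyad - triad difference in overlap probability."""
        return (
            self.spec.overlap_prob[(2, transition_type)]
            - self.spec.overlap_prob[(3, transition_type)]
        )

    @property
    def n_transitions(self) -> int:
        return len(self.ledger)

    def n_excluded(self, category: Optional[str] = None) -> int:
        excl = self.ledger["excluded_reason"].notna()
        if category is not None:
            excl &= self.ledger["excluded_reason"] == category
        return int(excl.sum())

    @property
    def n_kept(self) -> int:
        return int(self.ledger["excluded_reason"].isna().sum())


def gen_conversation_corpus(spec: CorpusGenSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus of conversations plus its ground truth.

    Turns are chained on one timeline per conversation: each next turn is by
    a different speaker and starts at the prior offset plus a signed draw.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cats = list(EXCLUSION_ORDER)
    cat_probs = np.array([spec.exclusion_rates.get(c, 0.0) for c in cats])
    dur_mu, dur_sd = spec.turn_duration_ms

    conversations: list[Conversation] = []
    ledger_rows: list[dict] = []
    intercepts: dict[str, float] = {}

    for group_size in sorted(spec.n_conversations):
        for ci in range(spec.n_conversations[group_size]):
            conv_id = f"g{group_size}_c{ci:02d}"
            speakers = [f"{conv_id}_s{j}" for j in range(1, group_size + 1)]
            for s in speakers:
                intercepts[s] = float(
                    rng.normal(0.0, spec.speaker_intercept_sd)
                )

            # mutable per-turn state; frozen into Turn objects at the end
            onsets: list[float] = []
            offsets: list[float] = []
            turn_speakers: list[str] = []
            labels: list[set[str]] = []
            conv_ledger: list[dict] = []

            t_end = spec.minutes * 60_000.0
            onset = float(rng.uniform(0.0, 500.0))
            speaker = speakers[int(rng.integers(group_size))]
            pending_labels: set[str] = set()
            while onset < t_end:
                duration = max(
                    float(rng.normal(dur_mu, dur_sd)), spec.min_turn_duration_ms
                )
                onsets.append(onset)
                offsets.append(onset + duration)
                turn_speakers.append(speaker)
                labels.append(pending_labels)

                others = [s for s in speakers if s != speaker]
                nxt = others[int(rng.integers(len(others)))]

                ttype = "QR" if rng.random() < spec.qr_rate else "nonQR"
                u = rng.random()
                cum = np.cumsum(cat_probs)
                idx = int(np.searchsorted(cum, u, side="right"))
                category = cats[idx] if idx < len(cats) else None

                b = intercepts[nxt]
                if category == "extended_silence":
                    delta = 2000.0 + abs(float(rng.normal(3000.0, 800.0)))
                else:
                    overlap = rng.random() < spec.overlap_prob[
                        (group_size, ttype)
                    ]
                    if overlap:
                        mu, sd = spec.overlap_dist[(group_size, ttype)]
                        delta = _trunc_normal(
                            rng, mu + b, sd, -spec.max_overlap_ms, 0.0
                        )
                    else:
                        mu, sd = spec.gap_dist[(group_size, ttype)]
                        delta = _trunc_normal(rng, mu + b, sd, 0.0, math.inf)

                next_onset = offsets[-1] + delta
                if next_onset >= t_end:
                    break

                prior_idx = len(onsets) - 1
                if ttype == "QR":
                    labels[prior_idx].add("question")
                if category == "interrupted_prior":
                    labels[prior_idx].add("interrupted_prior")

                pending_labels = set()
                if ttype == "QR":
                    pending_labels.add("response")
                if category is not None and category != "interrupted_prior":
                    pending_labels.add(category)

                conv_ledger.append(
                    {
                        "conversation_id": conv_id,
                        "group_size": group_size,
                        "prior_speaker": speaker,
                        "next_speaker": nxt,
                        "transition_ms": delta,
                        "type": ttype,
                        "overlap": delta < 0,
                        "injected_category": category,
                    }
                )

                onset = next_onset
                speaker = nxt

            # effective exclusion reason, mirroring the measurement rules'
            # precedence: an unclear_overlap label on a turn also excludes
            # the *following* transition (rule checks either flanking turn)
            for j, row in enumerate(conv_ledger):
                cat = row["injected_category"]
                prev_cat = (
                    conv_ledger[j - 1]["injected_category"] if j > 0 else None
                )
                if cat in ("backchannel", "interrupted_prior",
                           "extended_silence"):
                    reason = cat
                elif cat == "unclear_overlap" or prev_cat == "unclear_overlap":
                    reason = "unclear_overlap"
                elif cat == "laughter_start":
                    reason = cat
                else:
                    reason = None
                row["excluded_reason"] = reason
            ledger_rows.extend(conv_ledger)

            # freeze turns
            turns = [
                Turn(
                    conversation_id=conv_id,
                    speaker_id=s,
                    onset_ms=o,
                    offset_ms=f,
                    labels=frozenset(lab),
                )
                for s, o, f, lab in zip(turn_speakers, onsets, offsets, labels)
            ]
            conversations.append(
                Conversation(
                    conversation_id=conv_id,
                    group_size=group_size,
                    turns=turns,
                )
            )

    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "conversation_id", "group_size", "prior_speaker", "next_speaker",
            "transition_ms", "type", "overlap", "injected_category",
            "excluded_reason",
        ],
    )
    truth = GroundTruth(spec=spec, ledger=ledger, speaker_intercepts=intercepts)
    return Corpus(conversations), truth
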