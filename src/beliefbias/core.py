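"""Odds-form Bayesian belief updating with confirmation-bias weighting.

The model tracks a single probability — the belief that treatment A (in the
motivating clinical setting, anatomic total shoulder arthroplasty) is superior
to treatment B (reverse total shoulder arthroplasty).  Each piece of evidence
is a likelihood ratio

    LR = P(evidence | A superior) / P(evidence | B superior),

so LR > 1 favours A, LR < 1 favours B and LR = 1 is neutral.  Unbiased
updating multiplies the prior odds by the likelihood ratio; confirmation bias
is modelled by raising the likelihood ratio to an exponent ``w`` in [0, 1]
whenever the evidence *disconfirms* the currently favoured treatment:

    posterior_odds = prior_odds * LR ** w

``w = 1`` recovers ideal Bayesian updating; ``w = 0`` ignores disconfirming
evidence entirely.  Whether evidence confirms or disconfirms is decided
against the belief held *before* the update, relative to a threshold
(default 0.5): a believer at or above the threshold favours A, below it
favours B.  Belief exactly at the threshold counts as favouring A, so
B-favouring evidence at equipoise is disconfirming.

All arithmetic is carried out in log-odds space and probabilities are clamped
to ``[1e-12, 1 - 1e-12]`` so that extreme priors cannot produce division by
zero or infinite odds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PROB_FLOOR",
    "BeliefState",
    "Evidence",
    "BiasPolicy",
    "UpdateRecord",
    "Trajectory",
    "clamp_probability",
    "probability_to_odds",
    "odds_to_probability",
    "classify_evidence",
    "apply_update",
    "run_sequence",
]

#: Probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR].
PROB_FLOOR = 1e-12

CONFIRMING = "confirming"
DISCONFIRMING = "disconfirming"
NEUTRAL = "neutral"


def clamp_probability(p: float) -> float:
    """Clamp ``p`` into the open unit interval used by the updater.

    Values within ``PROB_FLOOR`` of 0 or 1 are pulled back onto the floor;
    values outside ``[0, 1]`` altogether are a caller error.
    """
    p = float(p)
    if not math.isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p!r}")
    return min(max(p, PROB_FLOOR), 1.0 - PROB_FLOOR)


def probability_to_odds(p: float) -> float:
    """Convert a probability to odds ``p / (1 - p)``.

    The input is clamped first, so 0 and 1 map to the floor odds rather
    than to 0 or infinity.
    """
    p = clamp_probability(p)
    return p / (1.0 - p)


def odds_to_probability(o: float) -> float:
    """Convert odds to a probability ``o / (1 + o)``; inverse of
    :func:`probability_to_odds` on the clamped range."""
    o = float(o)
    if not math.isfinite(o) or o < 0.0:
        raise ValueError(f"odds must be finite and nonnegative, got {o!r}")
    return clamp_probability(o / (1.0 + o))


def _log_odds(p: float) -> float:
    p = clamp_probability(p)
    return math.log(p) - math.log1p(-p)


def _from_log_odds(lo: float) -> float:
    # logistic in a numerically safe split form
    if lo >= 0:
        return clamp_probability(1.0 / (1.0 + math.exp(-lo)))
    e = math.exp(lo)
    return clamp_probability(e / (1.0 + e))


@dataclass(frozen=True)
class BeliefState:
    """Belief that treatment A is superior, as a clamped probability."""

    p_superior_A: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_superior_A", clamp_probability(self.p_superior_A))

    @property
    def odds(self) -> float:
        return probability_to_odds(self.p_superior_A)


@dataclass(frozen=True)
class Evidence:
    """One trial's worth of evidence as an A-over-B likelihood ratio."""

    likelihood_ratio: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        lr = float(self.likelihood_ratio)
        if not math.isfinite(lr) or lr <= 0.0:
            raise ValueError(
                f"likelihood_ratio must be positive and finite, got {lr!r}"
            )
        object.__setattr__(self, "likelihood_ratio", lr)

    @property
    def favors(self) -> str:
        """Which treatment the evidence favours: ``"A"``, ``"B"`` or ``"neither"``."""
        if self.likelihood_ratio > 1.0:
            return "A"
        if self.likelihood_ratio < 1.0:
            return "B"
        return "neither"


@dataclass(frozen=True)
class BiasPolicy:
    """Exponent weights applied to the likelihood ratio by evidence class.

    ``w_confirming`` and ``w_disconfirming`` are exponents in [0, 1];
    ``threshold`` is the belief level at which the favoured treatment flips
    (belief >= threshold favours A).  The default policy is unbiased.
    """

    w_confirming: float = 1.0
    w_disconfirming: float = 1.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("w_confirming", "w_disconfirming"):
            w = float(getattr(self, name))
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {w!r}")
            object.__setattr__(self, name, w)
        t = float(self.threshold)
        if not 0.0 < t < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {t!r}")
        object.__setattr__(self, "threshold", t)

    @classmethod
    def unbiased(cls, threshold: float = 0.5) -> "BiasPolicy":
        return cls(1.0, 1.0, threshold)

    @classmethod
    def confirmation_bias(cls, w_disconfirming: float, threshold: float = 0.5) -> "BiasPolicy":
        """Down-weight disconfirming evidence only (the canonical bias)."""
        return cls(1.0, w_disconfirming, threshold)

    @property
    def is_unbiased(self) -> bool:
        return self.w_confirming == 1.0 and self.w_disconfirming == 1.0

    def weight_for(self, classification: str) -> float:
        if classification == CONFIRMING:
            return self.w_confirming
        if classification == DISCONFIRMING:
            return self.w_disconfirming
        if classification == NEUTRAL:
            # weight is irrelevant for LR = 1; confirming weight by convention
            return self.w_confirming
        raise ValueError(f"unknown classification {classification!r}")


def classify_evidence(belief: float, evidence: Evidence, threshold: float = 0.5) -> str:
    """Classify evidence against the belief held *before* the update.

    The agent favours A when ``belief >= threshold`` (ties favour A) and B
    otherwise.  Evidence is disconfirming iff it favours the non-favoured
    treatment; LR = 1 is neutral.
    """
    belief = clamp_probability(belief)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold!r}")
    lr = evidence.likelihood_ratio
    if lr == 1.0:
        return NEUTRAL
    favored_A = belief >= threshold
    if (favored_A and lr < 1.0) or (not favored_A and lr > 1.0):
        return DISCONFIRMING
    return CONFIRMING


def apply_update(belief: float, evidence: Evidence, weight: float) -> float:
    """One bias-weighted odds-form update, computed in log-odds space.

    Returns ``odds_to_probability(odds(belief) * LR ** weight)`` clamped to
    the working range.
    """
    w = float(weight)
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"weight must lie in [0, 1], got {weight!r}")
    delta = w * math.log(evidence.likelihood_ratio)
    if delta == 0.0:
        # neutral evidence or zero weight: exact identity, no round trip
        return clamp_probability(belief)
    return _from_log_odds(_log_odds(belief) + delta)


@dataclass(frozen=True)
class UpdateRecord:
    """Bookkeeping for one trial: what the agent saw and how it reacted."""

    trial_index: int  # 1-based
    trial_id: str
    likelihood_ratio: float
    pre_belief: float
    classification: str
    weight_applied: float
    post_belief: float


@dataclass(frozen=True)
class Trajectory:
    """An ordered belief path across an evidence stream."""

    initial_belief: float
    records: tuple[UpdateRecord, ...] = field(default_factory=tuple)

    @property
    def final_belief(self) -> float:
        return self.records[-1].post_belief if self.records else self.initial_belief

    @property
    def beliefs(self) -> list[float]:
        """Belief after each trial, prefixed by the initial belief."""
        return [self.initial_belief] + [r.post_belief for r in self.records]

    @property
    def n_trials(self) -> int:
        return len(self.records)

    def classifications(self) -> list[str]:
        return [r.classification for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": [r.trial_index for r in self.records],
                "trial_id": [r.trial_id for r in self.records],
                "likelihood_ratio": [r.likelihood_ratio for r in self.records],
                "classification": [r.classification for r in self.records],
                "weight_applied": [r.weight_applied for r in self.records],
                "pre_belief": [r.pre_belief for r in self.records],
                "post_belief": [r.post_belief for r in self.records],
            }
        )


def run_sequence(
    initial: "BeliefState | float",
    stream: Sequence[Evidence] | Iterable[Evidence],
    policy: BiasPolicy | None = None,
) -> Trajectory:
    """Run the full sequential update over an evidence stream.

    Each trial is classified against the current (pre-update) belief, the
    policy's weight for that class is applied as an exponent on the
    likelihood ratio, and the posterior becomes the next prior.
    """
    if policy is None:
        policy = BiasPolicy.unbiased()
    p = initial.p_superior_A if isinstance(initial, BeliefState) else clamp_probability(initial)
    stream = list(stream)
    if not stream:
        raise ValueError("evidence stream must be non-empty")
    # carry the state in log-odds so an unbiased run is exactly the running
    # sum of log-likelihood-ratios (no per-step probability round trips)
    lo_cap = _log_odds(1.0 - PROB_FLOOR)
    lo = _log_odds(p)
    records: list[UpdateRecord] = []
    for k, ev in enumerate(stream, start=1):
        cls = classify_evidence(p, ev, policy.threshold)
        w = policy.weight_for(cls)
        delta = w * math.log(ev.likelihood_ratio)
        if delta == 0.0:
            post = p  # ignored or neutral evidence changes nothing, exactly
        else:
            lo = min(max(lo + delta, -lo_cap), lo_cap)
            post = _from_log_odds(lo)
        records.append(
            UpdateRecord(
                trial_index=k,
                trial_id=ev.trial_id or str(k),
                likelihood_ratio=ev.likelihood_ratio,
                pre_belief=p,
                classification=cls,
                weight_applied=w,
                post_belief=post,
            )
        )
        p = post
    return Trajectory(initial_belief=records[0].pre_belief, records=tuple(records))
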