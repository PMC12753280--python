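"""Evidence-stream generators.

Three modes are supported:

* ``fixed`` — ``n`` trials with one constant likelihood ratio, the canonical
  constant-effect experiment;
* ``mixed`` — a shuffled stream with a stated number of A-favouring trials at
  LR = m and B-favouring trials at the reciprocal 1/m, so evidence strength is
  symmetric by construction;
* ``binomial`` — a generative mode in which each trial is a two-arm binomial
  experiment under point hypotheses HA ("A superior") and HB ("B superior"),
  and the likelihood ratio is computed from the simulated arm counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import binom

from .core import Evidence

__all__ = [
    "TrialDesign",
    "TrialOutcome",
    "StreamSpec",
    "make_fixed_stream",
    "make_mixed_stream",
    "simulate_trial",
    "trial_likelihood_ratio",
    "simulate_binomial_stream",
]


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm binomial trial under two point hypotheses.

    Success probabilities are given for each arm under each hypothesis:
    under HA treatment A is truly superior, under HB treatment B is.
    """

    n_per_arm: int
    p_success_A_under_HA: float
    p_success_B_under_HA: float
    p_success_A_under_HB: float
    p_success_B_under_HB: float

    def __post_init__(self) -> None:
        if int(self.n_per_arm) < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm!r}")
        object.__setattr__(self, "n_per_arm", int(self.n_per_arm))
        for name in (
            "p_success_A_under_HA",
            "p_success_B_under_HA",
            "p_success_A_under_HB",
            "p_success_B_under_HB",
        ):
            p = float(getattr(self, name))
            # [0, 1] inclusive: degenerate rates are legal for the generative
            # step (they just force the count), only the LR step can reject.
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
            object.__setattr__(self, name, p)

    def rates_under(self, hypothesis: str) -> tuple[float, float]:
        if hypothesis == "HA":
            return self.p_success_A_under_HA, self.p_success_B_under_HA
        if hypothesis == "HB":
            return self.p_success_A_under_HB, self.p_success_B_under_HB
        raise ValueError(f"hypothesis must be 'HA' or 'HB', got {hypothesis!r}")


@dataclass(frozen=True)
class TrialOutcome:
    """Observed success counts in each arm of one trial."""

    successes_A_arm: int
    successes_B_arm: int


def make_fixed_stream(n: int, lr: float) -> list[Evidence]:
    """``n`` evidence items all carrying the same likelihood ratio."""
    if n < 1:
        raise ValueError(f"stream length must be >= 1, got {n!r}")
    return [Evidence(likelihood_ratio=lr, trial_id=str(k)) for k in range(1, n + 1)]


def make_mixed_stream(
    n_favoring_A: int,
    n_favoring_B: int,
    lr_magnitude: float,
    order_seed: int = 0,
) -> list[Evidence]:
    """A shuffled stream of reciprocal-strength evidence in both directions.

    A-favouring items carry LR = max(m, 1/m) > 1 and B-favouring items its
    reciprocal, so log-likelihood-ratios cancel pairwise.  The order is a
    deterministic shuffle under ``order_seed``.
    """
    if n_favoring_A < 0 or n_favoring_B < 0:
        raise ValueError("counts must be nonnegative")
    if n_favoring_A + n_favoring_B == 0:
        raise ValueError("at least one trial is required")
    m = float(lr_magnitude)
    if not math.isfinite(m) or m <= 0.0:
        raise ValueError(f"lr_magnitude must be positive and finite, got {lr_magnitude!r}")
    lr_A = max(m, 1.0 / m)
    lrs = [lr_A] * n_favoring_A + [1.0 / lr_A] * n_favoring_B
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(lrs))
    return [
        Evidence(likelihood_ratio=lrs[i], trial_id=str(k))
        for k, i in enumerate(order, start=1)
    ]


def simulate_trial(
    design: TrialDesign,
    true_hypothesis: Literal["HA", "HB"],
    rng: np.random.Generator,
) -> TrialOutcome:
    """Draw one trial's arm counts under the true hypothesis."""
    p_A, p_B = design.rates_under(true_hypothesis)
    return TrialOutcome(
        successes_A_arm=int(rng.binomial(design.n_per_arm, p_A)),
        successes_B_arm=int(rng.binomial(design.n_per_arm, p_B)),
    )


def trial_likelihood_ratio(design: TrialDesign, outcome: TrialOutcome) -> Evidence:
    """Likelihood ratio of one trial's joint arm counts, computed in log space.

    LR = [Bin(kA; n, pA|HA) Bin(kB; n, pB|HA)] / [Bin(kA; n, pA|HB) Bin(kB; n, pB|HB)]
    """
    n = design.n_per_arm
    for k in (outcome.successes_A_arm, outcome.successes_B_arm):
        if not 0 <= k <= n:
            raise ValueError(f"success count {k} outside [0, {n}]")
    log_num = binom.logpmf(outcome.successes_A_arm, n, design.p_success_A_under_HA) + binom.logpmf(
        outcome.successes_B_arm, n, design.p_success_B_under_HA
    )
    log_den = binom.logpmf(outcome.successes_A_arm, n, design.p_success_A_under_HB) + binom.logpmf(
        outcome.successes_B_arm, n, design.p_success_B_under_HB
    )
    if not np.isfinite(log_den):
        raise ValueError(
            f"outcome {outcome} has zero probability under HB; likelihood ratio undefined"
        )
    if not np.isfinite(log_num):
        raise ValueError(
            f"outcome {outcome} has zero probability under HA; likelihood ratio undefined"
        )
    return Evidence(likelihood_ratio=float(np.exp(log_num - log_den)))


def simulate_binomial_stream(
    design: TrialDesign,
    n_trials: int,
    true_hypothesis: Literal["HA", "HB"],
    seed: int,
) -> list[Evidence]:
    """Simulate ``n_trials`` independent trials and convert each to Evidence."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials!r}")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(1, n_trials + 1):
        ev = trial_likelihood_ratio(design, simulate_trial(design, true_hypothesis, rng))
        out.append(Evidence(likelihood_ratio=ev.likelihood_ratio, trial_id=str(k)))
    return out


@dataclass(frozen=True)
class StreamSpec:
    """Declarative description of an evidence stream.

    ``mode`` selects the generator: ``fixed`` needs ``lr``; ``mixed`` needs
    ``lr`` (the magnitude) and the two direction counts; ``binomial`` needs a
    :class:`TrialDesign` plus the true hypothesis.  ``seed`` drives any
    randomness (shuffle order, binomial draws) reproducibly.
    """

    n_trials: int
    mode: Literal["fixed", "mixed", "binomial"] = "fixed"
    lr: float | None = None
    n_favoring_A: int | None = None
    n_favoring_B: int | None = None
    design: TrialDesign | None = None
    true_hypothesis: Literal["HA", "HB"] = "HB"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials!r}")
        if self.mode == "fixed":
            if self.lr is None:
                raise ValueError("fixed mode requires lr")
        elif self.mode == "mixed":
            if self.lr is None:
                raise ValueError("mixed mode requires lr (the magnitude)")
            if self.n_favoring_A is None or self.n_favoring_B is None:
                raise ValueError("mixed mode requires n_favoring_A and n_favoring_B")
            if self.n_favoring_A + self.n_favoring_B != self.n_trials:
                raise ValueError(
                    "n_favoring_A + n_favoring_B must equal n_trials "
                    f"({self.n_favoring_A} + {self.n_favoring_B} != {self.n_trials})"
                )
        elif self.mode == "binomial":
            if self.design is None:
                raise ValueError("binomial mode requires a TrialDesign")
        else:
            raise ValueError(f"unknown stream mode {self.mode!r}")

    def build(self) -> list[Evidence]:
        if self.mode == "fixed":
            return make_fixed_stream(self.n_trials, self.lr)
        if self.mode == "mixed":
            return make_mixed_stream(self.n_favoring_A, self.n_favoring_B, self.lr, self.seed)
        return simulate_binomial_stream(self.design, self.n_trials, self.true_hypothesis, self.seed)
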