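"""Inverse problems for the constant-effect updating model.

Given a (prior, final, number of trials) triple from an unbiased run with a
constant per-trial likelihood ratio, the update rule inverts in closed form:

    LR = (odds(final) / odds(prior)) ** (1 / n)

Given a biased endpoint, the bias exponent ``w`` is recovered by bisection on
forward simulations, since for an all-disconfirming stream the final belief
is monotone in ``w``.  A consistency diagnostic checks whether a set of
published endpoints can be explained by one shared likelihood ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import (
    BiasPolicy,
    clamp_probability,
    probability_to_odds,
    run_sequence,
)
from .evidence import make_fixed_stream

__all__ = [
    "CalibrationResult",
    "ConsistencyReport",
    "calibrate_constant_lr",
    "solve_bias_factor",
    "implied_lr_report",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Constant per-trial likelihood ratio implied by an endpoint pair."""

    implied_lr: float
    prior: float
    final: float
    n_trials: int
    name: str = ""


@dataclass(frozen=True)
class ConsistencyReport:
    """Whether several endpoints share one constant likelihood ratio."""

    results: tuple[CalibrationResult, ...]
    max_pairwise_lr_discrepancy: float
    tolerance: float
    consistent_flag: bool


def calibrate_constant_lr(
    prior: float, final: float, n_trials: int, name: str = ""
) -> CalibrationResult:
    """Closed-form inverse: the constant LR taking ``prior`` to ``final``
    in ``n_trials`` unbiased updates."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials!r}")
    prior = clamp_probability(prior)
    final = clamp_probability(final)
    log_lr = (
        math.log(probability_to_odds(final)) - math.log(probability_to_odds(prior))
    ) / n_trials
    return CalibrationResult(
        implied_lr=math.exp(log_lr), prior=prior, final=final, n_trials=int(n_trials), name=name
    )


def solve_bias_factor(
    prior: float,
    lr: float,
    n_trials: int,
    observed_biased_final: float,
    threshold: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Recover the disconfirming-evidence exponent ``w`` from an endpoint.

    Bisects on ``w`` in [0, 1]; every iterate is evaluated by a full forward
    simulation (with threshold-dependent classification), so trajectories
    that cross the threshold are handled exactly rather than by a closed
    form.  Raises with the attainable final-belief range when the observed
    endpoint cannot be produced by any ``w`` in [0, 1].
    """
    stream = make_fixed_stream(n_trials, lr)
    target = clamp_probability(observed_biased_final)

    def final_at(w: float) -> float:
        policy = BiasPolicy(w_confirming=1.0, w_disconfirming=w, threshold=threshold)
        return run_sequence(prior, stream, policy).final_belief

    lo_w, hi_w = 0.0, 1.0
    f_lo, f_hi = final_at(lo_w), final_at(hi_w)
    low, high = min(f_lo, f_hi), max(f_lo, f_hi)
    if not low - tol <= target <= high + tol:
        raise ValueError(
            f"observed final {target:.6g} is outside the attainable range "
            f"[{low:.6g}, {high:.6g}] spanned by w in [0, 1]"
        )
    if abs(f_lo - target) <= tol and abs(f_lo - target) <= abs(f_hi - target):
        return lo_w
    if abs(f_hi - target) <= tol:
        return hi_w
    increasing = f_hi > f_lo  # final belief as a function of w
    for _ in range(max_iter):
        mid = 0.5 * (lo_w + hi_w)
        if hi_w - lo_w < 1e-13:
            break
        f_mid = final_at(mid)
        if (f_mid < target) == increasing:
            lo_w = mid
        else:
            hi_w = mid
    return 0.5 * (lo_w + hi_w)


def implied_lr_report(
    endpoint_table: list[tuple[str, float, float, int]],
    tolerance: float = 0.01,
) -> ConsistencyReport:
    """Calibrate each (name, prior, final, n) row and compare implied LRs.

    ``consistent_flag`` is true iff the largest pairwise spread of implied
    likelihood ratios is within ``tolerance`` — i.e. a single constant LR
    explains every row.
    """
    if not endpoint_table:
        raise ValueError("endpoint table must be non-empty")
    results = tuple(
        calibrate_constant_lr(prior, final, n, name=name)
        for name, prior, final, n in endpoint_table
    )
    lrs = [r.implied_lr for r in results]
    spread = max(lrs) - min(lrs)
    return ConsistencyReport(
        results=results,
        max_pairwise_lr_discrepancy=spread,
        tolerance=tolerance,
        consistent_flag=spread <= tolerance,
    )
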