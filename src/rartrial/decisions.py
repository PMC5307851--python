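"""Interim calendar, success gate, and stopping rules.

The design begins interim analyses once every arm has enrolled its burn-in
quota (150 subjects by default) and repeats them every 13 weeks.  From 800
total enrollments onward an interim may stop the trial for success when the
posterior probability that some arm is best exceeds 0.995; enrollment
otherwise continues to a hard cap (1355 enrollments, chosen so that ~1200
subjects complete after an expected 11% dropout).  A final analysis after
all births applies the same evidence bar; crossing it there is "late"
success.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError

__all__ = [
    "DesignSpec",
    "InterimDecision",
    "FinalDecision",
    "interim_decision",
    "final_decision",
    "interim_calendar",
    "CONTINUE",
    "STOP_EARLY_SUCCESS",
    "STOP_ENROLLMENT_CAP",
]

CONTINUE = "continue"
STOP_EARLY_SUCCESS = "stop_early_success"
STOP_ENROLLMENT_CAP = "stop_enrollment_cap"


@dataclass(frozen=True)
class DesignSpec:
    """Design parameters of the adaptive trial.

    burn_in_per_arm        equal-allocation phase: first interim once every
                           arm has this many enrollments (default 150)
    interim_interval_weeks cadence of subsequent interims (default 13)
    success_gate_enrolled  earliest total enrollment at which an interim may
                           stop for success (default 800)
    success_threshold      interim evidence bar on max prob_best (default 0.995)
    max_enrolled           enrollment cap (default 1355)
    max_completers         expected outcome-complete subjects at the cap,
                           n_max (default 1200)
    final_threshold        evidence bar at the final analysis (default 0.995)
    """

    burn_in_per_arm: int = 150
    interim_interval_weeks: float = 13.0
    success_gate_enrolled: int = 800
    success_threshold: float = 0.995
    max_enrolled: int = 1355
    max_completers: int = 1200
    final_threshold: float = 0.995

    def __post_init__(self) -> None:
        for name in ("success_threshold", "final_threshold"):
            v = getattr(self, name)
            if not 0.5 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0.5, 1], got {v}")
        if self.interim_interval_weeks <= 0:
            raise ConfigError("interim_interval_weeks must be positive")
        if self.max_completers > self.max_enrolled:
            raise ConfigError("max_completers cannot exceed max_enrolled")
        if self.success_gate_enrolled > self.max_enrolled:
            raise ConfigError("success gate cannot exceed the enrollment cap")

    def validate(self, n_arms: int) -> None:
        if self.burn_in_per_arm * n_arms > self.success_gate_enrolled:
            raise ConfigError(
                f"burn-in of {self.burn_in_per_arm}/arm over {n_arms} arms "
                f"exceeds the {self.success_gate_enrolled}-subject success gate"
            )


@dataclass(frozen=True)
class InterimDecision:
    interim_id: int
    prob_best: np.ndarray
    total_enrolled: int
    action: str
    winning_arm: int | None  # arm index, set only on early success


@dataclass(frozen=True)
class FinalDecision:
    success: bool
    winning_arm: int | None
    prob_best: np.ndarray


def _check_prob_best(prob_best) -> np.ndarray:
    pb = np.asarray(prob_best, dtype=float)
    if pb.ndim != 1 or pb.size < 2 or np.any(pb < 0) or abs(pb.sum() - 1.0) > 1e-6:
        raise ValueError("prob_best must be a 1-D probability vector summing to 1")
    return pb


def interim_decision(
    prob_best,
    total_enrolled: int,
    design: DesignSpec,
    interim_id: int = 0,
) -> InterimDecision:
    """Apply the interim stopping logic to one analysis.

    Stop for success only when the best arm's posterior probability exceeds
    the threshold *and* the success gate (total enrollments) has been
    reached; at or beyond the enrollment cap the action is the cap stop
    regardless of the evidence (success can then only be declared at the
    final analysis).
    """
    pb = _check_prob_best(prob_best)
    if total_enrolled >= design.max_enrolled:
        action, winner = STOP_ENROLLMENT_CAP, None
    elif (
        total_enrolled >= design.success_gate_enrolled
        and float(pb.max()) > design.success_threshold
    ):
        action, winner = STOP_EARLY_SUCCESS, int(pb.argmax())
    else:
        action, winner = CONTINUE, None
    return InterimDecision(
        interim_id=interim_id,
        prob_best=pb,
        total_enrolled=total_enrolled,
        action=action,
        winning_arm=winner,
    )


def final_decision(prob_best, design: DesignSpec) -> FinalDecision:
    """Success call at the final analysis, once all outcomes are observed."""
    pb = _check_prob_best(prob_best)
    if float(pb.max()) > design.final_threshold:
        return FinalDecision(success=True, winning_arm=int(pb.argmax()), prob_best=pb)
    return FinalDecision(success=False, winning_arm=None, prob_best=pb)


def interim_calendar(
    enroll_times_by_arm: Sequence[Sequence[float]],
    design: DesignSpec,
    horizon_weeks: float,
) -> np.ndarray:
    """Scheduled interim times implied by an enrollment stream.

    The first interim falls at the earliest time every arm has reached its
    burn-in quota; later interims follow at the fixed cadence up to
    ``horizon_weeks`` (a stopped trial simply truncates the calendar).
    Returns an empty array when burn-in is never completed.
    """
    firsts = []
    for times in enroll_times_by_arm:
        t = np.asarray(times, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("enrollment times must be nondecreasing")
        if t.size < design.burn_in_per_arm:
            return np.array([])
        firsts.append(t[design.burn_in_per_arm - 1])
    t0 = max(firsts)
    if t0 > horizon_weeks:
        return np.array([])
    return np.arange(t0, horizon_weeks + 1e-9, design.interim_interval_weeks)
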