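"""Virtual-trial simulation and operating characteristics.

A simulated trial draws a Poisson enrollment stream, assigns each subject
to an arm by the current allocation weights, and gives each pregnancy a
gestational age at entry, a delivery gestational age (early preterm birth
defined as delivery before 34 weeks), and a dropout indicator.  Outcomes
accrue with a realistic lag — a subject's birth enters the interim data
only once her delivery date has passed — so interim posteriors always run
behind enrollment.

The engine plays the full adaptive design against this stream: equal
allocation until every arm reaches its burn-in quota, interims every 13
weeks updating the allocation weights from the posterior, an early-success
stop once the evidence bar is crossed after the enrollment gate, a hard
enrollment cap, and a final intent-to-treat analysis of all births.
Operating characteristics (power, Type I error, expected sample size and
duration, allocation split) are Monte-Carlo aggregates over replicate
trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtri
from scipy.stats import norm

from .allocation import allocation_weights, burn_in_weights
from .decisions import (
    CONTINUE,
    STOP_EARLY_SUCCESS,
    DesignSpec,
    final_decision,
    interim_decision,
)
from .exceptions import ConfigError
from .posterior import ArmCounts, GridSpec, PriorSpec, posterior_quadrature, prob_best

__all__ = [
    "DeliveryModel",
    "Scenario",
    "SubjectRecord",
    "InterimRecord",
    "TrialResult",
    "OperatingCharacteristics",
    "simulate_subject",
    "run_trial",
    "run_oc",
    "scenario_presets",
    "EPTB_CUTOFF_WEEKS",
]

EPTB_CUTOFF_WEEKS = 34.0  # early preterm birth: delivery before 34 weeks gestation


@dataclass(frozen=True)
class DeliveryModel:
    """Delivery gestational age conditional on early-preterm status.

    Early preterm deliveries are uniform on [26, 34) weeks; all others
    follow a normal distribution (mean 39.2, sd 1.6 weeks) truncated to
    [34, 42].  Only the <34-week indicator feeds the statistics, so the
    operating characteristics are sensitive to this model only through the
    enrollment-to-outcome lag it implies.
    """

    term_mean: float = 39.2
    term_sd: float = 1.6
    term_lo: float = 34.0
    term_hi: float = 42.0
    eptb_lo: float = 26.0
    eptb_hi: float = 34.0


@dataclass(frozen=True)
class Scenario:
    """Truth model for one set of virtual trials."""

    name: str
    true_rates: tuple[float, ...]  # per-arm true ePTB probability
    enroll_rate_per_week: float = 6.5
    ga_entry_lo: float = 12.0
    ga_entry_hi: float = 20.0
    delivery: DeliveryModel = field(default_factory=DeliveryModel)
    dropout_prob: float = 0.11
    arm_labels: tuple[str, ...] = ("group1", "group2")

    def __post_init__(self) -> None:
        if len(self.true_rates) != len(self.arm_labels):
            raise ConfigError("true_rates and arm_labels must have equal length")
        if any(not 0.0 <= r <= 1.0 for r in self.true_rates):
            raise ConfigError("true ePTB rates must be probabilities")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if self.enroll_rate_per_week <= 0:
            raise ConfigError("enroll_rate_per_week must be positive")


@dataclass(frozen=True)
class SubjectRecord:
    id: int
    site: str
    enroll_time_weeks: float
    arm: int
    ga_at_entry_weeks: float
    dropout: bool
    delivery_time_weeks: float  # absolute calendar time of delivery
    eptb: bool


@dataclass(frozen=True)
class InterimRecord:
    interim_id: int
    time_weeks: float
    enrolled_per_arm: tuple[int, ...]
    births_per_arm: tuple[int, ...]
    events_per_arm: tuple[int, ...]
    prob_best: tuple[float, ...]
    weights: tuple[float, ...]
    action: str


@dataclass(frozen=True)
class TrialResult:
    scenario: str
    seed: object
    n_enrolled: int
    n_enrolled_per_arm: tuple[int, ...]
    n_completers: int
    n_completers_per_arm: tuple[int, ...]
    n_dropouts: int
    stop_type: str  # "early_success" | "late_success" | "no_success"
    winning_arm: int | None
    duration_weeks: float
    final_prob_best: tuple[float, ...]
    interims: tuple[InterimRecord, ...]


def simulate_subject(
    arm: int,
    scenario: Scenario,
    rng: np.random.Generator,
    subject_id: int = 0,
    site: str = "site1",
    enroll_time: float = 0.0,
) -> SubjectRecord:
    """Draw one subject's entry, outcome, and dropout status.

    The early-preterm indicator is Bernoulli with the arm's true rate;
    delivery gestational age is then drawn from the delivery model
    conditional on that indicator, and delivery calendar time is the
    enrollment time plus the remaining gestation.  Dropout is decided at
    enrollment; dropouts never contribute an outcome but still occupy an
    enrollment slot.
    """
    dm = scenario.delivery
    ga_entry = rng.uniform(scenario.ga_entry_lo, scenario.ga_entry_hi)
    eptb = rng.random() < scenario.true_rates[arm]
    if eptb:
        ga_delivery = rng.uniform(dm.eptb_lo, dm.eptb_hi)
    else:
        lo = norm.cdf(dm.term_lo, dm.term_mean, dm.term_sd)
        hi = norm.cdf(dm.term_hi, dm.term_mean, dm.term_sd)
        ga_delivery = dm.term_mean + dm.term_sd * float(ndtri(rng.uniform(lo, hi)))
    dropout = rng.random() < scenario.dropout_prob
    return SubjectRecord(
        id=subject_id,
        site=site,
        enroll_time_weeks=enroll_time,
        arm=arm,
        ga_at_entry_weeks=ga_entry,
        dropout=dropout,
        delivery_time_weeks=enroll_time + (ga_delivery - ga_entry),
        eptb=eptb,
    )


def _interim_counts(
    subjects: list[SubjectRecord], k: int, time_weeks: float
) -> tuple[np.ndarray, np.ndarray]:
    births = np.zeros(k, dtype=int)
    events = np.zeros(k, dtype=int)
    for s in subjects:
        if not s.dropout and s.delivery_time_weeks <= time_weeks:
            births[s.arm] += 1
            events[s.arm] += int(s.eptb)
    return births, events


def run_trial(
    scenario: Scenario,
    design: DesignSpec = DesignSpec(),
    seed: int | np.random.SeedSequence | None = None,
    prior: PriorSpec = PriorSpec(),
    grid: GridSpec = GridSpec(hi=4.0),
) -> TrialResult:
    """Simulate one complete virtual trial.

    Orchestrates the whole design: Poisson accrual, Bernoulli arm
    assignment at the current weights (equal during burn-in), interims at
    the 13-week cadence computed on births delivered by the interim date,
    allocation-weight updates, the gated early-success stop, the enrollment
    cap, follow-up of every enrolled pregnancy to delivery, and the final
    intent-to-treat analysis.  Identical seeds reproduce the trial exactly.
    """
    k = len(scenario.true_rates)
    design.validate(k)
    rng = np.random.default_rng(seed)

    subjects: list[SubjectRecord] = []
    n_arm = np.zeros(k, dtype=int)
    weights = burn_in_weights(k).normalized
    cum_weights = np.cumsum(weights)
    next_interim: float | None = None
    interim_id = 0
    interims: list[InterimRecord] = []
    stopped_early = False
    early_winner: int | None = None
    early_prob_best: np.ndarray | None = None
    t = 0.0

    def do_interim(time_weeks: float) -> str:
        nonlocal interim_id, weights, cum_weights, early_winner, early_prob_best
        interim_id += 1
        births, events = _interim_counts(subjects, k, time_weeks)
        counts = [
            ArmCounts(scenario.arm_labels[j], int(births[j]), int(events[j]))
            for j in range(k)
        ]
        posts = [posterior_quadrature(c, prior, grid) for c in counts]
        pb = prob_best(posts)
        decision = interim_decision(pb, len(subjects), design, interim_id=interim_id)
        if decision.action == CONTINUE:
            w = allocation_weights(
                pb,
                np.array([p.variance for p in posts]),
                n_arm.astype(float),
                interim_id=interim_id,
            )
            weights = w.normalized
            cum_weights = np.cumsum(weights)
        elif decision.action == STOP_EARLY_SUCCESS:
            early_winner = decision.winning_arm
            early_prob_best = pb
        interims.append(
            InterimRecord(
                interim_id=interim_id,
                time_weeks=time_weeks,
                enrolled_per_arm=tuple(int(v) for v in n_arm),
                births_per_arm=tuple(int(v) for v in births),
                events_per_arm=tuple(int(v) for v in events),
                prob_best=tuple(float(v) for v in pb),
                weights=tuple(float(v) for v in weights),
                action=decision.action,
            )
        )
        return decision.action

    while len(subjects) < design.max_enrolled:
        t_next = t if not subjects else t + rng.exponential(1.0 / scenario.enroll_rate_per_week)
        # interims scheduled before the next enrollment
        while next_interim is not None and next_interim <= t_next:
            action = do_interim(next_interim)
            next_interim += design.interim_interval_weeks
            if action == STOP_EARLY_SUCCESS:
                stopped_early = True
                break
        if stopped_early:
            break
        arm = int(np.searchsorted(cum_weights, rng.random(), side="right"))
        subjects.append(
            simulate_subject(
                arm, scenario, rng, subject_id=len(subjects) + 1, enroll_time=t_next
            )
        )
        n_arm[arm] += 1
        t = t_next
        if next_interim is None and int(n_arm.min()) >= design.burn_in_per_arm:
            # first interim at the moment burn-in completes
            action = do_interim(t)
            next_interim = t + design.interim_interval_weeks
            if action == STOP_EARLY_SUCCESS:  # impossible before the gate, but total
                stopped_early = True
                break

    completers = [s for s in subjects if not s.dropout]
    last_event = max(
        (s.delivery_time_weeks for s in completers),
        default=max((s.enroll_time_weeks for s in subjects), default=0.0),
    )
    duration = max(last_event, interims[-1].time_weeks if interims else 0.0)

    n_comp_arm = np.zeros(k, dtype=int)
    for s in completers:
        n_comp_arm[s.arm] += 1

    if stopped_early:
        stop_type = "early_success"
        winner = early_winner
        final_pb = early_prob_best
    else:
        births, events = _interim_counts(subjects, k, np.inf)
        counts = [
            ArmCounts(scenario.arm_labels[j], int(births[j]), int(events[j]))
            for j in range(k)
        ]
        posts = [posterior_quadrature(c, prior, grid) for c in counts]
        final_pb = prob_best(posts)
        fd = final_decision(final_pb, design)
        stop_type = "late_success" if fd.success else "no_success"
        winner = fd.winning_arm

    return TrialResult(
        scenario=scenario.name,
        seed=seed,
        n_enrolled=len(subjects),
        n_enrolled_per_arm=tuple(int(v) for v in n_arm),
        n_completers=len(completers),
        n_completers_per_arm=tuple(int(v) for v in n_comp_arm),
        n_dropouts=len(subjects) - len(completers),
        stop_type=stop_type,
        winning_arm=winner,
        duration_weeks=float(duration),
        final_prob_best=tuple(float(v) for v in final_pb),
        interims=tuple(interims),
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo aggregates over replicate virtual trials.

    Percentages carry binomial Monte-Carlo standard errors; means carry the
    standard error of the mean.  ``mean_subjects`` counts outcome-complete
    subjects (analyzable births), the scale on which the design's expected
    sample size is quoted; ``mean_enrolled`` counts randomized subjects
    including dropouts.
    """

    scenario: str
    n_reps: int
    pct_finish_early: float
    pct_finish_late: float
    power: float
    mean_subjects: float
    mean_enrolled: float
    mean_duration_weeks: float
    alloc_pct: tuple[float, ...]  # mean % of enrolled subjects per arm
    se_finish_early: float
    se_finish_late: float
    se_power: float
    se_mean_subjects: float
    se_mean_duration: float
    se_alloc_pct: tuple[float, ...]
    arm_labels: tuple[str, ...]

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "finish_early_pct": self.pct_finish_early,
            "finish_late_pct": self.pct_finish_late,
            "power_pct": self.power,
            "mean_subjects": self.mean_subjects,
            "mean_trial_weeks": self.mean_duration_weeks,
        }
        for label, pct, se in zip(self.arm_labels, self.alloc_pct, self.se_alloc_pct):
            row[f"alloc_pct_{label}"] = pct
            row[f"alloc_pct_{label}_se"] = se
        row.update(
            {
                "finish_early_pct_se": self.se_finish_early,
                "finish_late_pct_se": self.se_finish_late,
                "power_pct_se": self.se_power,
                "mean_subjects_se": self.se_mean_subjects,
                "mean_trial_weeks_se": self.se_mean_duration,
                "n_reps": self.n_reps,
            }
        )
        return row


def _pct_and_se(flags: np.ndarray) -> tuple[float, float]:
    p = float(flags.mean())
    se = float(np.sqrt(p * (1.0 - p) / flags.size))
    return 100.0 * p, 100.0 * se


def _mean_and_se(x: np.ndarray) -> tuple[float, float]:
    if x.size > 1:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))
    return float(x.mean()), 0.0


def run_oc(
    scenario: Scenario,
    design: DesignSpec = DesignSpec(),
    n_reps: int = 100,
    master_seed: int = 0,
    prior: PriorSpec = PriorSpec(),
) -> OperatingCharacteristics:
    """Simulate ``n_reps`` trials and aggregate their operating characteristics.

    Per-replicate random streams are spawned from the master seed by
    counter, so results are reproducible and replicates are independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    results = [
        run_trial(scenario, design, seed=np.random.SeedSequence((master_seed, rep)), prior=prior)
        for rep in range(n_reps)
    ]
    return summarize(results, scenario)


def summarize(results: Sequence[TrialResult], scenario: Scenario) -> OperatingCharacteristics:
    """Aggregate already-simulated trial results into operating characteristics."""
    early = np.array([r.stop_type == "early_success" for r in results])
    late = np.array([r.stop_type == "late_success" for r in results])
    subjects = np.array([r.n_completers for r in results], dtype=float)
    enrolled = np.array([r.n_enrolled for r in results], dtype=float)
    duration = np.array([r.duration_weeks for r in results], dtype=float)
    alloc = np.array(
        [np.asarray(r.n_enrolled_per_arm) / r.n_enrolled for r in results], dtype=float
    )

    pe, se_pe = _pct_and_se(early)
    pl, se_pl = _pct_and_se(late)
    pw, se_pw = _pct_and_se(early | late)
    ms, se_ms = _mean_and_se(subjects)
    me, _ = _mean_and_se(enrolled)
    md, se_md = _mean_and_se(duration)
    alloc_mean = 100.0 * alloc.mean(axis=0)
    alloc_se = (
        100.0 * alloc.std(axis=0, ddof=1) / np.sqrt(len(results))
        if len(results) > 1
        else np.zeros(alloc.shape[1])
    )
    return OperatingCharacteristics(
        scenario=scenario.name,
        n_reps=len(results),
        pct_finish_early=pe,
        pct_finish_late=pl,
        power=pw,
        mean_subjects=ms,
        mean_enrolled=me,
        mean_duration_weeks=md,
        alloc_pct=tuple(alloc_mean),
        se_finish_early=se_pe,
        se_finish_late=se_pl,
        se_power=se_pw,
        se_mean_subjects=se_ms,
        se_mean_duration=se_md,
        se_alloc_pct=tuple(alloc_se),
        arm_labels=scenario.arm_labels,
    )


_PRESET_RATES = {
    "#1": ("very likely (4 vs 1%)", (0.04, 0.01)),
    "#2": ("likely (3 vs 0.5%)", (0.03, 0.005)),
    "#3": ("unlikely (3 vs 1%)", (0.03, 0.01)),
    "#4": ("very unlikely (3 vs 2%)", (0.03, 0.02)),
    "#5": ("no difference (3 vs 3%)", (0.03, 0.03)),
}


def scenario_presets(**overrides) -> dict[str, Scenario]:
    """The five canonical truth scenarios for the operating-characteristics study.

    Group 1 is the control arm (higher or equal ePTB rate), group 2 the
    treated arm.  Keyword overrides apply to every preset (e.g. a different
    enrollment rate).
    """
    presets = {}
    for key, (desc, rates) in _PRESET_RATES.items():
        presets[key] = Scenario(name=f"{key} {desc}", true_rates=rates, **overrides)
    return presets
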