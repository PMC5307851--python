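"""Response-adaptive allocation weights and permuted-block schedules.

Between interim analyses, new subjects are allocated to arm ``j`` with
probability proportional to

    V_j = [ P(arm j is best) * Var(theta_j) / (n_j + 1) ] ** (1/4)

which sends more subjects to the most promising arm while the fourth root
dampens extreme ratios and the ``Var/(n_j + 1)`` factor keeps information
flowing to under-observed arms.  During burn-in (before the first interim)
allocation is equal across arms.

For trial conduct the normalized weights are materialized as blinded
per-site permuted-block randomization schedules; each site's schedule is
reproducible from a master seed plus the site label.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import BlockRoundingError, DegenerateAllocationError

__all__ = [
    "AllocationWeights",
    "RandomizationSchedule",
    "allocation_weights",
    "burn_in_weights",
    "make_schedule",
    "site_seed",
]


@dataclass(frozen=True)
class AllocationWeights:
    """Raw V_j values and their normalization, with an audit trail of inputs."""

    raw: np.ndarray
    normalized: np.ndarray
    interim_id: int = 0
    inputs_digest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.raw < 0):
            raise ValueError("raw allocation weights must be nonnegative")
        if abs(float(self.normalized.sum()) - 1.0) > 1e-12:
            raise ValueError("normalized allocation weights must sum to 1")


def allocation_weights(
    prob_best,
    post_var,
    n,
    interim_id: int = 0,
) -> AllocationWeights:
    """Information-weighted allocation from the current posterior state.

    Parameters are per-arm arrays: the probability-best vector, the
    posterior variance of each arm's ePTB rate, and the current per-arm
    enrollment ``n_j``.
    """
    pb = np.asarray(prob_best, dtype=float)
    var = np.asarray(post_var, dtype=float)
    n = np.asarray(n, dtype=float)
    if not (pb.shape == var.shape == n.shape) or pb.ndim != 1 or pb.size < 2:
        raise ValueError("prob_best, post_var and n must be 1-D arrays of equal length >= 2")
    if np.any(n < 0):
        raise ValueError("enrollment counts must be nonnegative")
    if np.any(var <= 0):
        raise ValueError("posterior variances must be positive")
    raw = (pb * var / (n + 1.0)) ** 0.25
    total = raw.sum()
    if total == 0.0:
        raise DegenerateAllocationError("all raw allocation weights are zero")
    return AllocationWeights(
        raw=raw,
        normalized=raw / total,
        interim_id=interim_id,
        inputs_digest={
            "prob_best": pb.tolist(),
            "post_var": var.tolist(),
            "n": n.tolist(),
        },
    )


def burn_in_weights(n_arms: int) -> AllocationWeights:
    """Equal allocation used until the first interim analysis."""
    if n_arms < 2:
        raise ValueError(f"need at least 2 arms, got {n_arms}")
    w = np.full(n_arms, 1.0 / n_arms)
    return AllocationWeights(raw=w.copy(), normalized=w, interim_id=0,
                             inputs_digest={"burn_in": True})


def site_seed(master_seed: int, site_id: str) -> int:
    """Stable per-site seed derived from a master seed and the site label."""
    return (int(master_seed) + zlib.crc32(site_id.encode("utf-8"))) % (2**31)


@dataclass(frozen=True)
class RandomizationSchedule:
    """An ordered blinded assignment list for one site."""

    site_id: str
    entries: tuple[tuple[int, str], ...]  # (sequence number, arm label)
    block_size: int
    seed: int

    def arm_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for _, arm in self.entries:
            totals[arm] = totals.get(arm, 0) + 1
        return totals


def make_schedule(
    weights: AllocationWeights,
    n_entries: int,
    block_size: int,
    site_id: str,
    seed: int,
    arm_labels=None,
) -> RandomizationSchedule:
    """Permuted-block schedule realizing the allocation weights.

    Each block contains ``round(weight * block_size)`` slots per arm in a
    random order.  ``n_entries`` must be a multiple of ``block_size`` and
    the rounded per-block counts must fill the block exactly, otherwise a
    :class:`BlockRoundingError` suggests changing the block size.
    """
    k = weights.normalized.size
    if arm_labels is None:
        arm_labels = [f"arm{i + 1}" for i in range(k)]
    if len(arm_labels) != k:
        raise ValueError("arm_labels length must match the number of arms")
    if n_entries <= 0 or block_size <= 0 or n_entries % block_size != 0:
        raise ValueError("n_entries must be a positive multiple of block_size")
    target = weights.normalized * block_size
    counts = np.rint(target).astype(int)
    if counts.sum() != block_size or np.any(np.abs(counts - target) > 0.5 + 1e-9):
        raise BlockRoundingError(
            f"weights {np.round(weights.normalized, 3).tolist()} are not "
            f"representable in blocks of {block_size}; choose a block size "
            "whose per-arm targets round to whole counts summing to the block"
        )
    rng = np.random.default_rng(seed)
    template = np.repeat(np.arange(k), counts)
    entries = []
    seq = 1
    for _ in range(n_entries // block_size):
        for arm_index in rng.permutation(template):
            entries.append((seq, arm_labels[int(arm_index)]))
            seq += 1
    return RandomizationSchedule(
        site_id=site_id,
        entries=tuple(entries),
        block_size=block_size,
        seed=seed,
    )
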