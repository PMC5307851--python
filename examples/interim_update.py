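"""One interim analysis: posterior update, probability-best, new allocation.

Suppose an interim look finds 6 early preterm births among 150 deliveries
in the control group and 2 among 150 in the treated group.  This script
fits the per-arm posteriors, computes the probability that each arm has
the lowest ePTB rate, derives the information-weighted allocation for the
next enrollment block, and prints a small permuted-block schedule.
"""

import numpy as np

from rartrial import (
    ArmCounts,
    allocation_weights,
    fit_posterior,
    make_schedule,
    site_seed,
)

counts = [ArmCounts("control", 150, 6), ArmCounts("treated", 150, 2)]
result = fit_posterior(counts, level=0.95)

for i, arm in enumerate(result.arm_ids):
    print(
        f"{arm:8s} posterior mean {100 * result.mean[i]:.2f}%  "
        f"95% CI [{100 * result.lower[i]:.2f}%, {100 * result.upper[i]:.2f}%]  "
        f"P(best) = {result.prob_best[i]:.3f}"
    )

weights = allocation_weights(
    result.prob_best, result.variance, n=[150, 150], interim_id=1
)
print(f"\nallocation weights for the next block: "
      f"{np.round(weights.normalized, 3).tolist()}")
print("(the fourth root dampens the update: P(best) of 0.92 vs 0.08 maps to")
print(" roughly a 60/40 allocation, not 92/8)")

sched = make_schedule(
    weights, n_entries=20, block_size=10, site_id="site1",
    seed=site_seed(0, "site1"), arm_labels=[c.arm_id for c in counts],
)
print(f"\nfirst block of the site1 schedule: "
      f"{[arm for _, arm in sched.entries[:10]]}")
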