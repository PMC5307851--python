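"""Posterior inference for per-arm early-preterm-birth (ePTB) rates.

The outcome model is binomial: in arm ``j`` the number of early preterm
births ``Y_j`` among ``n_j`` observed births is ``Binom(n_j, theta_j)``,
with a weakly informative logit-normal prior ``logit(theta_j) ~ N(mu,
sigma^2)`` (defaults mu = -3.5, sigma = 1.5, i.e. a prior median ePTB rate
of 2.9% with 95% of the mass between 0.16% and 36%).

Two inference engines are provided:

* :func:`posterior_quadrature` — deterministic numerical integration on a
  uniform grid over ``logit(theta)``.  This is what the trial engine uses,
  so every allocation and stopping decision is reproducible bit-for-bit.
* :func:`sample_posterior` — an adaptive random-walk Metropolis sampler on
  the logit scale, retained as an independent stochastic cross-check.

"Best" arm means the arm with the *lowest* ePTB rate; :func:`prob_best`
computes the posterior probability of being best for each arm under
independent per-arm posteriors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, log_expit, logit, ndtri

from .exceptions import GridError, InvalidPriorError, SamplerWarning

__all__ = [
    "PriorSpec",
    "ArmCounts",
    "GridSpec",
    "PriorSummary",
    "QuadraturePosterior",
    "PosteriorResult",
    "prior_summary",
    "posterior_quadrature",
    "sample_posterior",
    "prob_best",
    "fit_posterior",
    "effective_sample_size",
]


@dataclass(frozen=True)
class PriorSpec:
    """Logit-normal prior on an arm's ePTB rate: logit(theta) ~ N(mu, sigma^2)."""

    mu: float = -3.5
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise InvalidPriorError(f"prior mu must be finite, got {self.mu}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise InvalidPriorError(f"prior sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class ArmCounts:
    """Observed births and early-preterm events for one arm at an interim."""

    arm_id: str
    births: int
    events: int

    def __post_init__(self) -> None:
        if self.births < 0:
            raise ValueError(f"births must be nonnegative, got {self.births}")
        if not (0 <= self.events <= self.births):
            raise ValueError(
                f"events must satisfy 0 <= events <= births, got "
                f"events={self.events}, births={self.births}"
            )


@dataclass(frozen=True)
class GridSpec:
    """Uniform quadrature grid on the logit(theta) scale.

    The default covers theta from ~6e-6 to 0.88, far beyond plausible
    early-preterm rates.  For saturated data (event fraction near 1) pass a
    wider grid; :func:`posterior_quadrature` refuses grids that truncate
    visible posterior mass.
    """

    lo: float = -12.0
    hi: float = 2.0
    n: int = 4001

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("grid needs at least 3 points")
        if not self.hi > self.lo:
            raise ValueError("grid hi must exceed lo")

    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)


@dataclass(frozen=True)
class PriorSummary:
    point: float  # prior median of theta (inverse-logit of mu)
    lower: float
    upper: float
    level: float


def prior_summary(prior: PriorSpec, level: float = 0.95) -> PriorSummary:
    """Point estimate (median) and central interval of theta implied by the prior.

    The logit-normal prior's quantiles map through the inverse logit, so the
    median of theta is ``expit(mu)`` and the central interval at ``level`` is
    ``expit(mu -/+ z*sigma)`` with ``z`` the standard-normal quantile.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = float(ndtri(0.5 + level / 2.0))
    return PriorSummary(
        point=float(expit(prior.mu)),
        lower=float(expit(prior.mu - z * prior.sigma)),
        upper=float(expit(prior.mu + z * prior.sigma)),
        level=level,
    )


@dataclass(frozen=True)
class QuadraturePosterior:
    """Normalized posterior of one arm's theta on a fixed logit grid."""

    counts: ArmCounts
    prior: PriorSpec
    grid: GridSpec
    logit_theta: np.ndarray = field(repr=False)
    theta: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    mean: float = 0.0
    variance: float = 0.0

    def quantile(self, q) -> np.ndarray | float:
        """Posterior quantile(s) of theta by midpoint-CDF interpolation."""
        cdf = np.cumsum(self.weights) - 0.5 * self.weights
        return np.interp(q, cdf, self.theta)

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        if not 0.0 < level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {level}")
        a = (1.0 - level) / 2.0
        lo, hi = self.quantile([a, 1.0 - a])
        return float(lo), float(hi)


def _log_posterior_grid(x: np.ndarray, counts: ArmCounts, prior: PriorSpec) -> np.ndarray:
    # Binomial log-likelihood in the logit parameter plus normal log-prior,
    # both up to additive constants.
    ll = counts.events * log_expit(x) + (counts.births - counts.events) * log_expit(-x)
    lp = -0.5 * ((x - prior.mu) / prior.sigma) ** 2
    return ll + lp


def posterior_quadrature(
    counts: ArmCounts,
    prior: PriorSpec = PriorSpec(),
    grid: GridSpec = GridSpec(),
    boundary_tol: float = 1e-6,
) -> QuadraturePosterior:
    """Deterministic posterior of theta for one arm by grid quadrature.

    The unnormalized log-density is evaluated on a uniform grid over
    ``logit(theta)`` and normalized with a max-shift (log-sum-exp); moments
    and quantiles are computed from the resulting discrete weights.

    Raises :class:`GridError` when the normalized mass on either endpoint
    exceeds ``boundary_tol``, which signals a grid too narrow for the data.
    """
    x = grid.points()
    lw = _log_posterior_grid(x, counts, prior)
    lw -= lw.max()
    w = np.exp(lw)
    # trapezoid rule on the uniform grid: endpoints carry half weight
    w[0] *= 0.5
    w[-1] *= 0.5
    w /= w.sum()
    if w[0] > boundary_tol or w[-1] > boundary_tol:
        raise GridError(
            f"posterior mass at grid boundary ({max(w[0], w[-1]):.2e}) exceeds "
            f"{boundary_tol:.0e}; widen the logit grid [{grid.lo}, {grid.hi}]"
        )
    theta = expit(x)
    mean = float(w @ theta)
    variance = float(w @ (theta - mean) ** 2)
    return QuadraturePosterior(
        counts=counts,
        prior=prior,
        grid=grid,
        logit_theta=x,
        theta=theta,
        weights=w,
        mean=mean,
        variance=variance,
    )


def effective_sample_size(draws: np.ndarray) -> float:
    """Effective sample size of a single MCMC chain (via ``arviz.ess``)."""
    import arviz as az

    return float(az.ess(np.asarray(draws, dtype=float)))


def sample_posterior(
    counts: ArmCounts,
    prior: PriorSpec = PriorSpec(),
    n_draws: int = 20_000,
    seed: int | None = None,
    n_burn: int = 2_000,
    check_ess: bool = True,
) -> np.ndarray:
    """Draw from one arm's posterior of theta by adaptive random-walk Metropolis.

    The chain walks on the logit scale (a well-behaved 1-D target); the
    proposal standard deviation is tuned during burn-in by Robbins-Monro
    adaptation toward a 44% acceptance rate and then frozen.  Returns
    ``n_draws`` values of theta in (0, 1); identical seeds give identical
    draw sequences.  A :class:`SamplerWarning` is emitted when the effective
    sample size falls below 100.
    """
    if n_draws < 1000:
        raise ValueError(f"n_draws must be at least 1000, got {n_draws}")
    rng = np.random.default_rng(seed)
    y, n = counts.events, counts.births

    def log_post(x: float) -> float:
        # y*log(theta) + (n-y)*log(1-theta) in logit form, plus normal prior.
        ll = y * x - n * np.logaddexp(0.0, x)
        return ll - 0.5 * ((x - prior.mu) / prior.sigma) ** 2

    x = float(logit((y + 0.5) / (n + 1.0))) if n > 0 else prior.mu
    # Start near the posterior scale: combine prior and (rough) data precision.
    p0 = expit(x)
    data_prec = n * p0 * (1.0 - p0)
    step = 2.4 / np.sqrt(1.0 / prior.sigma**2 + data_prec)

    total = n_burn + n_draws
    z = rng.standard_normal(total)
    log_u = np.log(rng.random(total))
    out = np.empty(n_draws)
    lp = log_post(x)
    for i in range(total):
        prop = x + step * z[i]
        lpp = log_post(prop)
        accepted = log_u[i] < lpp - lp
        if accepted:
            x, lp = prop, lpp
        if i < n_burn:
            step *= float(np.exp((float(accepted) - 0.44) / (1.0 + i) ** 0.6))
        else:
            out[i - n_burn] = x

    theta = expit(out)
    if check_ess:
        ess = effective_sample_size(theta)
        if ess < 100:
            warnings.warn(
                f"effective sample size {ess:.0f} < 100 for arm "
                f"{counts.arm_id!r}; treat posterior summaries with caution",
                SamplerWarning,
                stacklevel=2,
            )
    return theta


def _prob_best_quadrature(posteriors: Sequence[QuadraturePosterior]) -> np.ndarray:
    grids = {(p.grid.lo, p.grid.hi, p.grid.n) for p in posteriors}
    if len(grids) != 1:
        raise ValueError("quadrature posteriors must share one grid for prob_best")
    W = np.vstack([p.weights for p in posteriors])
    # P(theta_k > grid point i), counting half of the atom at i itself so
    # that identical posteriors score an exact 1/2 against each other.
    tail = np.cumsum(W[:, ::-1], axis=1)[:, ::-1] - W
    gt = tail + 0.5 * W
    k = len(posteriors)
    out = np.empty(k)
    for j in range(k):
        others = np.prod(gt[[m for m in range(k) if m != j]], axis=0)
        out[j] = float(W[j] @ others)
    return out / out.sum()


def _prob_best_draws(draws: np.ndarray) -> np.ndarray:
    theta = np.asarray(draws, dtype=float)
    if theta.ndim != 2 or theta.shape[0] < 2:
        raise ValueError("expected a (n_arms, n_draws) array with n_arms >= 2")
    best = np.argmin(theta, axis=0)
    k = theta.shape[0]
    return np.bincount(best, minlength=k) / theta.shape[1]


def prob_best(posteriors) -> np.ndarray:
    """Posterior probability that each arm has the lowest ePTB rate.

    Accepts either a sequence of :class:`QuadraturePosterior` objects fitted
    on a common grid (deterministic 1-D integration of each arm's density
    against the product of the other arms' survival functions) or a
    ``(n_arms, n_draws)`` array of posterior draws (empirical argmin
    frequencies).  Entries are in [0, 1] and sum to 1.
    """
    if isinstance(posteriors, np.ndarray):
        return _prob_best_draws(posteriors)
    posteriors = list(posteriors)
    if len(posteriors) < 2:
        raise ValueError("prob_best needs at least 2 arms")
    if all(isinstance(p, QuadraturePosterior) for p in posteriors):
        return _prob_best_quadrature(posteriors)
    return _prob_best_draws(np.vstack([np.asarray(p, dtype=float) for p in posteriors]))


@dataclass(frozen=True)
class PosteriorResult:
    """Joint posterior summary for all arms at one analysis."""

    arm_ids: tuple[str, ...]
    mean: np.ndarray
    variance: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    prob_best: np.ndarray
    method: str  # "quadrature" | "sampling"
    n_draws: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "arms": [
                {
                    "arm_id": a,
                    "mean": float(self.mean[i]),
                    "variance": float(self.variance[i]),
                    "median": float(self.median[i]),
                    "lower": float(self.lower[i]),
                    "upper": float(self.upper[i]),
                    "prob_best": float(self.prob_best[i]),
                }
                for i, a in enumerate(self.arm_ids)
            ],
            "level": self.level,
            "method": self.method,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


def fit_posterior(
    counts: Sequence[ArmCounts],
    prior: PriorSpec = PriorSpec(),
    method: str = "quadrature",
    level: float = 0.95,
    grid: GridSpec = GridSpec(),
    n_draws: int = 20_000,
    seed: int | None = None,
) -> PosteriorResult:
    """Fit all arms under a common prior and summarize, including prob_best."""
    counts = list(counts)
    if len(counts) < 2:
        raise ValueError("fit_posterior needs at least 2 arms")
    if method == "quadrature":
        posts = [posterior_quadrature(c, prior, grid) for c in counts]
        pb = prob_best(posts)
        alpha = (1.0 - level) / 2.0
        return PosteriorResult(
            arm_ids=tuple(c.arm_id for c in counts),
            mean=np.array([p.mean for p in posts]),
            variance=np.array([p.variance for p in posts]),
            median=np.array([p.median for p in posts]),
            lower=np.array([p.quantile(alpha) for p in posts]),
            upper=np.array([p.quantile(1.0 - alpha) for p in posts]),
            level=level,
            prob_best=pb,
            method="quadrature",
        )
    if method == "sampling":
        ss = np.random.SeedSequence(seed)
        draws = np.vstack(
            [
                sample_posterior(c, prior, n_draws=n_draws, seed=child)
                for c, child in zip(counts, ss.spawn(len(counts)))
            ]
        )
        pb = prob_best(draws)
        alpha = (1.0 - level) / 2.0
        return PosteriorResult(
            arm_ids=tuple(c.arm_id for c in counts),
            mean=draws.mean(axis=1),
            variance=draws.var(axis=1, ddof=1),
            median=np.median(draws, axis=1),
            lower=np.quantile(draws, alpha, axis=1),
            upper=np.quantile(draws, 1.0 - alpha, axis=1),
            level=level,
            prob_best=pb,
            method="sampling",
            n_draws=n_draws,
            seed=seed,
        )
    raise ValueError(f"unknown method {method!r}; use 'quadrature' or 'sampling'")
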