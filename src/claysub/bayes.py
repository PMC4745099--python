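"""Sequential beta-binomial inference on the wood-for-clay substitution hypothesis.

A loaded-arm replicate is scored a *success* when the termites deposited more
clay than the experiment's loaded-arm average while eating more than half of
the wood — the signature of clay progressively substituting the load-bearing
wood.  Successes are fed one at a time through conjugate beta-binomial
updating (the i-th posterior becomes the (i+1)-th prior, a Polya-urn scheme),
starting from either the Jeffreys Beta(1/2, 1/2) or the uniform Beta(1, 1)
prior.  The reported point estimate is the posterior median of the binomial
success probability, and uncertainty is a highest-density region (HDR)
credible interval: the narrowest interval holding the requested posterior
mass, which for monotone beta densities abuts a support boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import optimize, stats

from claysub.core import AnalysisConfig, ExperimentDataset, UnitMeasurement, filter_included

logger = logging.getLogger("claysub")

__all__ = [
    "PosteriorState",
    "CredibleInterval",
    "SubstitutionReport",
    "is_success",
    "make_prior",
    "update_sequential",
    "posterior_median",
    "equal_tailed_interval",
    "hdr_interval",
    "run_substitution_inference",
]


@dataclass(frozen=True)
class PosteriorState:
    """Beta(alpha, beta) posterior with the full sequential-update history.

    ``history`` holds the (alpha, beta) pair after every observation,
    starting with the prior, so ``len(history) == n_observed + 1`` and
    ``alpha + beta == prior_alpha + prior_beta + n_observed``.
    """

    alpha: float
    beta: float
    n_observed: int = 0
    history: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("pseudo-counts must be positive")
        if not self.history:
            object.__setattr__(self, "history", ((self.alpha, self.beta),))
        if len(self.history) != self.n_observed + 1:
            raise ValueError("history length must equal n_observed + 1")

    def distribution(self) -> stats.rv_continuous:
        return stats.beta(self.alpha, self.beta)


@dataclass(frozen=True)
class CredibleInterval:
    """A posterior interval [lower, upper] holding ``mass`` probability."""

    lower: float
    upper: float
    mass: float
    method: str  # "hdr" or "equal_tailed"

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper <= 1):
            raise ValueError("interval must satisfy 0 <= lower < upper <= 1")
        if self.method not in ("hdr", "equal_tailed"):
            raise ValueError(f"unknown interval method {self.method!r}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def is_success(loaded: UnitMeasurement, mean_clay: float) -> bool:
    """Substitution success: above-average clay AND less than half the wood left.

    ``mean_clay`` must be the mean clay mass over the included loaded arms of
    the same experiment.  Both inequalities are strict, so ties count as
    failure.
    """
    return (loaded.clay_mass > mean_clay) and (
        loaded.leftover_wood < 0.5 * loaded.initial_wood
    )


def make_prior(kind: str = "jeffreys") -> PosteriorState:
    """Jeffreys -> Beta(1/2, 1/2); uniform -> Beta(1, 1)."""
    if kind == "jeffreys":
        return PosteriorState(alpha=0.5, beta=0.5)
    if kind == "uniform":
        return PosteriorState(alpha=1.0, beta=1.0)
    raise ValueError(f"unknown prior kind {kind!r}")


def update_sequential(prior: PosteriorState, outcomes: Iterable[bool]) -> PosteriorState:
    """Conjugate updating, one outcome at a time, recording every intermediate state.

    Each success adds one to alpha, each failure one to beta.  The final
    state equals the batch update on the outcome counts (exchangeability).
    """
    a, b = prior.alpha, prior.beta
    history = list(prior.history)
    n = prior.n_observed
    for outcome in outcomes:
        if outcome:
            a += 1.0
        else:
            b += 1.0
        n += 1
        history.append((a, b))
    return PosteriorState(alpha=a, beta=b, n_observed=n, history=tuple(history))


def posterior_median(state: PosteriorState) -> float:
    """The 0.5 quantile of Beta(alpha, beta)."""
    return float(stats.beta.ppf(0.5, state.alpha, state.beta))


def equal_tailed_interval(state: PosteriorState, mass: float) -> CredibleInterval:
    """Central interval cutting (1 - mass)/2 from each tail."""
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0, 1)")
    tail = (1 - mass) / 2
    lo, hi = stats.beta.ppf([tail, 1 - tail], state.alpha, state.beta)
    return CredibleInterval(lower=float(lo), upper=float(hi), mass=mass, method="equal_tailed")


def hdr_interval(state: PosteriorState, mass: float = 0.99) -> CredibleInterval:
    """Highest-density credible interval of the beta posterior.

    For an interior mode (a > 1, b > 1) the lower endpoint is optimized so
    that the interval [l, F^-1(F(l) + mass)] has minimal width; the contained
    mass is then exact by construction (tolerance 1e-6).  Monotone densities
    pin the interval to the support boundary: decreasing (a <= 1 < b) gives
    [0, q_mass], increasing (b <= 1 < a) gives [q_{1-mass}, 1].  The flat
    Beta(1, 1) case returns the centred interval.  A U-shaped density
    (a < 1 and b < 1) has no single highest-density interval; the central
    equal-tailed interval is returned instead, flagged by its ``method`` and
    a warning.
    """
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0, 1)")
    a, b = state.alpha, state.beta
    dist = stats.beta(a, b)

    if a < 1 and b < 1:
        warnings.warn(
            "U-shaped Beta posterior: the HDR is a union of boundary intervals; "
            "falling back to the equal-tailed interval",
            stacklevel=2,
        )
        return equal_tailed_interval(state, mass)
    if a == 1 and b == 1:
        half = mass / 2
        return CredibleInterval(0.5 - half, 0.5 + half, mass, "hdr")
    if a <= 1:  # b >= 1: monotone decreasing, mode at 0
        return CredibleInterval(0.0, float(dist.ppf(mass)), mass, "hdr")
    if b <= 1:  # a > 1: monotone increasing, mode at 1
        return CredibleInterval(float(dist.ppf(1 - mass)), 1.0, mass, "hdr")

    # Interior mode: minimize the width over the feasible lower endpoint.
    def width(lo: float) -> float:
        return float(dist.ppf(min(dist.cdf(lo) + mass, 1.0))) - lo

    upper_bound = float(dist.ppf(1 - mass))
    res = optimize.minimize_scalar(width, bounds=(0.0, upper_bound), method="bounded",
                                   options={"xatol": 1e-12})
    lo = float(res.x)
    hi = float(dist.ppf(dist.cdf(lo) + mass))
    return CredibleInterval(lower=lo, upper=hi, mass=mass, method="hdr")


@dataclass(frozen=True)
class SubstitutionReport:
    """Full output of the sequential substitution inference."""

    prior_kind: str
    mean_clay: float
    successes: tuple[bool, ...]
    posterior: PosteriorState
    median: float
    interval: CredibleInterval
    trajectory: tuple[dict, ...]  # per-step alpha, beta, median for plotting

    @property
    def n_successes(self) -> int:
        return sum(self.successes)


def run_substitution_inference(
    ds: ExperimentDataset, cfg: AnalysisConfig = AnalysisConfig()
) -> SubstitutionReport:
    """Score successes on the included loaded arms and run the sequential update.

    The success threshold (mean loaded-arm clay) is computed over the
    included replicates of the same experiment.  Returns the posterior
    median substitution probability, the HDR interval at
    ``cfg.credibility_mass`` and the whole updating trajectory.
    """
    included = filter_included(ds)
    if len(included) == 0:
        raise ValueError("no included replicates: cannot run inference")
    loaded_arms = [r.loaded for r in included.replicates]
    mean_clay = float(np.mean([u.clay_mass for u in loaded_arms]))
    outcomes = tuple(is_success(u, mean_clay) for u in loaded_arms)

    prior = make_prior(cfg.prior_kind)
    posterior = update_sequential(prior, outcomes)
    trajectory = tuple(
        {
            "step": i,
            "alpha": a,
            "beta": b,
            "median": float(stats.beta.ppf(0.5, a, b)),
        }
        for i, (a, b) in enumerate(posterior.history)
    )
    return SubstitutionReport(
        prior_kind=cfg.prior_kind,
        mean_clay=mean_clay,
        successes=outcomes,
        posterior=posterior,
        median=posterior_median(posterior),
        interval=hdr_interval(posterior, cfg.credibility_mass),
        trajectory=trajectory,
    )
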