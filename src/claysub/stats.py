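"""Choice-experiment test battery and the bootstrap bivariate beta joint model.

Covers the classical comparisons between the loaded and unloaded arms
(balanced one-way ANOVA on clay mass, clay per unit volume, leftover wood and
normalized consumption), the distributional checks (two-sample
Kolmogorov-Smirnov, Monte-Carlo Lilliefors normality), and the predictive
joint model: method-of-moments beta fits to percentage-scaled clay-per-volume
and leftover-wood data, joined by a Gaussian copula (or independently) and
bootstrapped to an n x 2 matrix of percentages whose kurtosis is compared
between arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from claysub.core import UnitMeasurement

__all__ = [
    "AnovaResult",
    "BetaFit",
    "CouplingSpec",
    "JointDistributionModel",
    "KurtosisReport",
    "FitError",
    "anova_oneway",
    "normalized_consumption",
    "clay_per_volume",
    "ks_two_sample",
    "lilliefors_normality",
    "fit_beta_moments",
    "to_percent",
    "bootstrap_joint",
    "compare_kurtosis",
]

#: Percent values of exactly 0 or 100 are clamped inside the open beta support.
PERCENT_EPS = 0.01


class FitError(ValueError):
    """Sample moments incompatible with the requested distribution family."""


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA summary: F = MS_between / MS_within with an upper-tail p."""

    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False  # zero within-group variance with nonzero between

    def __post_init__(self) -> None:
        if self.F < 0 or not (0 <= self.p <= 1):
            raise ValueError("invalid ANOVA result")


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Balanced one-way analysis of variance via the sum-of-squares decomposition.

    Requires >= 2 groups of equal size >= 2 (the experiments are balanced
    paired designs).  Zero within-group variance with nonzero between-group
    variance is reported as F = inf, p = 0 with ``degenerate=True``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    sizes = {a.size for a in arrays}
    if len(sizes) != 1:
        raise ValueError("unbalanced groups: the design requires equal group sizes")
    n = sizes.pop()
    if n < 2:
        raise ValueError("each group needs at least two values")

    data = np.stack(arrays)
    grand = data.mean()
    ss_between = n * float(np.sum((data.mean(axis=1) - grand) ** 2))
    ss_within = float(np.sum((data - data.mean(axis=1, keepdims=True)) ** 2))
    df_b = len(arrays) - 1
    df_w = data.size - len(arrays)

    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w, p=0.0, degenerate=True)

    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def normalized_consumption(u: UnitMeasurement) -> float:
    """Fraction of the initial wood eaten: (initial - leftover) / initial."""
    if u.initial_wood <= 0:
        raise ValueError("initial_wood must be positive")
    return (u.initial_wood - u.leftover_wood) / u.initial_wood


def clay_per_volume(u: UnitMeasurement) -> float:
    """Clay mass per residual inter-paver volume, g cm^-3."""
    if u.final_volume <= 0:
        raise ValueError("final_volume must be positive")
    return u.clay_mass / u.final_volume


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p).

    Returns ``(D, p)`` with D the supremum of the empirical-CDF difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _lilliefors_stat(z_sorted: np.ndarray) -> np.ndarray:
    """KS distance of standardized sorted rows to the standard normal CDF."""
    n = z_sorted.shape[-1]
    cdf = stats.norm.cdf(z_sorted)
    i = np.arange(n)
    d_plus = np.max((i + 1) / n - cdf, axis=-1)
    d_minus = np.max(cdf - i / n, axis=-1)
    return np.maximum(d_plus, d_minus)


def lilliefors_normality(x: Sequence[float], n_mc: int = 2000, seed: int = 0) -> float:
    """Lilliefors test of composite normality with a Monte-Carlo p-value.

    The statistic is the KS distance between the sample (standardized by its
    own mean and SD) and the standard normal CDF; the null distribution is
    simulated from ``n_mc`` standard-normal samples of the same size, so the
    p-value accounts for the estimated parameters.  Deterministic given
    ``seed``; the p-value uses the add-one permutation-test convention.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    d_obs = float(_lilliefors_stat((x - x.mean()) / sd))

    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, n))
    sims = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    d_null = _lilliefors_stat(np.sort(sims, axis=1))
    return float((1 + np.sum(d_null >= d_obs)) / (n_mc + 1))


# ---------------------------------------------------------------------------
# Beta marginals and the bootstrap joint distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaFit:
    """Beta(a, b) fitted to data on the percent scale (support [0, 100])."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise FitError("beta parameters must be positive")

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.a / (self.a + self.b)

    def frozen(self) -> stats.rv_continuous:
        """The fitted distribution on the unit scale."""
        return stats.beta(self.a, self.b)


def to_percent(x: Sequence[float], reference: float | None = None) -> np.ndarray:
    """Normalize values to the scale-invariant [0, 100] percent interval.

    ``reference`` defaults to the sample maximum; exact 0/100 endpoints are
    clamped to [PERCENT_EPS, 100 - PERCENT_EPS] because the beta support is
    open.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("percent normalization expects nonnegative values")
    ref = float(np.max(x)) if reference is None else float(reference)
    if ref <= 0:
        raise ValueError("reference must be positive")
    return np.clip(100.0 * x / ref, PERCENT_EPS, 100.0 - PERCENT_EPS)


def fit_beta_moments(x: Sequence[float], refine_mle: bool = False) -> BetaFit:
    """Fit Beta(a, b) to percentage data by method of moments.

    Values are rescaled to (0, 1) (with endpoint clamping) and the sample
    mean m and variance v inverted in closed form:
    ``a = m (m(1-m)/v - 1)``, ``b = (1-m)(m(1-m)/v - 1)``.
    ``refine_mle=True`` polishes the estimate by maximum likelihood.

    Raises ``FitError`` when ``v >= m(1-m)`` (impossible for a beta).
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("values must lie in [0, 100]")
    u = np.clip(x / 100.0, PERCENT_EPS / 100.0, 1 - PERCENT_EPS / 100.0)
    m = float(u.mean())
    v = float(u.var(ddof=1))
    if v <= 0:
        raise FitError("sample variance must be positive")
    if v >= m * (1 - m):
        raise FitError(f"variance {v:.4g} >= m(1-m) = {m * (1 - m):.4g}: no beta has these moments")
    common = m * (1 - m) / v - 1.0
    a, b = m * common, (1 - m) * common
    if refine_mle:
        a, b, _, _ = stats.beta.fit(u, a, b, floc=0, fscale=1)
    return BetaFit(a=float(a), b=float(b))


@dataclass(frozen=True)
class CouplingSpec:
    """How the two beta marginals are joined.

    ``gaussian_copula`` preserves both marginals while imposing the given
    Spearman rank correlation; ``independent`` ignores ``rho``.
    """

    kind: str = "gaussian_copula"
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("independent", "gaussian_copula"):
            raise ValueError(f"unknown coupling kind {self.kind!r}")
        if self.kind == "gaussian_copula" and not (-1 < self.rho < 1):
            raise ValueError("|rho| must be < 1")


@dataclass(frozen=True)
class JointDistributionModel:
    """Fitted marginals, coupling and the bootstrap sample matrix (percent scale)."""

    marginal_clay: BetaFit
    marginal_wood: BetaFit
    coupling: CouplingSpec
    bootstrap_samples: np.ndarray  # shape (n, 2), columns (clay %, leftover wood %)
    excess_kurtosis: tuple[float, float]
    joint_excess_kurtosis: float
    rank_correlation: float

    def __post_init__(self) -> None:
        s = np.asarray(self.bootstrap_samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 2:
            raise ValueError("bootstrap_samples must be an (n, 2) matrix")
        if np.any((s < 0) | (s > 100)):
            raise ValueError("bootstrap samples must lie in [0, 100]^2")


def bootstrap_joint(
    clay_fit: BetaFit,
    wood_fit: BetaFit,
    coupling: CouplingSpec,
    n: int = 10_000,
    seed: int = 0,
) -> JointDistributionModel:
    """Draw n paired samples from the predictive bivariate beta model.

    The fitted betas act as the statistically smoothed marginals.  Under the
    Gaussian copula the target Spearman rho is converted to the copula's
    Pearson parameter (``2 sin(pi rho / 6)``) so the rank correlation of the
    output matches the request while the marginals stay exactly beta.
    Per-margin excess kurtosis uses the standardized fourth moment; the joint
    statistic is Mardia's multivariate kurtosis minus its Gaussian value
    d(d+2) = 8.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    if coupling.kind == "independent":
        u = rng.random((n, 2))
    else:
        rho_p = 2.0 * math.sin(math.pi * coupling.rho / 6.0)
        z = rng.standard_normal((n, 2))
        z[:, 1] = rho_p * z[:, 0] + math.sqrt(1 - rho_p**2) * z[:, 1]
        u = stats.norm.cdf(z)
    clay = 100.0 * stats.beta.ppf(u[:, 0], clay_fit.a, clay_fit.b)
    wood = 100.0 * stats.beta.ppf(u[:, 1], wood_fit.a, wood_fit.b)
    samples = np.column_stack([clay, wood])

    kurt = tuple(float(stats.kurtosis(samples[:, j], fisher=True, bias=False)) for j in (0, 1))
    centred = samples - samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False)
    maha2 = np.einsum("ij,jk,ik->i", centred, np.linalg.inv(cov), centred)
    joint_kurt = float(np.mean(maha2**2) - 8.0)
    rho_s = float(stats.spearmanr(samples[:, 0], samples[:, 1]).statistic)

    return JointDistributionModel(
        marginal_clay=clay_fit,
        marginal_wood=wood_fit,
        coupling=coupling,
        bootstrap_samples=samples,
        excess_kurtosis=kurt,
        joint_excess_kurtosis=joint_kurt,
        rank_correlation=rho_s,
    )


@dataclass(frozen=True)
class KurtosisReport:
    """Loaded-vs-unloaded kurtosis comparison of the bootstrap joint models."""

    loaded_margins: tuple[float, float]
    unloaded_margins: tuple[float, float]
    margin_difference: tuple[float, float]  # loaded minus unloaded
    joint_difference: float
    loaded_more_platykurtic: bool


def compare_kurtosis(
    loaded: JointDistributionModel, unloaded: JointDistributionModel
) -> KurtosisReport:
    """Report per-margin excess kurtosis and the sign of loaded minus unloaded.

    A negative difference means the loaded-arm joint distribution is flatter
    (more platykurtic) than the unloaded one.
    """
    diff = tuple(
        l - u for l, u in zip(loaded.excess_kurtosis, unloaded.excess_kurtosis)
    )
    joint_diff = loaded.joint_excess_kurtosis - unloaded.joint_excess_kurtosis
    return KurtosisReport(
        loaded_margins=loaded.excess_kurtosis,
        unloaded_margins=unloaded.excess_kurtosis,
        margin_difference=diff,  # type: ignore[arg-type]
        joint_difference=float(joint_diff),
        loaded_more_platykurtic=bool(joint_diff < 0),
    )
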