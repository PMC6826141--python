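"""Drift-null significance testing and selection-coefficient estimation.

For a site observed with ``early_alt / early_total`` and
``late_alt / late_total`` reads, the model chain is

    early reads -> posterior over the true early frequency (uniform grid
    prior, binomial read likelihood through the sequencing-error map)
    -> binomial bottleneck of B founder cells
    -> fitness-biased growth to B * 2**d cells (``growth_distribution``)
    -> binomial sampling of ``late_total`` reads through the same error map.

The drift-null p-value is the probability, under this chain with s = 0, of
a late alternate-read count at least as extreme as the one observed, one
sided in the direction of the observed frequency change.  The selection
coefficient s (mutant cells divide at rate ``1 + s``) is estimated by a
grid search of the same chain's likelihood over s in [-1, 1], with a 95%
confidence interval from the likelihood-ratio test (chi-square, 1 df).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .growth import FrequencyDistribution, growth_kernel_stack, _atom_grid
from .params import ExperimentParams

__all__ = [
    "SiteObservation",
    "DriftTestResult",
    "SelectionEstimate",
    "allele_frequency_percent",
    "observed_read_prob",
    "early_frequency_posterior",
    "drift_pvalue",
    "bonferroni_alpha",
    "selection_likelihood",
    "estimate_selection",
    "default_s_grid",
]

# chi-square(1 df) 95% quantile for the likelihood-ratio confidence interval
LRT_CUTOFF_95 = float(stats.chi2.ppf(0.95, df=1))
# Target-region size in bp used for the default Bonferroni correction.
DEFAULT_TARGET_BP = 290_000
LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class SiteObservation:
    """Early- and late-passage alternate/total read counts at one site."""

    site_id: str
    early_alt: int
    early_total: int
    late_alt: int
    late_total: int

    def __post_init__(self) -> None:
        for stage in ("early", "late"):
            alt = getattr(self, f"{stage}_alt")
            total = getattr(self, f"{stage}_total")
            if total < 1:
                raise ValueError(f"{self.site_id}: {stage}_total must be >= 1")
            if not (0 <= alt <= total):
                raise ValueError(
                    f"{self.site_id}: {stage}_alt must satisfy 0 <= alt <= total"
                )

    @property
    def early_freq(self) -> float:
        return self.early_alt / self.early_total

    @property
    def late_freq(self) -> float:
        return self.late_alt / self.late_total

    @property
    def direction(self) -> str:
        """'gain' if the variant allele rose (or held) between passages."""
        return "gain" if self.late_freq >= self.early_freq else "loss"


@dataclass(frozen=True)
class DriftTestResult:
    site_id: str
    p_value: float
    alpha: float
    significant: bool
    direction: str


@dataclass(frozen=True)
class SelectionEstimate:
    site_id: str
    s_hat: float
    ci_low: float
    ci_high: float
    profile: tuple = field(repr=False)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.s_hat <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def allele_frequency_percent(alt: int, total: int) -> float:
    """Variant allele frequency as a percentage, 100 * alt / total."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not (0 <= alt <= total):
        raise ValueError("alt must satisfy 0 <= alt <= total")
    return 100.0 * alt / total


def observed_read_prob(f, params: ExperimentParams):
    """Probability that an aligned read shows the alternate allele.

    A read from a mutant template reports the alternate base unless
    miscalled; a read from a wild-type template is miscalled toward this
    specific alternate base with probability epsilon / 3 (miscalls spread
    uniformly over the three non-reference bases).  In diploid mode the
    cell fraction f contributes reads at f / 2.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequency must be in [0, 1]")
    eps = params.seq_error
    if params.diploid:
        f = f / 2.0
    out = f * (1.0 - eps) + (1.0 - f) * eps / 3.0
    return float(out) if out.ndim == 0 else out


def early_frequency_posterior(
    early_alt: int, early_total: int, params: ExperimentParams
) -> FrequencyDistribution:
    """Posterior over the true early frequency on the grid.

    Uniform prior over the frequency bins; binomial likelihood of the
    observed early read counts through :func:`observed_read_prob`.  This is
    the minimal-assumption conditioning step: an observed zero count leaves
    the true frequency near, but not pinned to, zero.
    """
    if early_total < 1:
        raise ValueError("early_total must be >= 1")
    if not (0 <= early_alt <= early_total):
        raise ValueError("early_alt out of range")
    centers = params.bin_centers
    like = stats.binom.pmf(early_alt, early_total, observed_read_prob(centers, params))
    total = like.sum()
    if total <= 0.0:
        raise ValueError("early-read likelihood underflowed on the whole grid")
    return FrequencyDistribution(centers, like / total)


def bonferroni_alpha(n_sites: int, fwer: float = 0.05) -> float:
    """Family-wise threshold fwer / n_sites (n_sites = target size in bp)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not (0.0 < fwer < 1.0):
        raise ValueError("fwer must be in (0, 1)")
    return fwer / n_sites


@functools.lru_cache(maxsize=32)
def _bottleneck_matrix(bottleneck_size: int, grid_size: int) -> np.ndarray:
    """grid_size x (B+1) matrix of Binomial(B, f0) masses at the bin centers."""
    centers = ExperimentParams(
        bottleneck_size=bottleneck_size, grid_size=grid_size
    ).bin_centers
    counts = np.arange(bottleneck_size + 1)
    mat = stats.binom.pmf(counts[None, :], bottleneck_size, centers[:, None])
    mat.setflags(write=False)
    return mat


def _founder_pmf(posterior: FrequencyDistribution, params: ExperimentParams) -> np.ndarray:
    """Mix the binomial bottleneck over the early-frequency posterior."""
    mat = _bottleneck_matrix(params.bottleneck_size, params.grid_size)
    pmf = posterior.probabilities @ mat
    return pmf / pmf.sum()


def _late_frequency_probs(
    obs: SiteObservation, params: ExperimentParams, s: float
) -> np.ndarray:
    post = early_frequency_posterior(obs.early_alt, obs.early_total, params)
    founders = _founder_pmf(post, params)
    kernel = growth_kernel_stack(params, s)
    return founders @ kernel


def late_frequency_distribution(
    obs: SiteObservation, params: ExperimentParams, s: float = 0.0
) -> FrequencyDistribution:
    """Predicted law of the true late frequency under selection coefficient s."""
    return FrequencyDistribution(_atom_grid(params), _late_frequency_probs(obs, params, s))


def drift_pvalue(
    obs: SiteObservation,
    params: ExperimentParams | None = None,
    target_bp: int = DEFAULT_TARGET_BP,
    fwer: float = 0.05,
) -> DriftTestResult:
    """One-sided p-value for the observed change under pure genetic drift.

    ``P(late count at least as extreme as observed)`` under the s = 0 chain,
    in the direction of the observed frequency change, compared with the
    Bonferroni threshold ``fwer / target_bp``.
    """
    params = params or ExperimentParams()
    probs = _late_frequency_probs(obs, params, 0.0)
    q = observed_read_prob(_atom_grid(params), params)
    if obs.direction == "gain":
        tail = stats.binom.sf(obs.late_alt - 1, obs.late_total, q)
    else:
        tail = stats.binom.cdf(obs.late_alt, obs.late_total, q)
    p = float(np.clip(probs @ tail, 0.0, 1.0))
    alpha = bonferroni_alpha(target_bp, fwer)
    return DriftTestResult(
        site_id=obs.site_id,
        p_value=p,
        alpha=alpha,
        significant=p < alpha,
        direction=obs.direction,
    )


def selection_likelihood(
    obs: SiteObservation, s: float, params: ExperimentParams | None = None
) -> float:
    """Log-likelihood of the late read count under selection coefficient s."""
    params = params or ExperimentParams()
    probs = _late_frequency_probs(obs, params, s)
    q = observed_read_prob(_atom_grid(params), params)
    pmf = stats.binom.pmf(obs.late_alt, obs.late_total, q)
    return math.log(max(float(probs @ pmf), LOG_FLOOR))


def default_s_grid(step: float = 0.05) -> np.ndarray:
    """Grid of selection coefficients spanning [-1, 1]."""
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = round(2.0 / step)
    return np.round(np.linspace(-1.0, 1.0, n + 1), 10)


def estimate_selection(
    obs: SiteObservation,
    params: ExperimentParams | None = None,
    grid_step: float = 0.05,
) -> SelectionEstimate:
    """Grid-search MLE of s with a 95% likelihood-ratio confidence interval.

    Ties at the maximum resolve toward the smallest ``|s|``; the interval is
    the smallest/largest grid value whose log-likelihood is within the
    chi-square(1) 95% cutoff of the maximum.
    """
    params = params or ExperimentParams()
    post = early_frequency_posterior(obs.early_alt, obs.early_total, params)
    founders = _founder_pmf(post, params)
    q = observed_read_prob(_atom_grid(params), params)
    read_pmf = stats.binom.pmf(obs.late_alt, obs.late_total, q)

    s_grid = default_s_grid(grid_step)
    loglik = np.empty(s_grid.size)
    for k, s in enumerate(s_grid):
        probs = founders @ growth_kernel_stack(params, float(s))
        loglik[k] = math.log(max(float(probs @ read_pmf), LOG_FLOOR))
    if np.all(loglik <= math.log(LOG_FLOOR) + 1.0):
        raise FloatingPointError(
            f"{obs.site_id}: likelihood underflowed over the whole s grid"
        )
    best = loglik.max()
    maximisers = np.flatnonzero(loglik == best)
    k_hat = maximisers[np.argmin(np.abs(s_grid[maximisers]))]
    inside = 2.0 * (best - loglik) <= LRT_CUTOFF_95 + 1e-12
    return SelectionEstimate(
        site_id=obs.site_id,
        s_hat=float(s_grid[k_hat]),
        ci_low=float(s_grid[inside].min()),
        ci_high=float(s_grid[inside].max()),
        profile=tuple(zip(s_grid.tolist(), loglik.tolist())),
    )
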