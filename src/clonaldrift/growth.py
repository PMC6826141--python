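"""Stochastic model of allele-frequency change through a bottleneck and regrowth.

The population model has two stages:

1. **Bottleneck** — B founder cells are drawn binomially from the early
   passage, so the founder mutant-cell count is ``Binomial(B, f0)``.

2. **Growth** — the founders expand to ``B * 2**d`` cells by sequential
   division events.  At every event one cell is chosen to divide with
   probability proportional to its fitness: 1 for wild type, ``1 + s`` for
   mutant carriers.  This is a fitness-biased Pólya urn — equivalently the
   embedded jump chain of two independent Yule (pure-birth) processes with
   rates 1 and ``1 + s`` — and is the "growth transition matrix" of the
   discrete Markov chain the drift test is built on.

The analytic law of the final mutant frequency is computed from the
branching-process limit: a Yule process started from ``i`` cells satisfies
``M(t) e^{-(1+s)t} -> X ~ Gamma(i, 1)`` almost surely, so with
``Y ~ Gamma(B - i, 1)`` for the wild-type side and the stopping condition
``M + W = N`` the final frequency f solves ``X u^{1+s} + Y u = N`` with
``f = X u^{1+s} / N``.  Inverting at a frequency threshold c gives the
closed-form conditional CDF

    P(f <= c | Y) = GammaCDF_i( c (1-c)^{-(1+s)} Y^{1+s} N^{-s} ),

which is averaged over Y by Gauss-Legendre quadrature in probability space.
For s = 0 this reduces exactly to the Beta(i, B - i) law of neutral growth.
For small final populations an exact event-by-event dynamic program over
mutant counts is used instead, and the Monte Carlo simulator
(:func:`simulate_growth`) is the arbiter for both.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .params import ExperimentParams

__all__ = [
    "FounderDistribution",
    "FrequencyDistribution",
    "bottleneck_distribution",
    "growth_distribution",
    "simulate_growth",
    "simulate_growth_many",
    "total_variation",
]

# Final population size up to which growth_distribution uses the exact
# event-by-event dynamic program rather than the branching-process limit.
EXACT_DP_MAX_N = 4096
# Population size up to which simulate_growth runs event-by-event exactly;
# beyond it, growth continues along the deterministic branching flow.
SIMULATE_EXACT_N = 1 << 16

_CHI2_EPS = 1e-12


@dataclass(frozen=True)
class FounderDistribution:
    """Probability mass over founder mutant-cell counts 0..B."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("probabilities must be a 1-D vector of length B+1")
        if np.any(p < -1e-15):
            raise ValueError("founder probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("founder probabilities must sum to 1")

    @property
    def bottleneck_size(self) -> int:
        return self.probabilities.size - 1

    def mean(self) -> float:
        return float(np.arange(self.probabilities.size) @ self.probabilities)


@dataclass(frozen=True)
class FrequencyDistribution:
    """Discrete distribution over mutant-allele frequencies in [0, 1].

    ``grid`` holds the support points (strictly increasing).  Distributions
    produced by :func:`growth_distribution` put their first and last support
    points at exactly 0 and 1 so that extinction and fixation are
    represented as true atoms rather than smeared into the first/last bin.
    """

    grid: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "probabilities", p)
        if g.shape != p.shape or g.ndim != 1:
            raise ValueError("grid and probabilities must be matching 1-D vectors")
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        if g[0] < -1e-15 or g[-1] > 1 + 1e-15:
            raise ValueError("grid must lie within [0, 1]")
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("probabilities must sum to 1")

    def mean(self) -> float:
        return float(self.grid @ self.probabilities)

    def variance(self) -> float:
        m = self.mean()
        return float(((self.grid - m) ** 2) @ self.probabilities)

    def cdf(self, x: float) -> float:
        return float(self.probabilities[self.grid <= x].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.grid, "probability": self.probabilities}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyDistribution":
        df = pd.read_csv(path, sep="\t")
        return cls(df["bin_center"].to_numpy(), df["probability"].to_numpy())


def bottleneck_distribution(
    f0: float, params: ExperimentParams
) -> FounderDistribution:
    """Founder-count law after binomially sampling B cells at frequency f0."""
    if not (0.0 <= f0 <= 1.0):
        raise ValueError(f"f0 must be in [0, 1], got {f0}")
    b = params.bottleneck_size
    pmf = stats.binom.pmf(np.arange(b + 1), b, f0)
    return FounderDistribution(pmf / pmf.sum())


def _check_s(s: float) -> None:
    if not (-1.0 <= s <= 1.0):
        raise ValueError(f"selection coefficient s must be in [-1, 1], got {s}")


@functools.lru_cache(maxsize=512)
def _gamma_quantile_nodes(shape: int, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes in probability space mapped through the Gamma PPF."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (x + 1.0)
    y = stats.gamma.ppf(u, shape)
    return y, 0.5 * w


def _atom_grid(params: ExperimentParams) -> np.ndarray:
    """Support: atom at 0, interior bin centers, atom at 1."""
    return np.concatenate([[0.0], params.bin_centers, [1.0]])


def _growth_probs_limit(
    founders: int, params: ExperimentParams, s: float, n_nodes: int = 128
) -> np.ndarray:
    """Binned final-frequency law from the branching-process limit."""
    b = params.bottleneck_size
    n_final = params.final_size
    if s == 0.0:
        # Neutral growth has the exact closed form Beta(i, B - i); the
        # incomplete-beta routines keep full relative accuracy in both
        # tails, which the drift-null p-values depend on.
        def cdf_at(c: np.ndarray) -> np.ndarray:
            return special.betainc(founders, b - founders, c)

        def sf_at(c: np.ndarray) -> np.ndarray:
            return special.betaincc(founders, b - founders, c)

    else:
        y, w = _gamma_quantile_nodes(b - founders, n_nodes)
        ys = y ** (1.0 + s) * n_final ** (-s)

        def _x(c: np.ndarray) -> np.ndarray:
            return np.outer(c * (1.0 - c) ** (-(1.0 + s)), ys)

        def cdf_at(c: np.ndarray) -> np.ndarray:
            return special.gammainc(founders, _x(c)) @ w

        def sf_at(c: np.ndarray) -> np.ndarray:
            return special.gammaincc(founders, _x(c)) @ w

    # Bin masses are differenced on whichever side of the distribution keeps
    # full relative accuracy: the CDF saturates at 1 in double precision, so
    # far upper-tail masses (p-value territory) must come from the survival
    # function, and symmetrically for the lower tail.
    edges = params.bin_edges
    interior = edges[1:-1]
    cdf = np.concatenate([[0.0], cdf_at(interior), [1.0]])
    sf = np.concatenate([[1.0], sf_at(interior), [0.0]])
    lower = np.diff(cdf)
    upper = -np.diff(sf)
    use_upper = cdf[1:] > 0.5
    pmf = np.where(use_upper, upper, lower)
    # Mass below one cell in the final population is treated as extinction.
    atom0 = float(cdf_at(np.array([1.0 / n_final]))[0])
    out = np.zeros(params.grid_size + 2)
    out[0] = atom0
    out[1:-1] = pmf
    out[1] = max(out[1] - atom0, 0.0)
    np.clip(out, 0.0, None, out=out)
    out /= out.sum()
    return out


def _growth_probs_exact(
    founders: int, params: ExperimentParams, s: float
) -> np.ndarray:
    """Exact event-by-event DP over mutant counts, for small final sizes."""
    b = params.bottleneck_size
    n_final = params.final_size
    pmf = np.zeros(n_final + 1)
    pmf[founders] = 1.0
    m = np.arange(n_final + 1, dtype=float)
    for n in range(b, n_final):
        # all-mutant state: the divider is certainly mutant (0/0 at s = -1)
        with np.errstate(invalid="ignore"):
            div = m[: n + 1] * (1.0 + s) / (n + m[: n + 1] * s)
        div[n] = 1.0
        nxt = np.zeros(n + 2)
        nxt[: n + 1] += pmf[: n + 1] * (1.0 - div)
        nxt[1 : n + 2] += pmf[: n + 1] * div
        pmf[: n + 2] = nxt
    freqs = np.arange(n_final + 1) / n_final
    out = np.zeros(params.grid_size + 2)
    out[0] = pmf[0]
    out[-1] = pmf[-1]
    idx = np.clip(
        np.searchsorted(params.bin_edges, freqs[1:-1], side="right") - 1,
        0,
        params.grid_size - 1,
    )
    np.add.at(out, idx + 1, pmf[1:-1])
    out /= out.sum()
    return out


@functools.lru_cache(maxsize=100_000)
def _growth_probs_cached(
    founders: int,
    s: float,
    bottleneck_size: int,
    divisions: int,
    grid_size: int,
) -> np.ndarray:
    params = ExperimentParams(
        bottleneck_size=bottleneck_size, divisions=divisions, grid_size=grid_size
    )
    n_total = params.grid_size + 2
    if founders == 0:
        out = np.zeros(n_total)
        out[0] = 1.0
    elif founders == bottleneck_size:
        # No wild-type founders: the population stays pure mutant.
        out = np.zeros(n_total)
        out[-1] = 1.0
    elif params.final_size <= EXACT_DP_MAX_N:
        out = _growth_probs_exact(founders, params, s)
    else:
        out = _growth_probs_limit(founders, params, s)
    out.setflags(write=False)
    return out


def growth_distribution(
    founders: int, params: ExperimentParams, s: float = 0.0
) -> FrequencyDistribution:
    """Law of the mutant frequency after growth from ``founders`` mutant cells.

    Under s = 0 the mean equals ``founders / B`` (the neutral process is a
    martingale) and the law converges to Beta(founders, B - founders).
    """
    _check_s(s)
    if not (0 <= founders <= params.bottleneck_size):
        raise ValueError(
            f"founders must be in 0..{params.bottleneck_size}, got {founders}"
        )
    probs = _growth_probs_cached(
        int(founders),
        float(s),
        params.bottleneck_size,
        params.divisions,
        params.grid_size,
    )
    return FrequencyDistribution(_atom_grid(params), probs)


def growth_kernel_stack(params: ExperimentParams, s: float) -> np.ndarray:
    """(B+1) x (grid_size+2) matrix of growth laws for every founder count.

    Row i is the binned final-frequency law from i mutant founders; mixing a
    founder distribution through the stack is a single matrix-vector product.
    """
    _check_s(s)
    return np.vstack(
        [
            _growth_probs_cached(
                i, float(s), params.bottleneck_size, params.divisions, params.grid_size
            )
            for i in range(params.bottleneck_size + 1)
        ]
    )


def _branching_continuation(
    m: np.ndarray, w: np.ndarray, s: float, n_final: int
) -> np.ndarray:
    """Deterministic frequency at total size n_final given (m, w) mid-growth.

    Solves ``m e^{(1+s)t} + w e^t = n_final`` for t by Newton iteration on the
    (convex, increasing) log-population function and returns the mutant share.
    """
    m = m.astype(float)
    w = w.astype(float)
    out = np.empty_like(m)
    pure0 = m == 0
    pure1 = w == 0
    mixed = ~(pure0 | pure1)
    out[pure0] = 0.0
    out[pure1] = 1.0
    if np.any(mixed):
        mm, wm = m[mixed], w[mixed]
        t = np.log(n_final / (mm + wm))
        for _ in range(60):
            gm = mm * np.exp((1.0 + s) * t)
            gw = wm * np.exp(t)
            h = gm + gw - n_final
            dh = (1.0 + s) * gm + gw
            step = h / dh
            t = t - step
            if np.max(np.abs(step)) < 1e-13:
                break
        gm = mm * np.exp((1.0 + s) * t)
        out[mixed] = gm / n_final
    return out


def simulate_growth_many(
    founders: np.ndarray,
    params: ExperimentParams,
    s: float,
    seed: int,
    exact_to: int = SIMULATE_EXACT_N,
) -> np.ndarray:
    """Simulate one growth trajectory per entry of ``founders``.

    Division events are drawn exactly (one Bernoulli per event, vectorised
    across replicates) until the population reaches ``min(final, exact_to)``
    cells; any remaining growth follows the deterministic branching flow,
    whose neglected drift is below the frequency-grid resolution (see
    docs/methods.md).  Identical seeds give identical output.
    """
    _check_s(s)
    founders = np.asarray(founders, dtype=np.int64)
    if np.any((founders < 0) | (founders > params.bottleneck_size)):
        raise ValueError("founders out of range")
    rng = np.random.default_rng(seed)
    b = params.bottleneck_size
    n_final = params.final_size
    n_stop = min(n_final, exact_to)
    m = founders.astype(np.float64)
    for n in range(b, n_stop):
        with np.errstate(invalid="ignore"):
            div = np.where(m == n, 1.0, m * (1.0 + s) / (n + m * s))
        m += rng.random(m.size) < div
    if n_stop >= n_final:
        return m / n_final
    return _branching_continuation(m, n_stop - m, s, n_final)


def simulate_growth(
    founders: int,
    params: ExperimentParams,
    s: float,
    replicates: int,
    seed: int,
    exact_to: int = SIMULATE_EXACT_N,
) -> np.ndarray:
    """Monte Carlo oracle: final mutant frequencies for ``replicates`` runs."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    arr = np.full(replicates, founders, dtype=np.int64)
    return simulate_growth_many(arr, params, s, seed, exact_to=exact_to)


def total_variation(
    dist: FrequencyDistribution, samples: np.ndarray, n_bins: int = 16
) -> float:
    """TV distance between an analytic law and an empirical sample.

    Both are coarsened onto ``n_bins`` equal-mass bins of the analytic
    distribution so the comparison is not dominated by per-bin Monte Carlo
    noise on a fine grid.
    """
    samples = np.asarray(samples, dtype=float)
    # Snap samples to the distribution's support (nearest grid point) so the
    # discrete law and the empirical law live on identical atoms.
    mids = 0.5 * (dist.grid[:-1] + dist.grid[1:])
    # side='right' so values exactly on a boundary bin upward, matching the
    # edge convention of the analytic binning.
    idx = np.searchsorted(mids, samples, side="right")
    emp_fine = np.bincount(idx, minlength=dist.grid.size) / samples.size
    # Coarsen both onto equal-mass groups of the analytic distribution.
    p = dist.probabilities
    cum_mid = np.cumsum(p) - p / 2.0
    group = np.minimum((cum_mid * n_bins).astype(int), n_bins - 1)
    p_coarse = np.bincount(group, weights=p, minlength=n_bins)
    e_coarse = np.bincount(group, weights=emp_fine, minlength=n_bins)
    return 0.5 * float(np.abs(p_coarse - e_coarse).sum())
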