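"""Forward simulation of complete paired-passage sequencing experiments.

Generates, with known ground truth, everything the other modules consume:
per-site pileup tables for both passages, the site table of early/late
alternate counts at planted variant sites, and a truth table.  The default
geometry mirrors the study design the model targets: a ~290 kb target
region, mean depth 1656x (log-normal dispersion spanning the reported
661-2856x range), a 200-cell bottleneck and 13-17 doublings of regrowth,
and Q30-floored sequencing error (epsilon = 1e-3, uniform over the three
non-reference bases).

Planted variants follow the full generative chain (true early frequency ->
binomial bottleneck -> fitness-biased growth with their selection
coefficient -> read sampling); a variant may instead pin ``late_freq``
directly, which is convenient for screen-recovery tests where the true
late frequency must be controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import simulate_growth_many
from .inference import observed_read_prob
from .mixtures import MixtureSpec
from .params import ExperimentParams

__all__ = [
    "VariantSpec",
    "TruthConfig",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_doped_library",
]

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantSpec:
    """A planted somatic variant: position index, early frequency, fitness."""

    site_index: int
    early_freq: float
    s: float = 0.0
    late_freq: float | None = None  # pin the true late frequency if set

    def __post_init__(self) -> None:
        if not (0.0 <= self.early_freq <= 1.0):
            raise ValueError("early_freq must be in [0, 1]")
        if not (-1.0 <= self.s <= 1.0):
            raise ValueError("s must be in [-1, 1]")
        if self.late_freq is not None and not (0.0 <= self.late_freq <= 1.0):
            raise ValueError("late_freq must be in [0, 1]")


@dataclass(frozen=True)
class TruthConfig:
    """Geometry of one synthetic experiment."""

    n_sites: int = 290_000
    variants: tuple = ()
    mean_depth: float = 1656.0
    depth_sd_log: float = 0.25  # 0 -> constant depth
    params: ExperimentParams = field(default_factory=ExperimentParams)
    phred: int = 30
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.mean_depth < 1:
            raise ValueError("n_sites and mean_depth must be >= 1")
        idx = [v.site_index for v in self.variants]
        if len(idx) != len(set(idx)):
            raise ValueError("variant site indices must be unique")
        if any(i < 0 or i >= self.n_sites for i in idx):
            raise ValueError("variant site_index out of range")


@dataclass
class SimulatedExperiment:
    site_table: pd.DataFrame
    early_pileup: pd.DataFrame
    late_pileup: pd.DataFrame
    truth: pd.DataFrame


def _draw_depths(rng, n: int, mean: float, sd_log: float) -> np.ndarray:
    if sd_log <= 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    mu = np.log(mean) - sd_log**2 / 2.0
    d = np.maximum(np.rint(rng.lognormal(mu, sd_log, size=n)), 1.0)
    return d.astype(np.int64)


def _error_counts(rng, depth: np.ndarray, eps: float) -> np.ndarray:
    """(n, 3) error-read counts toward the three non-reference bases."""
    total = rng.binomial(depth, eps)
    a = rng.binomial(total, 1.0 / 3.0)
    b = rng.binomial(total - a, 0.5)
    return np.stack([a, b, total - a - b], axis=1)


def _pileup(
    rng,
    config: TruthConfig,
    refs: np.ndarray,
    alt_choice: np.ndarray,
    depth: np.ndarray,
    var_idx: np.ndarray,
    var_freq: np.ndarray,
) -> pd.DataFrame:
    """Emit one passage's pileup given true variant frequencies per site."""
    eps = config.params.seq_error
    n = config.n_sites
    counts = np.zeros((n, 4), dtype=np.int64)
    err = _error_counts(rng, depth, eps)
    # scatter error counts onto the three non-ref columns of each site
    for r in range(4):
        mask = refs == r
        non_ref = [c for c in range(4) if c != r]
        counts[np.ix_(mask, non_ref)] = err[mask]
    if var_idx.size:
        q = observed_read_prob(var_freq, config.params)
        alt_reads = rng.binomial(depth[var_idx], q)
        counts[var_idx, alt_choice[var_idx]] = alt_reads
    ref_reads = depth - counts.sum(axis=1)
    # extreme error draws could exceed depth at tiny depths; clamp at zero
    ref_reads = np.maximum(ref_reads, 0)
    counts[np.arange(n), refs] = ref_reads
    df = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": np.arange(1, n + 1),
            "ref": np.array(BASES)[refs],
        }
    )
    for j, b in enumerate(BASES):
        df[f"count_{b}"] = counts[:, j]
    return df


def simulate_experiment(config: TruthConfig) -> SimulatedExperiment:
    """Simulate one full paired-passage experiment; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    refs = rng.integers(0, 4, size=n)
    # each site's designated alternate allele (used only where a variant sits)
    alt_choice = (refs + rng.integers(1, 4, size=n)) % 4

    depth_e = _draw_depths(rng, n, config.mean_depth, config.depth_sd_log)
    depth_l = _draw_depths(rng, n, config.mean_depth, config.depth_sd_log)

    variants = list(config.variants)
    var_idx = np.array([v.site_index for v in variants], dtype=np.int64)
    f_early = np.array([v.early_freq for v in variants], dtype=float)

    f_late = np.empty(len(variants))
    pinned = np.array([v.late_freq is not None for v in variants], dtype=bool)
    f_late[pinned] = [v.late_freq for v in variants if v.late_freq is not None]
    free = np.flatnonzero(~pinned)
    if free.size:
        b = config.params.bottleneck_size
        founders = rng.binomial(b, f_early[free])
        for s_val in np.unique([variants[i].s for i in free]):
            grp = np.array([i for i in free if variants[i].s == s_val])
            f_late[grp] = simulate_growth_many(
                founders[np.searchsorted(free, grp)],
                config.params,
                float(s_val),
                seed=int(rng.integers(2**31 - 1)),
            )

    early = _pileup(rng, config, refs, alt_choice, depth_e, var_idx, f_early)
    late = _pileup(rng, config, refs, alt_choice, depth_l, var_idx, f_late)

    alt_bases = np.array(BASES)[alt_choice]
    site_ids = [
        f"{config.chrom}:{i + 1}:{alt_bases[i]}" for i in var_idx
    ]
    site_table = pd.DataFrame(
        {
            "site_id": site_ids,
            "early_alt": [
                early.at[i, f"count_{alt_bases[i]}"] for i in var_idx
            ],
            "early_total": depth_e[var_idx],
            "late_alt": [late.at[i, f"count_{alt_bases[i]}"] for i in var_idx],
            "late_total": depth_l[var_idx],
        }
    )
    truth = pd.DataFrame(
        {
            "site_id": site_ids,
            "alt": alt_bases[var_idx],
            "true_s": [v.s for v in variants],
            "true_early_freq": f_early,
            "true_late_freq": f_late,
        }
    )
    return SimulatedExperiment(site_table, early, late, truth)


def simulate_doped_library(spec: MixtureSpec, seed: int) -> pd.DataFrame:
    """Pileup of a host+dope mixed library; deterministic per seed.

    Each read samples a template allele from the mixture frequencies
    ``(1 - fraction) * host + fraction * dope`` and is miscalled with
    probability epsilon, uniformly toward the other three bases.
    """
    rng = np.random.default_rng(seed)
    eps = spec.params.seq_error
    base_idx = {b: i for i, b in enumerate(BASES)}
    n = len(spec.host)
    freq = np.zeros((n, 4))
    for tbl, wt in ((spec.host, 1.0 - spec.dope_fraction), (spec.dope, spec.dope_fraction)):
        for col in ("allele1", "allele2"):
            idx = tbl[col].map(base_idx).to_numpy()
            freq[np.arange(n), idx] += wt / 2.0
    # sequencing-error channel: true base survives w.p. 1-eps
    read_prob = freq * (1.0 - eps) + (1.0 - freq) * eps / 3.0
    read_prob /= read_prob.sum(axis=1, keepdims=True)

    depth = np.full(n, spec.depth, dtype=np.int64)
    counts = np.zeros((n, 4), dtype=np.int64)
    remaining = depth.copy()
    residual = np.ones(n)
    for j in range(3):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(residual > 1e-300, read_prob[:, j] / residual, 0.0)
        p = np.clip(p, 0.0, 1.0)
        counts[:, j] = rng.binomial(remaining, p)
        remaining -= counts[:, j]
        residual -= read_prob[:, j]
    counts[:, 3] = remaining

    df = pd.DataFrame({"site_id": spec.host["site_id"].to_numpy()})
    for j, b in enumerate(BASES):
        df[f"count_{b}"] = counts[:, j]
    return df
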