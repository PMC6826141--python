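"""Empirical somatic-variant screen on paired-passage pileup summaries.

The screen re-implements the two-step discovery procedure for variants whose
frequency changed between passages ("SM-Vs"):

(a) quality-aware calling — at each site and alternate allele, the p-value
    that the observed alternate-read count arose from sequencing error alone,
    from the Poisson-binomial law of per-read phred error probabilities,
    compared against a Bonferroni-corrected threshold over the screened
    target;
(b) passage uniqueness — alleles called in one passage are discarded if the
    same allele is detectably present (relaxed, uncorrected call) in the
    other passage; alleles present in both passages instead pass through an
    outlier rule that flags between-passage frequency differences more than
    3 standard deviations above the mean across shared sites.

Candidates are then restricted to sites whose host genotype looks homozygous
reference, filtered by a minimum alternate-read count, merged into
dinucleotide events when adjacent, and dropped when a 50 bp neighbourhood
holds an excess of other candidates.

Pileups are exchanged as columnar tables (pandas DataFrames with columns
``chrom, pos, ref, count_A..count_T`` and optional per-allele quality lists
``quals_A..quals_T``); :class:`PileupSite` is the per-site record for the
scalar API.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BASES",
    "PileupSite",
    "SMVRecord",
    "ScreenThresholds",
    "poisson_binomial_call",
    "screen_pair",
    "shared_site_outliers",
    "neighborhood_filter",
    "classify_substitution",
    "pileup_frame",
]

BASES = ("A", "C", "G", "T")
COUNT_COLS = tuple(f"count_{b}" for b in BASES)
QUAL_COLS = tuple(f"quals_{b}" for b in BASES)
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
UV_SIGNATURE = {("CC", "TT"), ("GG", "AA")}


@dataclass(frozen=True)
class PileupSite:
    """Per-allele read counts (with optional phred qualities) at one site."""

    chrom: str
    pos: int
    ref: str
    counts: dict
    quals: dict | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise ValueError(f"ref must be one of {BASES}, got {self.ref!r}")
        for b in BASES:
            if self.counts.get(b, 0) < 0:
                raise ValueError("counts must be non-negative")
        if self.quals is not None:
            for b, qs in self.quals.items():
                if any(q < 0 or q > 60 for q in qs):
                    raise ValueError("phred qualities must lie in [0, 60]")

    @property
    def depth(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES)


@dataclass
class SMVRecord:
    """One discovered variant with changing frequency between passages."""

    site_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    passage_detected: str  # 'early' | 'late' | 'both'
    early_alt: int
    early_total: int
    late_alt: int
    late_total: int
    substitution_class: str = ""
    dinucleotide: bool = False
    p_early: float = 1.0
    p_late: float = 1.0

    @property
    def early_freq(self) -> float:
        return self.early_alt / self.early_total if self.early_total else 0.0

    @property
    def late_freq(self) -> float:
        return self.late_alt / self.late_total if self.late_total else 0.0


@dataclass(frozen=True)
class ScreenThresholds:
    """Tunable thresholds of the screen.

    ``call_alpha`` is divided by ``bonferroni_sites`` (by default the number
    of screened sites) before comparison, mirroring quality-aware callers
    that correct for the number of tested positions; ``presence_alpha`` is
    the relaxed, uncorrected level used only to decide whether an allele is
    detectably present in the other passage.
    """

    call_alpha: float = 0.01
    bonferroni_sites: int | None = None
    presence_alpha: float = 0.01
    min_alt_count: int = 3
    hom_ref_fraction: float = 0.98
    outlier_sd: float = 3.0
    window_bp: int = 50
    max_neighbors: int = 1
    base_quality: int = 30  # assumed phred when a pileup carries no qualities


def poisson_binomial_call(alt_count: int, qualities) -> float:
    """P(at least ``alt_count`` reads show this allele by sequencing error).

    ``qualities`` are the phred scores of all reads piled on the site (both
    reference- and alternate-supporting); read r is miscalled toward the
    specific alternate base with probability ``10**(-Q_r/10) / 3``.  The tail
    probability of the Poisson-binomial error count is computed by exact
    dynamic-programming convolution, truncated at ``alt_count`` successes.
    """
    qualities = np.asarray(qualities, dtype=float)
    if qualities.size == 0:
        raise ValueError("empty pileup: no read qualities")
    if alt_count > qualities.size:
        raise ValueError("alt_count cannot exceed the number of reads")
    if alt_count <= 0:
        return 1.0
    probs = 10.0 ** (-qualities / 10.0) / 3.0
    uniq = np.unique(probs)
    if uniq.size == 1:  # homogeneous qualities: plain binomial tail
        return float(stats.binom.sf(alt_count - 1, probs.size, uniq[0]))
    # pmf[j] = P(j error reads so far), tracked only for j < alt_count
    pmf = np.zeros(alt_count)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1.0 - p) + pmf[:-1] * p
        pmf[0] *= 1.0 - p
    return float(max(0.0, 1.0 - pmf.sum()))


def _binom_call_pvalues(counts: np.ndarray, depth: np.ndarray, per_read_err: float) -> np.ndarray:
    """Vectorised constant-quality calling p-values (P(X >= count))."""
    p = np.ones_like(counts, dtype=float)
    mask = counts > 0
    p[mask] = stats.binom.sf(counts[mask] - 1, depth[mask], per_read_err)
    return p


def classify_substitution(ref: str, alt: str) -> str:
    """'transition', 'transversion', or 'dinucleotide' for tandem events."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != len(alt) or len(ref) not in (1, 2):
        raise ValueError("ref and alt must both be 1 or 2 bases")
    if any(b not in BASES for b in ref + alt):
        raise ValueError("ref and alt must be ACGT strings")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if len(ref) == 2:
        return "dinucleotide"
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


def is_uv_signature(ref: str, alt: str) -> bool:
    """True for the tandem CC>TT / GG>AA class typical of UV damage."""
    return (ref.upper(), alt.upper()) in UV_SIGNATURE


def shared_site_outliers(early_freq, late_freq, site_ids=None, n_sd: float = 3.0):
    """Indices (or ids) of shared variants whose |delta frequency| is extreme.

    A site is flagged when its absolute between-passage frequency difference
    exceeds ``mean + n_sd * SD`` of the differences across all shared sites.
    """
    early_freq = np.asarray(early_freq, dtype=float)
    late_freq = np.asarray(late_freq, dtype=float)
    if early_freq.size != late_freq.size:
        raise ValueError("early and late frequency vectors must match")
    if early_freq.size < 2:
        warnings.warn(
            "fewer than 2 shared variant sites: outlier rule not applicable",
            stacklevel=2,
        )
        return []
    delta = np.abs(late_freq - early_freq)
    cutoff = delta.mean() + n_sd * delta.std(ddof=0)
    flagged = np.flatnonzero(delta > cutoff)
    if site_ids is not None:
        site_ids = list(site_ids)
        return [site_ids[i] for i in flagged]
    return flagged.tolist()


def _merge_dinucleotides(records: list[SMVRecord]) -> list[SMVRecord]:
    """Merge candidates at adjacent positions into single tandem events."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    out: list[SMVRecord] = []
    i = 0
    while i < len(records):
        r = records[i]
        if (
            i + 1 < len(records)
            and records[i + 1].chrom == r.chrom
            and records[i + 1].pos == r.pos + 1
            and records[i + 1].passage_detected == r.passage_detected
            and len(r.ref) == 1
            and len(records[i + 1].ref) == 1
        ):
            nxt = records[i + 1]
            merged = SMVRecord(
                site_id=f"{r.chrom}:{r.pos}:{r.alt}{nxt.alt}",
                chrom=r.chrom,
                pos=r.pos,
                ref=r.ref + nxt.ref,
                alt=r.alt + nxt.alt,
                passage_detected=r.passage_detected,
                early_alt=min(r.early_alt, nxt.early_alt),
                early_total=min(r.early_total, nxt.early_total),
                late_alt=min(r.late_alt, nxt.late_alt),
                late_total=min(r.late_total, nxt.late_total),
                substitution_class="dinucleotide",
                dinucleotide=True,
                p_early=max(r.p_early, nxt.p_early),
                p_late=max(r.p_late, nxt.p_late),
            )
            out.append(merged)
            i += 2
        else:
            out.append(r)
            i += 1
    return out


def neighborhood_filter(
    candidates: list[SMVRecord], window_bp: int = 50, max_neighbors: int = 1
) -> list[SMVRecord]:
    """Drop candidates with an excess of other candidates within +-window_bp.

    Adjacent-position pairs are first merged into single dinucleotide events
    so a tandem mutation does not veto itself.
    """
    merged = _merge_dinucleotides(candidates)
    kept = []
    for r in merged:
        span = len(r.ref) - 1
        neighbors = sum(
            1
            for o in merged
            if o is not r
            and o.chrom == r.chrom
            and not (o.pos > r.pos + span + window_bp or o.pos + len(o.ref) - 1 < r.pos - window_bp)
        )
        if neighbors <= max_neighbors:
            kept.append(r)
    return kept


def pileup_frame(sites: list[PileupSite] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a pileup (list of sites or DataFrame) to the columnar form."""
    if isinstance(sites, pd.DataFrame):
        missing = [c for c in ("chrom", "pos", "ref", *COUNT_COLS) if c not in sites]
        if missing:
            raise ValueError(f"pileup table missing columns: {missing}")
        return sites.reset_index(drop=True)
    rows = []
    for s in sites:
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref}
        for b in BASES:
            row[f"count_{b}"] = s.counts.get(b, 0)
            if s.quals is not None:
                row[f"quals_{b}"] = tuple(s.quals.get(b, ()))
        rows.append(row)
    return pd.DataFrame(rows)


def _site_quals(row, base_quality: int) -> np.ndarray:
    """All read qualities piled on a site, from explicit lists or constant Q."""
    chunks = []
    for b in BASES:
        col = f"quals_{b}"
        qs = row.get(col) if hasattr(row, "get") else None
        n = int(row[f"count_{b}"])
        if qs is not None and not (isinstance(qs, float) and np.isnan(qs)):
            chunks.append(np.asarray(qs, dtype=float))
        elif n:
            chunks.append(np.full(n, float(base_quality)))
    return np.concatenate(chunks) if chunks else np.empty(0)


def _has_explicit_quals(df: pd.DataFrame) -> bool:
    return any(c in df.columns for c in QUAL_COLS)


def screen_pair(
    early, late, thresholds: ScreenThresholds | None = None
) -> list[SMVRecord]:
    """Run the full paired-passage screen; returns the retained SM-V records.

    Both pileups must cover the same sites in the same order.  The screen is
    symmetric in the passage labels: swapping them swaps ``passage_detected``
    without changing the discovered site set.
    """
    th = thresholds or ScreenThresholds()
    early = pileup_frame(early)
    late = pileup_frame(late)
    if len(early) != len(late) or not (
        early["pos"].to_numpy() == late["pos"].to_numpy()
    ).all() or not (early["chrom"].to_numpy() == late["chrom"].to_numpy()).all():
        raise ValueError("early and late pileups must cover identical sites")
    if not (early["ref"].to_numpy() == late["ref"].to_numpy()).all():
        raise ValueError("reference alleles disagree between passages")

    n_sites = len(early)
    tau = th.call_alpha / (th.bonferroni_sites or n_sites)
    per_read_err = 10.0 ** (-th.base_quality / 10.0) / 3.0

    depth_e = early[list(COUNT_COLS)].to_numpy().sum(axis=1)
    depth_l = late[list(COUNT_COLS)].to_numpy().sum(axis=1)
    ref = early["ref"].to_numpy()
    explicit_e = _has_explicit_quals(early)
    explicit_l = _has_explicit_quals(late)

    single: list[SMVRecord] = []
    shared: list[SMVRecord] = []
    for b in BASES:
        alt_mask = ref != b
        ce = early[f"count_{b}"].to_numpy()
        cl = late[f"count_{b}"].to_numpy()
        if explicit_e:
            pe = np.array(
                [
                    poisson_binomial_call(int(c), _site_quals(early.iloc[i], th.base_quality))
                    if c > 0
                    else 1.0
                    for i, c in enumerate(ce)
                ]
            )
        else:
            pe = _binom_call_pvalues(ce, depth_e, per_read_err)
        if explicit_l:
            pl = np.array(
                [
                    poisson_binomial_call(int(c), _site_quals(late.iloc[i], th.base_quality))
                    if c > 0
                    else 1.0
                    for i, c in enumerate(cl)
                ]
            )
        else:
            pl = _binom_call_pvalues(cl, depth_l, per_read_err)

        called_e = alt_mask & (pe < tau)
        called_l = alt_mask & (pl < tau)
        present_e = alt_mask & (pe < th.presence_alpha)
        present_l = alt_mask & (pl < th.presence_alpha)

        def _record(i: int, detected: str) -> SMVRecord:
            return SMVRecord(
                site_id=f"{early.at[i, 'chrom']}:{int(early.at[i, 'pos'])}:{b}",
                chrom=str(early.at[i, "chrom"]),
                pos=int(early.at[i, "pos"]),
                ref=str(ref[i]),
                alt=b,
                passage_detected=detected,
                early_alt=int(ce[i]),
                early_total=int(depth_e[i]),
                late_alt=int(cl[i]),
                late_total=int(depth_l[i]),
                substitution_class=classify_substitution(str(ref[i]), b),
                p_early=float(pe[i]),
                p_late=float(pl[i]),
            )

        for i in np.flatnonzero(called_e & ~present_l):
            single.append(_record(int(i), "early"))
        for i in np.flatnonzero(called_l & ~present_e):
            single.append(_record(int(i), "late"))
        for i in np.flatnonzero((called_e | called_l) & present_e & present_l):
            shared.append(_record(int(i), "both"))

    # Rule (b) complement: shared variants survive only via the outlier rule.
    if len(shared) >= 2:
        flagged = shared_site_outliers(
            [r.early_freq for r in shared],
            [r.late_freq for r in shared],
            n_sd=th.outlier_sd,
        )
        single.extend(shared[i] for i in flagged)
    candidates = single

    def _hom_ref(r: SMVRecord) -> bool:
        # Germline gate: the lower-frequency passage must look homozygous ref.
        if r.early_freq <= r.late_freq:
            return 1.0 - r.early_freq >= th.hom_ref_fraction
        return 1.0 - r.late_freq >= th.hom_ref_fraction

    def _min_count(r: SMVRecord) -> bool:
        if r.passage_detected == "early":
            return r.early_alt >= th.min_alt_count
        if r.passage_detected == "late":
            return r.late_alt >= th.min_alt_count
        return max(r.early_alt, r.late_alt) >= th.min_alt_count

    candidates = [r for r in candidates if _hom_ref(r) and _min_count(r)]
    return neighborhood_filter(candidates, th.window_bp, th.max_neighbors)
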