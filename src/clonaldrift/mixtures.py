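"""Sensitivity/specificity evaluation of low-frequency variant detection.

Emulates the doped-mixture control: DNA from a "dope" individual is mixed
into a "host" individual's DNA at a small fraction, the library is
sequenced deep, and alternate alleles of the dope genotype are expected at
frequency ``dope_fraction * copies / 2`` wherever the host is homozygous
and the dope carries a different allele.  Sensitivity is the fraction of
expected variant sites detected; specificity is the fraction of
no-variant-expected sites with no detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ExperimentParams

__all__ = [
    "MixtureSpec",
    "ExpectedSite",
    "DetectionMetrics",
    "expected_variant_sites",
    "sensitivity_specificity",
    "evaluate_mixture",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Host/dope genotype tables plus mixing fraction and depth model.

    Genotype tables are DataFrames with columns ``site_id, allele1, allele2``
    over a shared site universe.
    """

    host: pd.DataFrame
    dope: pd.DataFrame
    dope_fraction: float
    depth: int = 2000
    params: ExperimentParams = field(default_factory=ExperimentParams)

    def __post_init__(self) -> None:
        if not (0.0 < self.dope_fraction < 0.5):
            raise ValueError("dope_fraction must be in (0, 0.5)")
        for name, df in (("host", self.host), ("dope", self.dope)):
            missing = {"site_id", "allele1", "allele2"} - set(df.columns)
            if missing:
                raise ValueError(f"{name} genotype table missing {missing}")
        if not self.host["site_id"].tolist() == self.dope["site_id"].tolist():
            raise ValueError("host and dope genotype tables must share a site universe")


@dataclass(frozen=True)
class ExpectedSite:
    site_id: str
    alt: str
    expected_freq: float


def expected_variant_sites(spec: MixtureSpec) -> list[ExpectedSite]:
    """Sites where the dope contributes an allele the homozygous host lacks.

    Only host-homozygous sites are eligible; the expected alternate-allele
    frequency is ``dope_fraction * copies / 2`` where copies is the number of
    dope allele copies differing from the host allele.
    """
    out: list[ExpectedSite] = []
    for h, d in zip(self_rows(spec.host), self_rows(spec.dope)):
        if h.allele1 != h.allele2:
            continue  # host heterozygous: excluded from the evaluation
        host_allele = h.allele1
        for alt in {d.allele1, d.allele2} - {host_allele}:
            copies = (d.allele1 == alt) + (d.allele2 == alt)
            out.append(
                ExpectedSite(
                    site_id=h.site_id,
                    alt=alt,
                    expected_freq=spec.dope_fraction * copies / 2.0,
                )
            )
    return out


def self_rows(df: pd.DataFrame):
    return df.itertuples(index=False)


@dataclass(frozen=True)
class DetectionMetrics:
    sensitivity: float
    specificity: float
    true_positives: int
    false_negatives: int
    false_positives: int
    true_negatives: int


def sensitivity_specificity(called: set, expected: set, eligible: set) -> DetectionMetrics:
    """Detection metrics over site identifiers.

    sensitivity = |called & expected| / |expected|;
    specificity = |eligible \\ (called | expected)| / |eligible \\ expected|.
    """
    called, expected, eligible = set(called), set(expected), set(eligible)
    if not expected <= eligible:
        raise ValueError("expected sites must be a subset of eligible sites")
    tp = len(called & expected)
    fn = len(expected - called)
    negatives = eligible - expected
    fp = len(called & negatives)
    tn = len(negatives - called)
    if expected:
        sens = tp / len(expected)
    else:
        warnings.warn("no expected variant sites: sensitivity undefined", stacklevel=2)
        sens = math.nan
    spec = tn / len(negatives) if negatives else math.nan
    return DetectionMetrics(
        sensitivity=sens,
        specificity=spec,
        true_positives=tp,
        false_negatives=fn,
        false_positives=fp,
        true_negatives=tn,
    )


def evaluate_mixture(
    spec: MixtureSpec, seed: int, min_alt_reads: int = 1
) -> DetectionMetrics:
    """Simulate the doped library and score detection against expectation.

    Detection uses the pileup presence rule used for the mixture controls
    (alternate-read count >= ``min_alt_reads`` at host-homozygous sites),
    not the paired-passage screen's corrected threshold.
    """
    from .simulate import simulate_doped_library  # local import avoids a cycle

    pileup = simulate_doped_library(spec, seed)
    expected = {(e.site_id, e.alt) for e in expected_variant_sites(spec)}

    host_hom = {
        r.site_id: r.allele1
        for r in self_rows(spec.host)
        if r.allele1 == r.allele2
    }
    called: set = set()
    eligible: set = set()
    for row in pileup.itertuples(index=False):
        sid = row.site_id
        if sid not in host_hom:
            continue
        for b in "ACGT":
            if b == host_hom[sid]:
                continue
            eligible.add((sid, b))
            if getattr(row, f"count_{b}") >= min_alt_reads:
                called.add((sid, b))
    return sensitivity_specificity(called, expected, eligible)
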