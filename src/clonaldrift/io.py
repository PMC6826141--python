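"""Readers and writers for the package's TSV dialects.

Formats:

* **site table** — ``site_id  early_alt  early_total  late_alt  late_total``;
  one row per candidate site, counts as integers.
* **results table** — the site table plus test/estimate columns
  (``p_value, alpha, significant, direction, s_hat, ci_low, ci_high``);
  p-values are printed in scientific notation with 3 significant digits and
  a YAML sidecar records parameters, seed and version so any results file
  can be regenerated from its inputs.
* **pileup table** — ``chrom  pos  ref  count_A..count_T`` plus optional
  comma-separated per-allele quality columns ``quals_A..quals_T``.
* **SM-V export** — results of the screen as TSV or minimal VCF with
  ``AF_EARLY`` / ``AF_LATE`` INFO fields.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import SiteObservation
from .params import ExperimentParams
from .screen import BASES, SMVRecord

__all__ = [
    "read_site_table",
    "write_site_table",
    "write_results",
    "read_results",
    "read_pileup",
    "write_pileup",
    "write_smv_table",
    "write_smv_vcf",
]

SITE_COLUMNS = ("site_id", "early_alt", "early_total", "late_alt", "late_total")
RESULT_COLUMNS = SITE_COLUMNS + (
    "p_value",
    "alpha",
    "significant",
    "direction",
    "s_hat",
    "ci_low",
    "ci_high",
)


def read_site_table(path: str | Path) -> list[SiteObservation]:
    """Read and validate a site table; errors name the offending row/field."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = {}
        for col in SITE_COLUMNS[1:]:
            raw = getattr(row, col)
            try:
                vals[col] = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {row_no}, field {col!r}: not an integer ({raw!r})"
                ) from None
        try:
            out.append(SiteObservation(site_id=row.site_id, **vals))
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from None
    return out


def write_site_table(observations, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "site_id": o.site_id,
                "early_alt": o.early_alt,
                "early_total": o.early_total,
                "late_alt": o.late_alt,
                "late_total": o.late_total,
            }
            for o in observations
        ],
        columns=list(SITE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def _fmt_p(p: float) -> str:
    return f"{p:.2e}"


def write_results(
    results: pd.DataFrame,
    path: str | Path,
    params: ExperimentParams | None = None,
    seed: int | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write a results table with deterministic column order plus a sidecar.

    ``results`` holds the site-table columns and whichever of the analysis
    columns were computed; the sidecar (``<path>.meta.yaml``) records the
    parameters, seed and package version.
    """
    if results is None:
        raise ValueError("results must not be None")
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    out = results.loc[:, cols].copy()
    for col in ("p_value", "alpha"):
        if col in out.columns:
            out[col] = out[col].map(_fmt_p)
    out.to_csv(path, sep="\t", index=False)
    meta = {
        "version": __version__,
        "seed": seed,
        "parameters": params.to_dict() if params is not None else None,
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("p_value", "alpha"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df


def write_pileup(pileup: pd.DataFrame, path: str | Path) -> None:
    df = pileup.copy()
    for b in BASES:
        col = f"quals_{b}"
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: ",".join(str(int(q)) for q in v) if isinstance(v, (list, tuple)) else ""
            )
    df.to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "pos", "ref"] + [f"count_{b}" for b in BASES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pileup columns {missing}")
    for b in BASES:
        col = f"quals_{b}"
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: tuple(int(x) for x in str(v).split(","))
                if isinstance(v, str) and v
                else ()
            )
    return df


def write_smv_table(records: list[SMVRecord], path: str | Path) -> None:
    rows = [asdict(r) for r in records]
    cols = [
        "site_id",
        "chrom",
        "pos",
        "ref",
        "alt",
        "passage_detected",
        "early_alt",
        "early_total",
        "late_alt",
        "late_total",
        "substitution_class",
        "dinucleotide",
        "p_early",
        "p_late",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_smv_vcf(records: list[SMVRecord], path: str | Path) -> None:
    """Minimal VCF export of screen hits (1-based inclusive coordinates)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=clonaldrift-{__version__}",
        '##INFO=<ID=AF_EARLY,Number=1,Type=Float,Description="Variant allele frequency, early passage">',
        '##INFO=<ID=AF_LATE,Number=1,Type=Float,Description="Variant allele frequency, late passage">',
        '##INFO=<ID=PASSAGE,Number=1,Type=String,Description="Passage in which the variant was detected">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        info = (
            f"AF_EARLY={r.early_freq:.6f};AF_LATE={r.late_freq:.6f};"
            f"PASSAGE={r.passage_detected}"
        )
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.site_id}\t{r.ref}\t{r.alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
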