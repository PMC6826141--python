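"""Experiment geometry and sequencing-noise parameters.

The experiment modelled throughout this package is a paired-passage cell
culture: an early-passage population is bottlenecked to ``bottleneck_size``
founder cells, expanded for ``divisions`` population doublings, and both
passages are deep-sequenced over a targeted region.  ``ExperimentParams``
carries the three quantities every downstream computation needs — the
bottleneck size B, the number of doublings d (final population B * 2**d),
and the per-base sequencing miscall probability epsilon — plus the
resolution of the frequency grid used by the numeric kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ExperimentParams", "load_params", "save_params"]


@dataclass(frozen=True)
class ExperimentParams:
    """Parameters of the bottleneck-and-regrowth experiment.

    Attributes
    ----------
    bottleneck_size:
        Number of founder cells B sampled at the bottleneck (default 200).
    divisions:
        Population doublings d during regrowth; the expanded population has
        ``B * 2**d`` cells.  The study design allows 13-17; the default of 17
        is the calibrated value (see docs/methods.md).
    seq_error:
        Per-base miscall probability epsilon.  A miscall lands on a specific
        wrong base with probability ``seq_error / 3``.  Default 1e-3
        corresponds to the Q30 base-quality floor applied to the reads.
    grid_size:
        Number of uniform frequency bins used by the numeric kernels.
    diploid:
        If True, frequencies are interpreted as heterozygous-cell fractions
        and a read samples the variant allele at half the cell fraction.
        Off by default: allele frequencies are modelled directly.
    """

    bottleneck_size: int = 200
    divisions: int = 17
    seq_error: float = 1e-3
    grid_size: int = 512
    diploid: bool = False

    def __post_init__(self) -> None:
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if self.divisions < 1:
            raise ValueError("divisions must be >= 1")
        if not (0.0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.grid_size < 64:
            raise ValueError("grid_size must be >= 64")

    @property
    def final_size(self) -> int:
        """Expanded population size B * 2**d."""
        return self.bottleneck_size * 2 ** self.divisions

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.grid_size + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def replace(self, **kwargs) -> "ExperimentParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def load_params(path: str | Path) -> ExperimentParams:
    """Read parameters from a YAML ``key: value`` config file.

    Unknown keys raise so that typos in config files do not silently fall
    back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = ExperimentParams.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return ExperimentParams(**raw)


def save_params(params: ExperimentParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
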