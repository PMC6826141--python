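import numpy as np
import pytest

from clonaldrift import ExperimentParams, SiteObservation


@pytest.fixture(scope="session")
def default_params() -> ExperimentParams:
    return ExperimentParams()


@pytest.fixture(scope="session")
def small_params() -> ExperimentParams:
    """A population small enough for the exact event-by-event kernel."""
    return ExperimentParams(bottleneck_size=20, divisions=4)


@pytest.fixture(scope="session")
def worked_examples() -> dict[str, SiteObservation]:
    """The three published clonal-expansion candidates used as worked examples."""
    return {
        "CDKN2A": SiteObservation("chr9:21974774:A", 0, 725, 156, 282),
        "ERCC8": SiteObservation("chr5:60169670:T", 0, 2168, 122, 705),
        "BRCA2": SiteObservation("chr13:32914714:T", 42, 3122, 642, 2996),
    }


def snap_to_grid(freqs: np.ndarray, params: ExperimentParams) -> np.ndarray:
    """Map simulated frequencies onto the model's grid representation.

    Exact 0 and 1 stay atoms; interior values take their bin's center, the
    same convention the analytic chain uses.
    """
    freqs = np.asarray(freqs, dtype=float)
    out = freqs.copy()
    interior = (freqs > 0.0) & (freqs < 1.0)
    idx = np.clip(
        np.searchsorted(params.bin_edges, freqs[interior], side="right") - 1,
        0,
        params.grid_size - 1,
    )
    out[interior] = params.bin_centers[idx]
    return out
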