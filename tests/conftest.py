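import numpy as np
import pytest

from rertdose import DoseVolumeHistogram


@pytest.fixture
def two_bin_diff():
    """Half the volume at 20 Gy, half at 60 Gy (edges 0/40/80)."""
    return DoseVolumeHistogram("brainstem", "differential", [0.0, 40.0, 80.0], [0.5, 0.5])


@pytest.fixture
def step_cumulative():
    """Cumulative DVH dropping from 1 to 0.5 at 40 Gy and to 0 at 60 Gy."""
    return DoseVolumeHistogram(
        "optic_chiasm", "cumulative", [0.0, 20.0, 40.0, 60.0], [1.0, 1.0, 0.5, 0.0]
    )


def random_cumulative_dvh(rng: np.random.Generator, n_bins: int = 40,
                          max_dose: float = 70.0) -> DoseVolumeHistogram:
    """Random valid cumulative DVH: sorted decreasing values from 1 to >= 0."""
    edges = np.sort(rng.uniform(0.0, max_dose, n_bins))
    edges = np.concatenate([[0.0], np.unique(edges)])
    vals = np.sort(rng.uniform(0.0, 1.0, edges.size - 1))[::-1]
    vals = np.concatenate([[1.0], vals * rng.uniform(0.2, 1.0)])
    vals = np.minimum.accumulate(vals)
    vals[-1] = 0.0  # grid covers the full dose support
    return DoseVolumeHistogram("brainstem", "cumulative", edges, vals)
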