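import numpy as np
import pytest

from cbmn import SynthParams, generate_field
from cbmn.score import score_field


@pytest.fixture(scope="session")
def default_field():
    """One default-noise field plus truth (seed 1)."""
    return generate_field(SynthParams(seed=1), 0, "B02")


@pytest.fixture(scope="session")
def noiseless_params():
    return SynthParams(seed=2, noise_sd=0.0, shot_noise=False, mn_rate=0.3)


def score_fields(params: SynthParams, n_fields: int):
    """Generate and score n fields; yields (cells, cyto_labels, truth)."""
    out = []
    for fi in range(n_fields):
        fld, truth = generate_field(params, fi)
        cells, cyto = score_field(fld)
        out.append((cells, cyto, truth))
    return out


def toy_disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
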