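import numpy as np
import pytest

from elongrate.core_io import TranscriptionUnit
from elongrate.features import FeatureMatrix, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_glm_data(rng):
    """A few genes with Gaussian features and counts drawn from the model."""
    M, N, F = 4, 400, 3
    kappa_true = np.array([-0.1, 0.05, -0.02])
    tus, blocks = [], []
    for j in range(M):
        Y = rng.normal(size=(N, F))
        zeta = np.exp(Y @ kappa_true)
        chi = rng.uniform(0.5, 2.0)
        x = rng.poisson(chi / zeta).astype(float)
        x[0] = max(x[0], 1)  # keep every gene non-degenerate
        tus.append(
            TranscriptionUnit(
                f"g{j}", "chr1", "+", j * N, (j + 1) * N, counts=x
            )
        )
        blocks.append(Y)
    fm = standardize(
        FeatureMatrix(
            names=[f"f{i}" for i in range(F)],
            raw=blocks,
            tu_ids=[t.id for t in tus],
        )
    )
    return tus, fm, kappa_true
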