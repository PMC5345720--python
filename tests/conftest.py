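import numpy as np
import pytest

from hatcv.reml import reml_fit
from hatcv.synthetic import SimulationSpec, simulate_dataset

#: the frozen small dataset used across the suite (n=60 lines, 200
#: markers, heritability 0.5, seed 58)
FIXTURE_SPEC = SimulationSpec(n=60, m=200, h2=0.5, seed=58)


@pytest.fixture(scope="session")
def fixture60():
    """Frozen synthetic dataset: (geno, kin(with eigen), y, X, truth)."""
    geno, kin, pheno, truth = simulate_dataset(FIXTURE_SPEC)
    kin = kin.require_eigen()
    y = pheno["y"].to_numpy()
    X = np.ones((FIXTURE_SPEC.n, 1))
    return geno, kin, y, X, truth


@pytest.fixture(scope="session")
def fit60(fixture60):
    """Whole-sample REML fit of the frozen dataset."""
    _, kin, y, X, _ = fixture60
    return reml_fit(y, X, kin)
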