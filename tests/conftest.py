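import numpy as np
import pytest

from mirgba.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def null_fit_2000():
    """Fitted model on a 2000-feature null simulation (no planted effects).

    Session-scoped: several calibration checks share it.
    """
    from mirgba.model import GbaModel

    cfg = SimulationConfig(
        n_features=2000,
        n_per_cell=5,
        dispersion=0.16,
        frac_pattern_a=0.0,
        frac_pattern_b=0.0,
        frac_pattern_c=0.0,
        frac_pattern_d=0.0,
        seed=2024,
    )
    counts, design, truth = simulate_counts(cfg)
    results = GbaModel(counts, design).fit()
    return counts, design, truth, results


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
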