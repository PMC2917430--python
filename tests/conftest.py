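import numpy as np
import pytest

import coexsig as cs


@pytest.fixture
def toy_matrix() -> cs.ExpressionMatrix:
    """3 genes x 4 samples; hand-checkable against both filter rules."""
    return cs.ExpressionMatrix(
        gene_ids=["CONST", "DIM", "VAR"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [500.0, 500.0, 500.0, 500.0],
                [80.0, 90.0, 70.0, 60.0],
                [100.0, 150.0, 300.0, 800.0],
            ]
        ),
    )


@pytest.fixture
def small_two_group():
    cfg = cs.TwoGroupSimConfig(n_genes=100, n_per_group=3, n_de_up=10, n_de_down=10, seed=1)
    return cs.simulate_two_group_experiment(cfg)


@pytest.fixture(scope="session")
def compendium_sim():
    cfg = cs.CompendiumSimConfig(n_genes=2000, module_size=20, rho=0.7, seed=7)
    return cs.simulate_tumor_compendium(cfg)


def brute_force_ks(positions, n, k) -> float:
    """Independent oracle: explicit running-sum walk over all prefixes."""
    hits = set(positions)
    best = running = 0.0
    for pos in range(1, n + 1):
        running += 1.0 / k if pos in hits else -1.0 / (n - k)
        best = max(best, running)
    return best
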