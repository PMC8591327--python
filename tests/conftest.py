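import numpy as np
import pytest

from hetocs import (
    FounderSpec,
    HaplotypePanel,
    draw_effects,
    simulate_founders,
)


def panel_from_X(X: np.ndarray, ids=None, generation: int = 0) -> HaplotypePanel:
    """Build a phased panel realizing a given L x N -1/0/1 genotype matrix.

    Heterozygotes are phased as (0, 1); the coding round-trip does not
    depend on phase.
    """
    L, N = X.shape
    hap = np.zeros((2 * N, L), dtype=np.int8)
    for i in range(N):
        for l in range(L):
            g = X[l, i]
            if g == 1:
                hap[2 * i, l] = hap[2 * i + 1, l] = 1
            elif g == 0:
                hap[2 * i + 1, l] = 1
    if ids is None:
        ids = [f"ind{i}" for i in range(N)]
    return HaplotypePanel(hap, ids, generation=generation)


def random_panel(n: int, L: int, seed: int) -> HaplotypePanel:
    rng = np.random.default_rng(seed)
    return HaplotypePanel(
        rng.integers(0, 2, size=(2 * n, L)).astype(np.int8),
        [f"ind{i}" for i in range(n)],
    )


# 3-individual / 4-locus micro fixture: genotype columns
#   A = (1, 1, 0, -1), B = (1, -1, 0, 0), C = (0, 1, 1, 1)
MICRO_X = np.array(
    [
        [1, 1, 0],
        [1, -1, 1],
        [0, 0, 1],
        [-1, 0, 1],
    ]
)
MICRO_EFFECTS = np.array([1.0, 2.0, -1.0, 0.5])


@pytest.fixture
def micro_panel() -> HaplotypePanel:
    return panel_from_X(MICRO_X, ids=["A", "B", "C"])


@pytest.fixture(scope="session")
def desk_founders():
    """Default desk-scale founder population with a calibrated trait."""
    panel, gmap = simulate_founders(FounderSpec(seed=7))
    effects = draw_effects(
        panel.n_loci, seed=8, founder_panel=panel, target_tbv_sd=25.9
    )
    return panel, gmap, effects
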