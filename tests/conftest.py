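import numpy as np
import pytest

import supragnn as sg


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial synthetic cohort for pipeline-level tests."""
    spec = sg.SyntheticSpec(n_genes=24, n_mirnas=8, n_samples=80, n_classes=2,
                            module_size=5, effect_size=3.0, seed=11)
    networks, omics, labels = sg.generate_cohort(spec)
    return spec, networks, omics, labels


@pytest.fixture(scope="session")
def default_cohort():
    """The package's standard cohort (60 genes, 20 miRNAs, 4 classes, 300
    samples)."""
    spec = sg.SyntheticSpec()
    networks, omics, labels = sg.generate_cohort(spec)
    return spec, networks, omics, labels


def random_supra_blocks(rng, n, m, density=0.3):
    """Random valid (A_gg, A_gm, A_mm) blocks."""
    a_gg = (rng.random((n, n)) < density).astype(float)
    a_gg = np.triu(a_gg, 1)
    a_gg = a_gg + a_gg.T
    a_gm = (rng.random((n, m)) < density).astype(float)
    a_mm = sg.build_meta_path_adjacency(a_gm)
    return a_gg, a_gm, a_mm


def random_connected_adjacency(rng, n, density=0.4):
    """Random symmetric adjacency with unit diagonal (self-loops)."""
    a = (rng.random((n, n)) < density).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    np.fill_diagonal(a, 1.0)
    return a
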