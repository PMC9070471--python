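import numpy as np
import pytest

from aadkit import synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.CohortConfig(seed=7)


@pytest.fixture(scope="session")
def spectrum_set(default_config):
    """Default 10/10/6 cohort spectra, shared across tests (read-only)."""
    sset, truths = synthetic.generate_spectrum_set(default_config)
    return sset


@pytest.fixture(scope="session")
def fl_matrix(spectrum_set):
    mask = spectrum_set.tissue_type == "FL"
    return spectrum_set.X[mask], spectrum_set.labels.loc[mask, "subcluster"].to_numpy().astype(int)


@pytest.fixture()
def vvg_pair():
    img, truth = synthetic.generate_vvg_image(
        128, 128, collagen_fraction=0.4, elastin_fraction=0.3, seed=5
    )
    return img, truth


def planted_partition(subclusters: np.ndarray) -> set[frozenset]:
    """Leaf-index sets of the planted FL sub-groups."""
    return {
        frozenset(np.flatnonzero(subclusters == j).tolist())
        for j in np.unique(subclusters)
    }
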