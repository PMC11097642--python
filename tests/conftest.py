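import numpy as np
import pandas as pd
import pytest

from virosurvey.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_survey():
    """One deterministic synthetic survey: 4 phyla x 15 samples, 30 families."""
    counts, meta, truth = generate_dataset(SyntheticConfig(phylum_effect=1.5, seed=42))
    return counts, meta, truth


@pytest.fixture(scope="session")
def null_survey():
    """A no-effect survey: all phyla share one generating composition."""
    counts, meta, truth = generate_dataset(SyntheticConfig(phylum_effect=0.0, seed=43))
    return counts, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_distance():
    """1-D points A={0,1}, B={3,4} with Euclidean distances."""
    from scipy.spatial.distance import pdist, squareform

    pts = np.array([[0.0], [1.0], [3.0], [4.0]])
    d = squareform(pdist(pts))
    labels = pd.DataFrame({"group": ["A", "A", "B", "B"]})
    return d, labels
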