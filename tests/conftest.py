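import numpy as np
import pytest

from porescreen.features import FeatureMatrix
from porescreen.synth import make_default_panel, simulate_features


@pytest.fixture(scope="session")
def panel():
    return make_default_panel()


@pytest.fixture(scope="session")
def panel_with_unknowns():
    return make_default_panel(include_unknowns=True)


@pytest.fixture(scope="session")
def small_features(panel):
    """120 events for each of the 10 target classes (D-MA excluded)."""
    counts = {n: 120 for n in
              ["CAT", "3-CQA", "D-SOR", "XYL", "L-MA", "L-TA", "CA", "ICIT", "D-GLC", "D-FRU"]}
    return simulate_features(panel, counts, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def gaussian_blob_matrix(rng, n, center, spread=0.5, label=None):
    """Helper: an isotropic 5-feature Gaussian blob as a FeatureMatrix."""
    import pandas as pd

    from porescreen.features import FEATURE_COLUMNS

    X = rng.normal(loc=center, scale=spread, size=(n, 5))
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    labels = None if label is None else np.full(n, label, dtype=object)
    return FeatureMatrix(df, labels)
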