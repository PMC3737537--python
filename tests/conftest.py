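import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from smrna import pipeline, simulate
from smrna.features import FEATURE_NAMES, FeatureMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """A small six-class synthetic dataset shared across test modules."""
    return simulate.generate_dataset(n_loci_per_class=30, seed=101)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return pipeline.features_from_dataset(small_dataset).subset_labelled()


def make_feature_matrix(X: np.ndarray, y=None) -> FeatureMatrix:
    """Wrap a raw array (n x 25) as a FeatureMatrix for model-layer tests."""
    df = pd.DataFrame(
        X, columns=FEATURE_NAMES,
        index=pd.Index([f"locus_{i}" for i in range(len(X))], name="locus_id"),
    )
    labels = None if y is None else pd.Series(np.asarray(y, dtype=object), index=df.index, name="label")
    return FeatureMatrix(df, labels)
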