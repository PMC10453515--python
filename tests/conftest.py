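import numpy as np
import pandas as pd
import pytest

from nestout.features import FeatureDataset
from nestout.synthetic import (
    default_outlier_profile,
    default_profiles,
    default_schedule,
    generate_stream,
    inject_outliers,
)


@pytest.fixture(scope="session")
def small_stream():
    """Two cycles of the four default activities at 20 Hz (240 s)."""
    return generate_stream(default_profiles(), default_schedule(n_cycles=2), seed=11)


@pytest.fixture(scope="session")
def outlier_stream(small_stream):
    """The small stream with two 10 s stair-climbing bouts spliced in."""
    return inject_outliers(
        small_stream, default_outlier_profile(),
        n_segments=2, segment_duration=10.0, seed=7,
    )


def random_feature_dataset(rng, n, classes, n_features=6, min_per_class=1):
    """Random dataset with every class represented at least min_per_class times."""
    labels = (list(classes) * min_per_class)[:n]
    labels += [classes[i] for i in rng.integers(0, len(classes), size=n - len(labels))]
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    features = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"f{j}" for j in range(n_features)],
    )
    return FeatureDataset(features, pd.Series(labels, dtype=object))
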