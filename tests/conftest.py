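import numpy as np
import pytest

from repsample import FeatureSpec, Schema, WeightedDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def mixed_schema():
    return Schema(
        (
            FeatureSpec("age", "numeric"),
            FeatureSpec("score", "numeric"),
            FeatureSpec("group", "categorical", ("a", "b", "c")),
        )
    )


@pytest.fixture
def mixed_csv(tmp_path):
    """4-row CSV with one incomplete row."""
    path = tmp_path / "cohort.csv"
    path.write_text(
        "age,score,group,outcome\n"
        "30,1.5,a,1\n"
        "41,,b,0\n"
        "25,0.25,c,1\n"
        "58,2.0,a,0\n"
    )
    return path


def make_dataset(features, target=None, weights=None):
    """Plain numeric dataset with auto schema, for tests that skip I/O."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    schema = Schema(tuple(FeatureSpec(f"x{j}", "numeric") for j in range(features.shape[1])))
    return WeightedDataset(
        features=features,
        weights=np.ones(len(features)) if weights is None else np.asarray(weights, float),
        ids=np.arange(len(features)),
        schema=schema,
        target=target,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
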