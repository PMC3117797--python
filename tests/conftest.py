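import numpy as np
import pytest

from gnegloc import (
    FeatureContext,
    GOVector,
    MultiLabelDataset,
    ProteinRecord,
    SyntheticSpec,
    make_dataset,
    make_feature_context,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset():
    return MultiLabelDataset([
        ProteinRecord("P00001", "M" + "ACDEFGHIKL" * 6, frozenset({3})),
        ProteinRecord("P00002", "M" + "KLMNPQRSTV" * 6, frozenset({1, 8})),
        ProteinRecord("P00003", "M" + "WYACDEFGHI" * 6, frozenset({2})),
    ])


@pytest.fixture
def small_spec():
    """A few hundred proteins with the benchmark's composition shape."""
    return SyntheticSpec(seed=42).scaled(200)


@pytest.fixture
def small_context(small_spec):
    dataset, _ = make_dataset(small_spec)
    return dataset, make_feature_context(dataset, small_spec)


def toy_context(points: dict[str, np.ndarray],
                labels: dict[str, frozenset[int]],
                go: dict[str, GOVector] | None = None,
                go_dim: int = 0,
                k: int = 5) -> FeatureContext:
    """Context from hand-placed 210-d SeqEvo points (padded with zeros)."""
    seqevo = {}
    for acc, x in points.items():
        v = np.zeros(210)
        v[: len(x)] = x
        seqevo[acc] = v
    return FeatureContext(
        accessions=list(points),
        labels=labels,
        seqevo=seqevo,
        go=go or {},
        go_dim=go_dim,
        k=k,
    )
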