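import numpy as np
import pytest

from enrichopt.eoa_engine import RankedList
from enrichopt.preprocessing import DescriptorDataset
from enrichopt.synthetic_benchmark import BenchmarkParams, generate_benchmark


def ranked_from_labels(labels) -> RankedList:
    """A RankedList with the given label order and strictly decreasing scores."""
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    return RankedList(
        compound_ids=[f"c{i}" for i in range(n)],
        scores=np.arange(n, 0, -1, dtype=float),
        labels=labels,
    )


def make_dataset(values, labels, names=None, ids=None) -> DescriptorDataset:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = names or [f"d{j}" for j in range(values.shape[1])]
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    return DescriptorDataset(
        compound_ids=ids,
        labels=np.asarray(labels, dtype=bool),
        descriptor_names=names,
        values=values,
    )


@pytest.fixture(scope="session")
def default_benchmark():
    """One draw of the default synthetic benchmark (50/500, 100 descriptors)."""
    return generate_benchmark(BenchmarkParams(seed=1))


@pytest.fixture
def toy_parent():
    """Small parent dataset for split tests: 20 actives, 80 decoys, 3 descriptors."""
    rng = np.random.default_rng(7)
    values = rng.standard_normal((100, 3))
    labels = np.zeros(100, dtype=bool)
    labels[:20] = True
    return make_dataset(values, labels)
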