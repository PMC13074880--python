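import pytest

from pmal.synthetic import make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """The 300-molecule / 2-endpoint synthetic benchmark (dataset, truth, config)."""
    return make_benchmark("small", seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_benchmark):
    return small_benchmark[0]
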