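import pytest

from regpath import RegulationRecord, build_network
from regpath.synthetic import sts_example


@pytest.fixture(scope="session")
def sts():
    """The curated 15-node STS composite-path example."""
    return sts_example()


@pytest.fixture()
def small_records():
    return [
        RegulationRecord("TFA", "TF", "G1", "gene", "db1"),
        RegulationRecord("TFA", "TF", "miR-1", "miRNA", "db1"),
        RegulationRecord("miR-1", "miRNA", "G2", "gene", "db2"),
    ]


@pytest.fixture()
def small_network(small_records):
    return build_network(small_records)
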