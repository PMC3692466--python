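import pytest

from mtsprofile import generate_dataset
from mtsprofile.seqio import Dataset, ProteinRecord


@pytest.fixture
def tiny_records():
    return [
        ProteinRecord("r1", "Hsap", "MLRSSVVRSR", "AKDEVQSTLK", gene_id="G1", accession="A1"),
        ProteinRecord("r2", "Hsap", "MFSRTSKLAA", "DDEEFGHKLM"),
        ProteinRecord("r3", "Scer", "MKSTRRLLSA", "ACDEFGHIKL"),
    ]


@pytest.fixture
def tiny_dataset(tiny_records):
    return Dataset(records=list(tiny_records), provenance="fixture")


@pytest.fixture(scope="session")
def synth():
    """Default-shape synthetic dataset (five species, 296 records) + annotations."""
    return generate_dataset(seed=1)
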