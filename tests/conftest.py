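import pytest

from smallrna_libbias.io_formats import Protocol, ReferenceRecord, RefClass, SmallRNARead
from smallrna_libbias.synthetic_data import make_reference_set, zipf_profile


@pytest.fixture(scope="session")
def mirna_refs():
    """Nine synthetic miRNA families plus contaminant references, distance-separated."""
    return make_reference_set(n_mirna=9, n_rrna=2, n_mrna=2, length_range=(21, 23), seed=42)


@pytest.fixture(scope="session")
def profile(mirna_refs):
    families = [r.family for r in mirna_refs if r.ref_class == RefClass.MIRNA]
    return zipf_profile(families)


def make_read(sequence, read_id="r1", library_id="lib1", protocol=Protocol.ILLUMINA_GA):
    return SmallRNARead(
        read_id=read_id, sequence=sequence, library_id=library_id, protocol=protocol
    )


@pytest.fixture
def read_factory():
    return make_read
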