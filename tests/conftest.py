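import pytest

from depbias.library_io import NON_TARGETING_SENTINEL, SgRNALibrary, SgRNARecord


@pytest.fixture
def tiny_library() -> SgRNALibrary:
    """Two targeting genes (2 + 1 guides) and one non-targeting guide."""
    return SgRNALibrary(
        records=[
            SgRNARecord("g1", "GENEA", "ACGTACGTACGTACGTACGT", "targeting"),
            SgRNARecord("g2", "GENEA", "TTTTACGTACGTACGTACGT", "targeting"),
            SgRNARecord("g3", "GENEB", "CCCCACGTACGTACGTACGT", "targeting"),
            SgRNARecord("nt1", NON_TARGETING_SENTINEL, "GGGGACGTACGTACGTACGT", "non_targeting"),
        ],
        name="tiny",
    )
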