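import pytest

from arvprofiler import example_panel
from arvprofiler.junctions import SignatureMatcher, build_signatures
from arvprofiler.rearrangements import GenomeIndex


@pytest.fixture(scope="session")
def panel():
    return example_panel()


@pytest.fixture(scope="session")
def signatures(panel):
    return build_signatures(panel)


@pytest.fixture(scope="session")
def matcher(signatures):
    return SignatureMatcher(signatures)


@pytest.fixture(scope="session")
def genome_index(panel):
    return GenomeIndex.from_panel(panel)
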