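import pytest

from ganglio.chem import LibraryConfig, enumerate_library


@pytest.fixture(scope="session")
def default_library():
    return enumerate_library(LibraryConfig.default())
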