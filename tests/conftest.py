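import pytest

from cassanet.library import load_library
from cassanet.simulate import library_specs


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def compound_specs(library):
    return library_specs(library)
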