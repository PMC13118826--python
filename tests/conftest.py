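import pytest

from glasstab import load_material_library


@pytest.fixture(scope="session")
def library():
    return load_material_library()


@pytest.fixture(scope="session")
def glb(library):
    return library["GLB"]
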