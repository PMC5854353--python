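import pytest

from aphidkey import load_bundled_keys, load_reference


@pytest.fixture(scope="session")
def ds():
    """Curated-layer reference dataset (all analysis defaults to this)."""
    return load_reference(layer="curated")


@pytest.fixture(scope="session")
def ds_printed():
    """Verbatim as-printed layer, anomalies included."""
    return load_reference(layer="as_printed")


@pytest.fixture(scope="session")
def keys(ds):
    return load_bundled_keys(ds)
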