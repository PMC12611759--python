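import pytest

from editscope.presets import example_amplicon_spec, gapdh_hdr_spec


@pytest.fixture(scope="session")
def amplicon_spec():
    """Synthetic 3.5-kb long-read amplicon spec with reference core."""
    return example_amplicon_spec()


@pytest.fixture(scope="session")
def hdr_amplicon_spec():
    """Amplicon spec for a locus with a 228-bp HDR template insertion."""
    return example_amplicon_spec(hdr_insertion_size=228)


@pytest.fixture(scope="session")
def class_spec():
    """GAPDH-style anchor classifier spec (synthetic amplicon context)."""
    return gapdh_hdr_spec()
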