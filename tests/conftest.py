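import pytest

from napqc.simulate import demo_reference_set


@pytest.fixture(scope="session")
def demo_refs():
    """Full-size synthetic construct (~14 kb plasmid, 11.2 kb transcript)."""
    return demo_reference_set(0)


@pytest.fixture(scope="session")
def small_refs():
    """Scaled-down construct (3.8 kb plasmid) for fast unit tests."""
    return demo_reference_set(
        1, replicon_body_len=2956, backbone_len=800, host_len=6000
    )
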