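import pytest

from classf_switch.generic_numbering import GenericLabel, HelixSegment, SegmentMap


@pytest.fixture
def fzd6_map() -> SegmentMap:
    """FZD6 with its TM6 span 408-427 anchored at 6.24 (so R416 is 6.32)."""
    return SegmentMap(
        "FZD6", (HelixSegment(6, 408, 427, GenericLabel(6, 24)),)
    )


@pytest.fixture
def smo_map() -> SegmentMap:
    """SMO with the lower TM7 anchored 534 -> 7.54 (T534, W535, W537)."""
    return SegmentMap(
        "SMO", (HelixSegment(7, 530, 545, GenericLabel(7, 50)),)
    )


@pytest.fixture
def two_helix_map() -> SegmentMap:
    """Small synthetic receptor with two helices for aggregation tests."""
    return SegmentMap(
        "SYN",
        (
            HelixSegment(6, 101, 110, GenericLabel(6, 30)),
            HelixSegment(7, 201, 210, GenericLabel(7, 50)),
        ),
    )
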