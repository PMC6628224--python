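import hypothesis
import pytest

from passalus.alignment_io import Alignment
from passalus.synthetic_data import rflp_reference_standin

hypothesis.settings.register_profile(
    "fast", derandomize=True, max_examples=40, deadline=None
)
hypothesis.settings.load_profile("fast")


@pytest.fixture(scope="session")
def standin():
    """Synthetic stand-in dataset carrying the published assay layout."""
    return rflp_reference_standin(seed=0)


@pytest.fixture
def small_two_clade():
    """Tiny hand-built two-clade alignment: clades differ at columns 2 and 5."""
    recs = [
        ("a1", "AACGTTGC"),
        ("a2", "AACGTTGC"),
        ("a3", "AACGTTAC"),
        ("b1", "AATGTAGC"),
        ("b2", "AATGTAGC"),
        ("b3", "AATGTAGG"),
    ]
    labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
    return Alignment.from_records(recs), labels
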