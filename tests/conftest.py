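import pytest

from histack import default_catalog, load_reference
from histack.align import HistoneSequence


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def hmfb_query(reference):
    return HistoneSequence(id="HMfB", residues=reference.sequence)


@pytest.fixture(scope="session")
def printed_identity_map():
    """HMfB position -> residue map from the documented functional identities.

    Covers the DNA anchors, hydrophobic core, fold salt bridge, tetramer
    interface, stacking loop glycine and the three canonical stacking
    hydrogen-bond pairs — exactly the positions the criteria consult.
    """
    return {
        10: "R", 19: "R",
        24: "A", 28: "L", 32: "L", 39: "I", 43: "A",
        52: "R", 59: "D",
        46: "L", 49: "H", 62: "L",
        16: "G",
        30: "K", 61: "E", 34: "E", 65: "R", 14: "D", 48: "R",
    }
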