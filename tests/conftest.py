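import numpy as np
import pytest

from specisite.core_io import AlignedSequence, MultipleAlignment, tree_from_newick


@pytest.fixture
def toy_alignment():
    """Six sequences, two clades, ungapped 10-column alignment."""
    seqs = [
        AlignedSequence("a1", "RKDELAVGIW", clade="CladeA"),
        AlignedSequence("a2", "RKDELAVGIW", clade="CladeA"),
        AlignedSequence("a3", "RKDELAVGIY", clade="CladeA"),
        AlignedSequence("b1", "AKDELEVGIW", clade="CladeB"),
        AlignedSequence("b2", "AKDELEVGIW", clade="CladeB"),
        AlignedSequence("b3", "AKDQLEVGIW", clade="CladeB"),
    ]
    return MultipleAlignment(sequences=seqs, reference_id="a1")


@pytest.fixture
def four_tip_tree():
    return tree_from_newick("((A:0.2,B:0.3)X:0.25,(C:0.15,D:0.4)Y:0.1)R;")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
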