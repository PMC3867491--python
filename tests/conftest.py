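import pytest

from motudelim.treeio import Alignment, PhyloTree


@pytest.fixture
def toy_tree():
    """((A:1,B:1)95:1,C:2); — supported cherry plus outgroup-like tip."""
    return PhyloTree.from_string("((A:1,B:1)95:1,C:2);")


@pytest.fixture
def symmetric_tree():
    """((A:1,B:1):2,(C:1,D:1):2); — two cherries at equal depth."""
    return PhyloTree.from_string("((A:1,B:1):2,(C:1,D:1):2);")


@pytest.fixture
def toy_alignment():
    return Alignment(
        ids=("a", "b", "c", "d"),
        seqs=("ACGTACGTAC", "ACGTACGTAC", "ACGTACGTTC", "ACTTACGTTA"),
        partitions={"locus1": (0, 4), "locus2": (4, 10)},
    )
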