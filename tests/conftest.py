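import numpy as np
import pytest

from coevo.phylo import Phylogeny, read_newick


@pytest.fixture
def tree_from_string(tmp_path):
    """Factory: parse a Newick string through the file-reading path."""

    def _make(newick: str) -> Phylogeny:
        p = tmp_path / ("t%d.nwk" % abs(hash(newick)))
        p.write_text(newick + "\n")
        return read_newick(p)

    return _make


@pytest.fixture
def cherry3(tree_from_string):
    """The worked 3-tip tree ((A:1,B:1):1,C:2)."""
    return tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def star4(tree_from_string):
    return tree_from_string("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
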