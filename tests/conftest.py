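import io
import sys
from pathlib import Path

import numpy as np
import pytest
from skbio import TreeNode

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def small_tree() -> TreeNode:
    """((A:1,B:2):0.5,C:3); — the three-leaf hand-example tree."""
    return TreeNode.read(io.StringIO("((A:1,B:2):0.5,C:3);"))


@pytest.fixture
def two_leaf_tree() -> TreeNode:
    return TreeNode.read(io.StringIO("(A:1,B:1);"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
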