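import numpy as np
import pytest

import ribopart as rp
from ribopart.models import GtrGamma, PartitionedModel
from ribopart.seqio import Alignment, CharacterSet, PartitionScheme


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(
        ["alpha", "beta", "gamma", "delta"],
        ["ACGTACGT", "ACGTACGA", "AC--ACGT", "ACGTTCGT"],
    )


@pytest.fixture
def gtr_model() -> GtrGamma:
    return GtrGamma((2.0, 8.0, 1.5, 1.2, 9.0, 1.0), (0.30, 0.20, 0.22, 0.28), 0.7, 4)


@pytest.fixture
def small_tree() -> rp.Tree:
    return rp.sample_tree(6, seed=11, target_tree_length=1.8)


@pytest.fixture
def simulated_small(gtr_model, small_tree):
    """6-taxon, 60-site single-partition dataset with known truth."""
    cs = CharacterSet("locus", ((0, 60),))
    scheme = PartitionScheme("single", ((cs, "nuc"),))
    pm = PartitionedModel((("locus", gtr_model),))
    aln, truth = rp.evolve_alignment(small_tree, scheme, pm, seed=21)
    return aln, scheme, pm, small_tree
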