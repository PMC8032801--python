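import pytest

from famflux import PhyloTree, PipelineConfig, SimParams, simulate_family


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def tree3():
    """Tiny species tree with branch lengths."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree6():
    """Clock-like 6-leaf species tree (all root-to-tip paths equal)."""
    return PhyloTree.from_newick(
        "(((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5):0.5,(E:1,F:1):0.5);"
    )


@pytest.fixture
def sim_truth(tree3):
    params = SimParams(lambda_dup=0.5, mu_loss=0.3, n0=2, seq_len_aa=80, seed=42)
    return simulate_family(tree3, params), SimParams(
        lambda_dup=0.5, mu_loss=0.3, n0=2, seq_len_aa=80, seed=42
    )
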