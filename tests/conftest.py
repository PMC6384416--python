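import numpy as np
import pytest

from cbnpa.benchmarks import toy_expression, toy_model
from cbnpa.layers import DownstreamEdge, TwoLayerModel
from cbnpa.network import CausalEdge, CausalNetwork, EntityRef


def make_backbone(edge_specs, extra_nodes=(), kinds=None):
    """Build a backbone network from (src, tgt, sign) triples over short
    node names; ``kinds`` maps a name to a non-protein kind."""
    kinds = kinds or {}
    names = {n for e in edge_specs for n in e[:2]} | set(extra_nodes)
    refs = {n: EntityRef(kinds.get(n, "protein"), "SYN", n) for n in names}
    ids = {n: refs[n].canonical for n in names}
    edges = [CausalEdge(ids[s], ids[t], sign) for s, t, sign in edge_specs]
    return CausalNetwork(nodes={ids[n]: refs[n] for n in names},
                         edges=edges), ids


def make_model(edge_specs, downstream_specs, extra_nodes=(), kinds=None):
    """Two-layer model from backbone triples + (node, gene, sign) triples."""
    backbone, ids = make_backbone(edge_specs, extra_nodes, kinds)
    downstream = [DownstreamEdge(ids[n], g, s) for n, g, s in downstream_specs]
    return TwoLayerModel(backbone, downstream), ids


@pytest.fixture
def toy():
    return toy_model()


@pytest.fixture
def toy_flipped():
    return toy_model(flipped=True)


@pytest.fixture
def toy_beta():
    return toy_expression()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
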