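import warnings

import numpy as np
import pytest

from polytax.core_io import GenomeRecord
from polytax.phylo import UnrootedTopology

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_additive_instance(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary topology with positive branch lengths and its
    exact additive distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    adj = {0: {n_taxa}, 1: {n_taxa}, 2: {n_taxa}, n_taxa: {0, 1, 2}}
    topo = UnrootedTopology(labels, adj)
    next_internal = n_taxa + 1
    for leaf in range(3, n_taxa):
        edges = topo.edges()
        u, v = edges[rng.integers(len(edges))]
        w = next_internal
        next_internal += 1
        topo.adj[u].remove(v)
        topo.adj[v].remove(u)
        topo.adj[u].add(w)
        topo.adj[v].add(w)
        topo.adj[w] = {u, v, leaf}
        topo.adj[leaf] = {w}
    lengths = {e: float(rng.uniform(0.1, 2.0)) for e in topo.edges()}
    d = np.zeros((n_taxa, n_taxa))
    sides = topo.edge_sides()
    for e, ln in lengths.items():
        side = sides[e]
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                if (i in side) != (j in side):
                    d[i, j] += ln
                    d[j, i] += ln
    return labels, d, topo, lengths


@pytest.fixture
def small_genome(rng):
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return GenomeRecord(id="g1", replicons=[("chr", seq)])
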