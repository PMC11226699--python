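"""Distance estimation and distance-based tree building.

Distances: p, Poisson, and pairwise maximum-likelihood distances under the
packaged empirical JTT / Dayhoff amino-acid models.  Trees: UPGMA, neighbor
joining (Studier-Keppler), and minimum evolution (OLS branch lengths,
nearest-neighbor-interchange search) with nonparametric bootstrap support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np
import skbio
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .core_io import Alignment, PhyloTree

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

__all__ = [
    "DistanceModel",
    "BootstrapSpec",
    "EmpiricalModel",
    "load_empirical_model",
    "pairwise_distance",
    "upgma",
    "neighbor_joining",
    "me_tree_length",
    "minimum_evolution",
    "bootstrap_support",
    "UnrootedTopology",
]


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------


class EmpiricalModel:
    """Reversible amino-acid model Q_ij = S_ij * pi_j, scaled to one expected
    substitution per site per unit time."""

    def __init__(self, name: str, exchange: np.ndarray, freqs: np.ndarray) -> None:
        self.name = name
        self.freqs = freqs / freqs.sum()
        q = exchange * self.freqs[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        rate = -np.dot(self.freqs, np.diag(q))
        q /= rate
        self.q = q
        # symmetric eigendecomposition: B = diag(sqrt pi) Q diag(1/sqrt pi)
        sq = np.sqrt(self.freqs)
        b = (q * sq[:, None]) / sq[None, :]
        w, u = eigh((b + b.T) / 2.0)
        self._w = w
        self._left = u / sq[:, None] * 1.0  # diag(1/sqrt pi) U
        self._right = (u * sq[:, None]).T  # U^T diag(sqrt pi)

    def transition(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t), clipped to non-negative."""
        p = (self._left * np.exp(self._w * t)) @ self._right
        return np.clip(p, 1e-300, None)


_MODEL_CACHE: dict[str, EmpiricalModel] = {}


def load_empirical_model(name: str) -> EmpiricalModel:
    key = name.lower()
    if key not in _MODEL_CACHE:
        path = resources.files("polytax.data") / f"{key}_model.tsv"
        lines = path.read_text().splitlines()
        order = lines[0].split("\t")[1:]
        assert "".join(order) == AA_ORDER
        rows = [list(map(float, ln.split("\t")[1:])) for ln in lines[1:21]]
        freqs = np.array(list(map(float, lines[21].split("\t")[1:])))
        _MODEL_CACHE[key] = EmpiricalModel(key, np.array(rows), freqs)
    return _MODEL_CACHE[key]


@dataclass(frozen=True)
class DistanceModel:
    """name: p | poisson | jtt | dayhoff | kimura-nt"""

    name: str = "p"

    def __post_init__(self) -> None:
        if self.name not in ("p", "poisson", "jtt", "dayhoff", "kimura-nt"):
            raise ValueError(f"unknown distance model {self.name!r}")


@dataclass(frozen=True)
class BootstrapSpec:
    replicates: int = 1000
    seed: int = 0
    support_threshold: float = 90.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


def _ml_distance(seq_a: str, seq_b: str, model: EmpiricalModel, pair: str) -> float:
    index = {a: i for i, a in enumerate(AA_ORDER)}
    counts = np.zeros((20, 20))
    for x, y in zip(seq_a, seq_b):
        i, j = index.get(x), index.get(y)
        if i is not None and j is not None:  # skip X / ambiguous
            counts[i, j] += 1
    if counts.sum() == 0:
        raise ValueError(f"no comparable residue pairs for {pair}")
    log_pi = np.log(model.freqs)

    def negll(t: float) -> float:
        p = model.transition(t)
        return -float(np.sum(counts * (log_pi[:, None] + np.log(p))))

    res = minimize_scalar(negll, bounds=(1e-8, 20.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"ML distance failed to converge for {pair}")
    return float(res.x)


def pairwise_distance(alignment: Alignment, model: DistanceModel) -> tuple[list[str], np.ndarray]:
    """Distance matrix (substitutions per site) between alignment rows.

    Gap-containing columns are removed first (complete deletion).
    """
    if len(alignment.rows) < 2:
        raise ValueError("need at least 2 rows")
    aln = alignment.drop_gap_columns()
    if aln.n_cols == 0:
        raise ValueError("no gap-free columns remain after complete deletion")
    n = len(aln.rows)
    d = np.zeros((n, n))
    emp = load_empirical_model(model.name) if model.name in ("jtt", "dayhoff") else None
    for i, j in itertools.combinations(range(n), 2):
        a, b = aln.rows[i], aln.rows[j]
        pair = f"({aln.labels[i]}, {aln.labels[j]})"
        if emp is not None:
            dist = _ml_distance(a, b, emp, pair)
        else:
            p = sum(x != y for x, y in zip(a, b)) / len(a)
            if model.name == "p":
                dist = p
            elif model.name == "poisson":
                if p >= 1.0:
                    raise ValueError(f"saturated distance (p >= 1) for {pair}")
                dist = -np.log(1.0 - p)
            elif model.name == "kimura-nt":
                ts = sum(
                    {x, y} in ({"A", "G"}, {"C", "T"}) for x, y in zip(a, b) if x != y
                ) / len(a)
                tv = p - ts
                inner1 = 1.0 - 2.0 * ts - tv
                inner2 = 1.0 - 2.0 * tv
                if inner1 <= 0 or inner2 <= 0:
                    raise ValueError(f"saturated distance for {pair}")
                dist = -0.5 * np.log(inner1) - 0.25 * np.log(inner2)
            else:  # pragma: no cover
                raise AssertionError(model.name)
        d[i, j] = d[j, i] = dist
    return list(aln.labels), d


# ---------------------------------------------------------------------------
# unrooted topology helper
# ---------------------------------------------------------------------------


class UnrootedTopology:
    """Adjacency-list unrooted tree over integer nodes; leaves 0..n-1 carry
    labels.  Backbone for OLS length fitting and NNI search."""

    def __init__(self, labels: list[str], adj: dict[int, set[int]]) -> None:
        self.labels = labels
        self.adj = {u: set(vs) for u, vs in adj.items()}

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (u, v) for u in self.adj for v in self.adj[u] if u < v
        )

    def copy(self) -> "UnrootedTopology":
        return UnrootedTopology(list(self.labels), self.adj)

    # -- splits ------------------------------------------------------------

    def edge_sides(self) -> dict[tuple[int, int], frozenset[int]]:
        """For each edge (u,v), the set of leaf indices on the v side."""
        sides = {}
        for u, v in self.edges():
            side = self._leaves_from(v, u)
            sides[(u, v)] = frozenset(side)
        return sides

    def _leaves_from(self, start: int, blocked: int) -> set[int]:
        out: set[int] = set()
        stack = [(start, blocked)]
        while stack:
            node, prev = stack.pop()
            if node < self.n_leaves:
                out.add(node)
            for nxt in self.adj[node]:
                if nxt != prev:
                    stack.append((nxt, node))
        return out

    def splits(self) -> frozenset[frozenset[str]]:
        """Canonical non-trivial splits as label sets (side without leaf 0)."""
        out = set()
        n = self.n_leaves
        for side in self.edge_sides().values():
            if 0 in side:
                side = frozenset(range(n)) - side
            if 2 <= len(side) <= n - 2:
                out.add(frozenset(self.labels[i] for i in side))
        return frozenset(out)

    # -- NNI ---------------------------------------------------------------

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if u >= self.n_leaves and v >= self.n_leaves
        ]

    def nni_neighbors(self) -> list["UnrootedTopology"]:
        """The two alternative topologies around every internal edge."""
        out = []
        for u, v in self.internal_edges():
            u_subs = sorted(self.adj[u] - {v})
            v_subs = sorted(self.adj[v] - {u})
            a = u_subs[0]
            for c in v_subs:
                t = self.copy()
                t.adj[u].remove(a); t.adj[a].remove(u)
                t.adj[v].remove(c); t.adj[c].remove(v)
                t.adj[u].add(c); t.adj[c].add(u)
                t.adj[v].add(a); t.adj[a].add(v)
                out.append(t)
        return out

    # -- conversion --------------------------------------------------------

    def to_phylotree(self, lengths: dict[tuple[int, int], float] | None = None,
                     clamp_negative: bool = True) -> PhyloTree:
        """Root arbitrarily at the internal node adjacent to leaf 0."""
        lengths = lengths or {}

        def get_len(u: int, v: int) -> float | None:
            key = (u, v) if u < v else (v, u)
            if key not in lengths:
                return None
            val = lengths[key]
            if clamp_negative and val < 0:
                val = 0.0
            return float(val)

        root_id = next(iter(self.adj[0])) if self.n_leaves > 1 else 0

        def build(node: int, prev: int | None) -> skbio.TreeNode:
            tn = skbio.TreeNode(
                name=self.labels[node] if node < self.n_leaves else None
            )
            if prev is not None:
                tn.length = get_len(node, prev)
            for nxt in sorted(self.adj[node]):
                if nxt != prev:
                    tn.append(build(nxt, node))
            return tn

        return PhyloTree(build(root_id, None))


def _topology_from_phylotree(tree: PhyloTree) -> tuple[UnrootedTopology, dict]:
    """Convert a PhyloTree into an UnrootedTopology, suppressing any degree-2
    root.  Returns (topology, edge lengths)."""
    tips = sorted(tree.root.tips(), key=lambda t: t.name)
    labels = [t.name for t in tips]
    ids: dict[int, int] = {}
    next_internal = [len(labels)]
    leaf_index = {t.name: i for i, t in enumerate(tips)}

    def node_id(node) -> int:
        key = id(node)
        if key not in ids:
            if node.is_tip():
                ids[key] = leaf_index[node.name]
            else:
                ids[key] = next_internal[0]
                next_internal[0] += 1
        return ids[key]

    adj: dict[int, set[int]] = {}
    lengths: dict[tuple[int, int], float] = {}

    def connect(a: int, b: int, ln: float) -> None:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
        key = (a, b) if a < b else (b, a)
        lengths[key] = lengths.get(key, 0.0) + ln

    root = tree.root
    children = root.children
    if len(children) == 2:  # suppress the rooted bifurcation into one edge
        a, b = children
        for ch in (a, b):
            for node in ch.traverse(include_self=True):
                for c2 in node.children:
                    connect(node_id(node), node_id(c2), c2.length or 0.0)
        connect(node_id(a), node_id(b), (a.length or 0.0) + (b.length or 0.0))
    else:
        for node in root.traverse(include_self=True):
            for c2 in node.children:
                connect(node_id(node), node_id(c2), c2.length or 0.0)
    return UnrootedTopology(labels, adj), lengths


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def upgma(labels: list[str], d: np.ndarray) -> PhyloTree:
    """Average-linkage agglomeration; node height = cluster distance / 2.

    Merge ties are broken by the lexicographically smallest pair of cluster
    name sets (deterministic).
    """
    _check_matrix(labels, d)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    clusters: dict[int, skbio.TreeNode] = {
        i: skbio.TreeNode(name=lab) for i, lab in enumerate(labels)
    }
    heights = {i: 0.0 for i in clusters}
    sizes = {i: 1 for i in clusters}
    names = {i: (labels[i],) for i in clusters}
    dist = {
        (i, j): float(d[i, j])
        for i, j in itertools.combinations(range(len(labels)), 2)
    }
    next_id = len(labels)
    while len(clusters) > 1:
        (i, j), dij = min(
            dist.items(), key=lambda kv: (kv[1], tuple(sorted((names[kv[0][0]], names[kv[0][1]])))),
        )
        h = dij / 2.0
        node = skbio.TreeNode()
        for k in (i, j):
            child = clusters.pop(k)
            child.length = h - heights[k]
            node.append(child)
        for k in list(clusters):
            if k == i or k == j:
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        del dist[(i, j)]
        clusters[next_id] = node
        heights[next_id] = h
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        names[next_id] = tuple(sorted(names.pop(i) + names.pop(j)))
        next_id += 1
    return PhyloTree(clusters.popitem()[1])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _check_matrix(labels: list[str], d: np.ndarray) -> None:
    d = np.asarray(d)
    if d.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")


def neighbor_joining(labels: list[str], d: np.ndarray) -> PhyloTree:
    """Studier-Keppler NJ.  Negative branch length estimates are clamped to
    zero with the deficit moved to the sister branch; the unrooted topology is
    returned rooted at an internal node (basal trifurcation)."""
    topo, lengths = _nj_topology(labels, np.asarray(d, dtype=float))
    return topo.to_phylotree(lengths)


def _nj_topology(labels: list[str], d: np.ndarray) -> tuple[UnrootedTopology, dict]:
    _check_matrix(labels, d)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    order = sorted(range(n), key=lambda i: labels[i])
    labels_sorted = [labels[i] for i in order]
    d = d[np.ix_(order, order)].astype(float)

    active = list(range(n))  # node ids into the growing graph
    dm = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    lengths: dict[tuple[int, int], float] = {}
    next_id = n

    def get(i: int, j: int) -> float:
        return dm[(i, j) if i < j else (j, i)]

    def connect(a: int, b: int, ln: float) -> None:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
        lengths[(a, b) if a < b else (b, a)] = ln

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * get(i, j) - r[i] - r[j]
            key = (q, i, j)
            if best is None or key < best:
                best = key
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:  # clamp, move deficit to sister
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        connect(i, u, li)
        connect(j, u, lj)
        for k in active:
            if k in (i, j):
                continue
            dm[(min(u, k), max(u, k))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    if len(active) == 3:
        a, b, c = active
        dab, dac, dbc = get(a, b), get(a, c), get(b, c)
        u = next_id
        la = max(0.0, 0.5 * (dab + dac - dbc))
        lb = max(0.0, 0.5 * (dab + dbc - dac))
        lc = max(0.0, 0.5 * (dac + dbc - dab))
        connect(a, u, la)
        connect(b, u, lb)
        connect(c, u, lc)

    return UnrootedTopology(labels_sorted, adj), lengths


# ---------------------------------------------------------------------------
# minimum evolution
# ---------------------------------------------------------------------------


def _ols_lengths(topo: UnrootedTopology, d: np.ndarray) -> tuple[dict, float]:
    """OLS branch lengths for a fixed topology and the resulting tree length
    (sum of raw OLS lengths, negatives allowed)."""
    n = topo.n_leaves
    edges = topo.edges()
    sides = topo.edge_sides()
    pairs = list(itertools.combinations(range(n), 2))
    a_mat = np.zeros((len(pairs), len(edges)))
    for e_idx, e in enumerate(edges):
        side = sides[e]
        for p_idx, (i, j) in enumerate(pairs):
            if (i in side) != (j in side):
                a_mat[p_idx, e_idx] = 1.0
    rhs = np.array([d[i, j] for i, j in pairs])
    sol, _, rank, _ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    if rank < len(edges):
        raise np.linalg.LinAlgError("singular OLS system for topology")
    lengths = {e: float(x) for e, x in zip(edges, sol)}
    return lengths, float(sol.sum())


def me_tree_length(tree: PhyloTree | UnrootedTopology, labels: list[str], d: np.ndarray) -> float:
    """Minimum-evolution objective: total OLS branch length of the topology."""
    topo = tree if isinstance(tree, UnrootedTopology) else _topology_from_phylotree(tree)[0]
    if sorted(topo.labels) != sorted(labels):
        raise ValueError("topology does not span the matrix labels")
    idx = [topo.labels.index(lab) for lab in labels]
    inv = np.empty(len(labels), dtype=int)
    for pos, i in enumerate(idx):
        inv[i] = pos
    d_re = np.asarray(d)[np.ix_(inv, inv)]
    _, total = _ols_lengths(topo, d_re)
    return total


def minimum_evolution(
    labels: list[str], d: np.ndarray, max_rounds: int = 1000
) -> PhyloTree:
    """ME tree: start from NJ, greedily accept the best NNI neighbor while the
    total OLS length improves.  Ties broken by canonical split-set ordering."""
    d = np.asarray(d, dtype=float)
    _check_matrix(labels, d)
    if len(labels) < 4:
        raise ValueError("minimum evolution needs >= 4 taxa")
    topo, _ = _nj_topology(labels, d)
    d_sorted_idx = sorted(range(len(labels)), key=lambda i: labels[i])
    d_s = d[np.ix_(d_sorted_idx, d_sorted_idx)]

    def canon(t: UnrootedTopology):
        return tuple(sorted(tuple(sorted(s)) for s in t.splits()))

    best_lengths, best_len = _ols_lengths(topo, d_s)
    for _ in range(max_rounds):
        candidates = []
        for nb in topo.nni_neighbors():
            ln, total = _ols_lengths(nb, d_s)
            candidates.append((total, canon(nb), nb, ln))
        candidates.sort(key=lambda c: (c[0], c[1]))
        total, _, nb, ln = candidates[0]
        if total < best_len - 1e-12:
            topo, best_len, best_lengths = nb, total, ln
        else:
            break
    return topo.to_phylotree(best_lengths)


def exhaustive_minimum_evolution(labels: list[str], d: np.ndarray) -> tuple[PhyloTree, float]:
    """Brute-force ME over all unrooted topologies (test oracle; n <= 8)."""
    d = np.asarray(d, dtype=float)
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    labs = [labels[i] for i in order]
    d_s = d[np.ix_(order, order)]
    best = None
    for topo in _all_topologies(labs):
        lengths, total = _ols_lengths(topo, d_s)
        key = (total, tuple(sorted(tuple(sorted(s)) for s in topo.splits())))
        if best is None or key < best[0]:
            best = (key, topo, lengths)
    _, topo, lengths = best
    return topo.to_phylotree(lengths), best[0][0]


def _all_topologies(labels: list[str]):
    """Sequential-addition enumeration of all unrooted binary topologies."""
    n = len(labels)
    base = UnrootedTopology(labels, {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}})

    def expand(topo: UnrootedTopology, next_leaf: int, next_internal: int):
        if next_leaf == n:
            yield topo
            return
        for u, v in topo.edges():
            t = topo.copy()
            w = next_internal
            t.adj[u].remove(v); t.adj[v].remove(u)
            t.adj[u].add(w); t.adj[v].add(w)
            t.adj[w] = {u, v, next_leaf}
            t.adj[next_leaf] = {w}
            yield from expand(t, next_leaf + 1, next_internal + 1)

    if n == 3:
        yield base
        return
    yield from expand(base, 3, n + 1)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

_BUILDERS: dict[str, Callable[[list[str], np.ndarray], PhyloTree]] = {
    "nj": neighbor_joining,
    "upgma": upgma,
    "me": minimum_evolution,
}


def build_tree(
    alignment: Alignment, model: DistanceModel, method: str = "nj"
) -> PhyloTree:
    labels, d = pairwise_distance(alignment, model)
    return _BUILDERS[method](labels, d)


def bootstrap_support(
    alignment: Alignment,
    model: DistanceModel,
    builder: str = "nj",
    spec: BootstrapSpec | None = None,
) -> PhyloTree:
    """Resample alignment columns with replacement, rebuild, and annotate the
    point-estimate tree's internal edges with percent bipartition support."""
    spec = spec or BootstrapSpec()
    if alignment.n_cols < 1:
        raise ValueError("alignment must have at least one column")
    tree = build_tree(alignment, model, builder)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(spec.seed)
    n_ok = 0
    for _ in range(spec.replicates):
        cols = rng.integers(0, alignment.n_cols, size=alignment.n_cols)
        resampled = alignment.take_columns(cols)
        try:
            rep = build_tree(resampled, model, builder)
        except (ValueError, RuntimeError):
            continue  # e.g. saturated distances in a pathological replicate
        n_ok += 1
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed")
    leaves = set(tree.leaf_names)
    anchor = min(leaves)
    for node in tree.root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        if anchor in side:
            side = frozenset(leaves - side)
        node.name = f"{100.0 * counts[side] / n_ok:g}"
    return tree
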