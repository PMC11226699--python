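"""Taxonomic decisions from similarity matrices and trees.

Species calls apply the conventional paired cutoffs (95% ANI / 70% DDH, both
inclusive); genus candidacy requires BOTH cluster-singleton status at the AAI
clustering threshold AND an isolated branch in the AAI tree — a single signal
yields an explicit "ambiguous" verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import PhyloTree, SimilarityMatrix

__all__ = [
    "DelineationPolicy",
    "TaxonCall",
    "threshold_clusters",
    "species_call",
    "genus_call",
]


@dataclass(frozen=True)
class DelineationPolicy:
    species_ani: float = 95.0
    species_ddh: float = 70.0
    verify_identity: float = 96.0
    verify_coverage: float = 90.0
    genus_aai_cluster: float = 80.0
    genus_tree_cutoff: float = 68.0

    def __post_init__(self) -> None:
        for v in (
            self.species_ani,
            self.species_ddh,
            self.verify_identity,
            self.verify_coverage,
            self.genus_aai_cluster,
            self.genus_tree_cutoff,
        ):
            if not 0 < v <= 100:
                raise ValueError("policy percentages must be in (0, 100]")


@dataclass
class TaxonCall:
    strain: str
    verdict: str  # same-species | novel-species | novel-genus-candidate | ambiguous | clustered
    nearest: str | None
    evidence: list[str]


def threshold_clusters(
    m: SimilarityMatrix,
    threshold: float,
    curated_edges: list[tuple[str, str]] | None = None,
) -> list[set[str]]:
    """Connected components of the graph with an edge wherever similarity is
    strictly above ``threshold`` ("above" read as strict).

    When ``curated_edges`` is given it REPLACES the threshold edges: the
    clustering then follows a curated edge reading (e.g. a published table's
    cluster boxes) instead of being recomputed from the raw values.
    """
    if not m.is_symmetric(tol=1e-6):
        raise ValueError("matrix must be symmetric for clustering")
    parent = {lab: lab for lab in m.labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    if curated_edges is None:
        n = len(m.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if m.values[i, j] > threshold:
                    union(m.labels[i], m.labels[j])
    else:
        for a, b in curated_edges:
            union(a, b)
    comps: dict[str, set[str]] = {}
    for lab in m.labels:
        comps.setdefault(find(lab), set()).add(lab)
    return sorted(comps.values(), key=lambda c: sorted(c)[0])


def species_call(
    strain: str,
    m_ani: SimilarityMatrix,
    m_ddh: SimilarityMatrix | None = None,
    policy: DelineationPolicy | None = None,
) -> TaxonCall:
    """same-species iff max ANI >= species_ani or max DDH >= species_ddh
    against any other strain in the matrices (inclusive boundaries)."""
    policy = policy or DelineationPolicy()
    if strain not in m_ani.labels:
        raise KeyError(f"strain {strain!r} not in ANI matrix")
    partner, max_ani = m_ani.row_max(strain)
    evidence = [f"max ANI {max_ani:.1f} vs {partner}"]
    same = max_ani >= policy.species_ani
    max_ddh = None
    if m_ddh is not None:
        if strain not in m_ddh.labels:
            raise KeyError(f"strain {strain!r} not in DDH matrix")
        ddh_partner, max_ddh = m_ddh.row_max(strain)
        flag = " (estimated)" if m_ddh.estimated else ""
        evidence.append(f"max DDH{flag} {max_ddh:.1f} vs {ddh_partner}")
        same = same or max_ddh >= policy.species_ddh
    evidence.append(
        f"cutoffs: ANI >= {policy.species_ani:g} or DDH >= {policy.species_ddh:g}"
    )
    verdict = "same-species" if same else "novel-species"
    return TaxonCall(strain, verdict, partner, evidence)


def genus_call(
    strain: str,
    m_aai: SimilarityMatrix,
    tree: PhyloTree | None = None,
    policy: DelineationPolicy | None = None,
    curated_edges: list[tuple[str, str]] | None = None,
) -> TaxonCall:
    """novel-genus-candidate iff the strain is a cluster singleton at the AAI
    threshold AND sits on its own branch in the tree (no other leaf within the
    tree cutoff, expressed as distance 1 - cutoff/100).  Conflicting evidence
    yields "ambiguous", never a silent resolution."""
    policy = policy or DelineationPolicy()
    if strain not in m_aai.labels:
        raise KeyError(f"strain {strain!r} not in AAI matrix")
    if tree is not None and not set(m_aai.labels) <= set(tree.leaf_names):
        raise ValueError("tree leaf set must cover the matrix labels")
    clusters = threshold_clusters(m_aai, policy.genus_aai_cluster, curated_edges)
    own = next(c for c in clusters if strain in c)
    singleton = len(own) == 1
    evidence = [
        f"cluster at AAI > {policy.genus_aai_cluster:g}: "
        + ("singleton" if singleton else f"grouped with {sorted(own - {strain})}")
    ]
    partner, _ = m_aai.row_max(strain)
    if tree is None:
        verdict = "novel-genus-candidate" if singleton else "clustered"
        evidence.append("no tree supplied; cluster evidence only")
        return TaxonCall(strain, verdict, partner, evidence)
    cutoff_dist = 1.0 - policy.genus_tree_cutoff / 100.0
    others = [n for n in tree.leaf_names if n != strain and n in m_aai.labels]
    nearest_leaf = min(others, key=lambda n: tree.path_distance(strain, n))
    nearest_dist = tree.path_distance(strain, nearest_leaf)
    isolated = nearest_dist > cutoff_dist
    evidence.append(
        f"tree: nearest leaf {nearest_leaf} at distance {nearest_dist:.4f} "
        f"(cutoff distance {cutoff_dist:.4f})"
    )
    if singleton and isolated:
        verdict = "novel-genus-candidate"
    elif not singleton and not isolated:
        verdict = "clustered"
    else:
        verdict = "ambiguous"
        evidence.append("cluster and tree evidence disagree")
    return TaxonCall(strain, verdict, partner, evidence)
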