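"""Universal single-copy marker selection, progressive alignment, and
concatenated alignments."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .core_io import Alignment, FormatError, Protein, ProteinSet
from .identity import AaiParams, _aa_aligner, _protein_pair_stats, rbh_aai

__all__ = [
    "OrthologTable",
    "ConcatenatedAlignment",
    "cluster_orthologs",
    "select_markers",
    "progressive_align",
    "concatenate",
    "read_ortholog_tsv",
]


@dataclass
class OrthologTable:
    """families: family id -> {strain id -> list of protein ids}."""

    families: dict[str, dict[str, list[str]]]
    tags: dict[str, frozenset[str]] = field(default_factory=dict)
    strains: list[str] = field(default_factory=list)

    def is_universal(self, family: str) -> bool:
        fam = self.families[family]
        return all(len(fam.get(s, [])) >= 1 for s in self.strains)

    def is_single_copy(self, family: str) -> bool:
        fam = self.families[family]
        return all(len(fam.get(s, [])) <= 1 for s in self.strains)


@dataclass
class ConcatenatedAlignment:
    labels: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]  # (marker, start, stop) 0-based half-open

    def __post_init__(self) -> None:
        n_cols = len(self.rows[0]) if self.rows else 0
        if any(len(r) != n_cols for r in self.rows):
            raise FormatError("rows differ in length")
        pos = 0
        for name, start, stop in self.partitions:
            if start != pos or stop < start:
                raise FormatError("partitions must tile the columns in order")
            pos = stop
        if pos != n_cols:
            raise FormatError("partitions do not cover all columns")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def as_alignment(self) -> Alignment:
        return Alignment(list(self.labels), list(self.rows))

    def residue_counts(self) -> dict[str, int]:
        """Ungapped residue count per strain (the per-strain "(aa)" report)."""
        return {
            lab: len(row) - row.count("-") for lab, row in zip(self.labels, self.rows)
        }


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------


def cluster_orthologs(
    proteomes: list[ProteinSet], params: AaiParams | None = None
) -> OrthologTable:
    """Families = connected components of the cross-strain RBH graph, with
    within-strain in-paralogs attached when a protein is closer to a same-
    strain partner than to any of its cross-strain orthologs.

    Tags of a family are the union of member protein tags.
    """
    if len(proteomes) < 3:
        raise ValueError("need at least 3 proteomes")
    params = params or AaiParams()
    # union-find over (strain, protein id)
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for ps in proteomes:
        for p in ps.proteins:
            parent[(ps.id, p.id)] = (ps.id, p.id)
    best_cross: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(proteomes, 2):
        result = rbh_aai(a, b, params)
        for ida, idb, identity in result.pairs:
            union((a.id, ida), (b.id, idb))
            for key in ((a.id, ida), (b.id, idb)):
                best_cross[key] = max(best_cross.get(key, 0.0), identity)
    # in-paralogs: same-strain pairs at least as similar to each other as
    # either is to its best cross-strain ortholog
    aligner = _aa_aligner(params)
    for ps in proteomes:
        for pa, pb in itertools.combinations(ps.proteins, 2):
            _, identity, coverage = _protein_pair_stats(
                aligner, pa.sequence, pb.sequence
            )
            if identity < params.min_identity or coverage < params.min_coverage:
                continue
            threshold = min(
                best_cross.get((ps.id, pa.id), 0.0),
                best_cross.get((ps.id, pb.id), 0.0),
            )
            if identity >= threshold:
                union((ps.id, pa.id), (ps.id, pb.id))

    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for key in parent:
        groups.setdefault(find(key), []).append(key)

    tag_lookup = {
        (ps.id, p.id): p.tags for ps in proteomes for p in ps.proteins
    }
    families: dict[str, dict[str, list[str]]] = {}
    tags: dict[str, frozenset[str]] = {}
    for idx, (root, members) in enumerate(sorted(groups.items())):
        fam_id = f"fam{idx:04d}"
        per_strain: dict[str, list[str]] = {}
        fam_tags: set[str] = set()
        for strain, pid in sorted(members):
            per_strain.setdefault(strain, []).append(pid)
            fam_tags |= tag_lookup[(strain, pid)]
        families[fam_id] = per_strain
        tags[fam_id] = frozenset(fam_tags)
    return OrthologTable(families, tags, [ps.id for ps in proteomes])


def select_markers(
    table: OrthologTable,
    required_tags: set[str] | frozenset[str] = frozenset(),
    universal: bool = True,
    single_copy: bool = True,
) -> list[str]:
    """Families present in all strains, single copy, carrying all required
    tags.  An empty result is returned as an empty list (explicit outcome)."""
    if not table.families:
        raise ValueError("ortholog table is empty")
    out = []
    for fam in sorted(table.families):
        if universal and not table.is_universal(fam):
            continue
        if single_copy and not table.is_single_copy(fam):
            continue
        if not set(required_tags) <= table.tags.get(fam, frozenset()):
            continue
        out.append(fam)
    return out


def read_ortholog_tsv(path: str | Path) -> tuple[list[ProteinSet], OrthologTable]:
    """Read the ortholog/annotation TSV: columns strain, protein_id,
    family_id (optional), tags (semicolon separated), sequence (optional)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for need in ("strain", "protein_id"):
            if need not in idx:
                raise FormatError(f"missing column {need!r} in {path}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(parts)

    def get(parts, col, default=""):
        i = idx.get(col)
        return parts[i] if i is not None and i < len(parts) else default

    per_strain: dict[str, list[Protein]] = {}
    families: dict[str, dict[str, list[str]]] = {}
    tags: dict[str, set[str]] = {}
    for parts in rows:
        strain = get(parts, "strain")
        pid = get(parts, "protein_id")
        ptags = frozenset(t for t in get(parts, "tags").split(";") if t)
        seq = get(parts, "sequence") or "M"
        per_strain.setdefault(strain, []).append(Protein(pid, seq, ptags))
        fam = get(parts, "family_id")
        if fam:
            families.setdefault(fam, {}).setdefault(strain, []).append(pid)
            tags.setdefault(fam, set()).update(ptags)
    proteomes = [ProteinSet(s, ps) for s, ps in per_strain.items()]
    table = OrthologTable(
        families,
        {f: frozenset(t) for f, t in tags.items()},
        [p.id for p in proteomes],
    )
    return proteomes, table


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

_GAP_OPEN = -11.0
_GAP_EXTEND = -1.0


def _submatrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    m = substitution_matrices.load(name)
    alpha = str(m.alphabet)
    index = {a: i for i, a in enumerate(alpha)}
    return np.asarray(m, dtype=float), index


def _profile(rows: list[str], index: dict[str, int], n_alpha: int) -> np.ndarray:
    """(L, n_alpha + 1) column count matrix; last channel counts gaps."""
    length = len(rows[0])
    prof = np.zeros((length, n_alpha + 1))
    for row in rows:
        for i, ch in enumerate(row):
            if ch == "-":
                prof[i, n_alpha] += 1
            else:
                prof[i, index.get(ch, index.get("X", 0))] += 1
    return prof


def _align_profiles(
    rows_a: list[str], rows_b: list[str], mat: np.ndarray, index: dict[str, int]
) -> tuple[list[str], list[str]]:
    """Affine-gap (Gotoh) profile-profile alignment, sum-of-pairs score."""
    n_alpha = mat.shape[0]
    pa = _profile(rows_a, index, n_alpha)
    pb = _profile(rows_b, index, n_alpha)
    na, nb = len(rows_a), len(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    # mean pairwise residue score per column pair (gap channel scores 0 here;
    # gaps inside a profile damp the column's weight)
    s = (pa[:, :n_alpha] @ mat @ pb[:, :n_alpha].T) / (na * nb)
    neg = -1e18
    m = np.full((la + 1, lb + 1), neg)
    x = np.full((la + 1, lb + 1), neg)  # gap in B (A consumed)
    y = np.full((la + 1, lb + 1), neg)  # gap in A
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        x[i, 0] = _GAP_OPEN + (i - 1) * _GAP_EXTEND
    for j in range(1, lb + 1):
        y[0, j] = _GAP_OPEN + (j - 1) * _GAP_EXTEND
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        xi = x[i - 1]
        mi = m[i - 1]
        for j in range(1, lb + 1):
            best_m = max(mi[j - 1], xi[j - 1], y[i - 1][j - 1])
            m[i, j] = best_m + s[i - 1, j - 1]
            ptr_m[i, j] = (
                0 if best_m == mi[j - 1] else (1 if best_m == xi[j - 1] else 2)
            )
            ox = m[i - 1, j] + _GAP_OPEN
            ex = x[i - 1, j] + _GAP_EXTEND
            x[i, j] = max(ox, ex)
            ptr_x[i, j] = 0 if ox >= ex else 1
            oy = m[i, j - 1] + _GAP_OPEN
            ey = y[i, j - 1] + _GAP_EXTEND
            y[i, j] = max(oy, ey)
            ptr_y[i, j] = 0 if oy >= ey else 2
    state = int(np.argmax([m[la, lb], x[la, lb], y[la, lb]]))
    i, j = la, lb
    cols: list[tuple[bool, bool]] = []  # (consume A, consume B)
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            cols.append((True, True))
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            cols.append((True, False))
            state = 0 if ptr_x[i, j] == 0 else 1
            i -= 1
        elif state == 2 and j > 0:
            cols.append((False, True))
            state = 0 if ptr_y[i, j] == 0 else 2
            j -= 1
        elif i > 0:
            cols.append((True, False))
            i -= 1
        else:
            cols.append((False, True))
            j -= 1
    cols.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = jb = 0
    for take_a, take_b in cols:
        for k, row in enumerate(rows_a):
            out_a[k] += row[ia] if take_a else "-"
        for k, row in enumerate(rows_b):
            out_b[k] += row[jb] if take_b else "-"
        ia += take_a
        jb += take_b
    return out_a, out_b


def _pairwise_pdistance(a: str, b: str, mat: np.ndarray, index: dict[str, int]) -> float:
    rows_a, rows_b = _align_profiles([a], [b], mat, index)
    ra, rb = rows_a[0], rows_b[0]
    pairs = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(x != y for x, y in pairs) / len(pairs)


def progressive_align(
    seqs: dict[str, str], matrix: str = "BLOSUM62"
) -> Alignment:
    """Progressive multiple alignment: UPGMA guide tree on pairwise
    p-distances, then profile-profile merges with affine gaps.

    Deterministic: guide-tree ties are broken by lexicographic label order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for label, s in seqs.items():
        if "-" in s:
            raise ValueError(f"input sequence {label!r} contains gap characters")
    mat, index = _submatrix(matrix)
    labels = sorted(seqs)
    if len(labels) == 2:
        a, b = labels
        ra, rb = _align_profiles([seqs[a]], [seqs[b]], mat, index)
        return Alignment([a, b], [ra[0], rb[0]])
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = _pairwise_pdistance(
            seqs[labels[i]], seqs[labels[j]], mat, index
        )
    from .phylo import upgma  # local import to avoid a module cycle

    guide = upgma(labels, d)

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [seqs[node.name]]
        parts = [merge(ch) for ch in node.children]
        labs, rows = parts[0]
        for labs_b, rows_b in parts[1:]:
            rows, rows_b = _align_profiles(rows, rows_b, mat, index)
            labs = labs + labs_b
            rows = rows + rows_b
        return labs, rows

    labs, rows = merge(guide.root)
    order = sorted(range(len(labs)), key=lambda k: labs[k])
    return Alignment([labs[k] for k in order], [rows[k] for k in order])


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------


def concatenate(alignments: list[tuple[str, Alignment]]) -> ConcatenatedAlignment:
    """Column-wise concatenation of per-marker alignments sharing one strain
    set; partition bookkeeping retained."""
    if not alignments:
        raise ValueError("no alignments given")
    label_sets = [set(aln.labels) for _, aln in alignments]
    universe = label_sets[0]
    for (name, _), ls in zip(alignments, label_sets):
        if ls != universe:
            missing = sorted(universe ^ ls)
            raise ValueError(
                f"marker {name!r} label set mismatch; differing labels: {missing}"
            )
    labels = sorted(universe)
    rows = {lab: [] for lab in labels}
    partitions = []
    pos = 0
    for name, aln in alignments:
        for lab in labels:
            rows[lab].append(aln.row(lab))
        partitions.append((name, pos, pos + aln.n_cols))
        pos += aln.n_cols
    return ConcatenatedAlignment(
        labels, ["".join(rows[lab]) for lab in labels], partitions
    )
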