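"""Domain types and plain-text I/O (FASTA, Newick, TSV) plus basic genome statistics.

Coordinates are 0-based, half-open internally; 1-based only in user-facing
reports.  All writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import skbio

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "GenomeRecord",
    "ProteinSet",
    "Protein",
    "SimilarityMatrix",
    "PhyloTree",
    "Alignment",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "gc_content",
    "at_content",
    "gc_skew",
]


class FormatError(ValueError):
    """Raised for malformed input files or sequences."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRecord:
    """A set of nucleotide replicons belonging to one strain."""

    id: str
    replicons: list[tuple[str, str]]
    topology: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.replicons]
        if len(names) != len(set(names)):
            raise FormatError(f"duplicate replicon names in genome {self.id!r}")
        for name, seq in self.replicons:
            if not seq:
                raise FormatError(f"empty sequence for replicon {name!r} in {self.id!r}")
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"illegal nucleotide characters {sorted(bad)} in replicon {name!r}"
                )
        for name in self.topology:
            if name not in set(names):
                raise FormatError(f"topology given for unknown replicon {name!r}")

    @property
    def sequence(self) -> str:
        """All replicons concatenated (analysis convenience, not a biological join)."""
        return "".join(seq for _, seq in self.replicons)

    def __len__(self) -> int:
        return sum(len(seq) for _, seq in self.replicons)


@dataclass(frozen=True)
class Protein:
    id: str
    sequence: str
    tags: frozenset[str] = frozenset()


@dataclass
class ProteinSet:
    """Named amino-acid sequences with optional annotation tags."""

    id: str
    proteins: list[Protein]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.proteins]
        if len(ids) != len(set(ids)):
            raise FormatError(f"duplicate protein ids in proteome {self.id!r}")
        for p in self.proteins:
            bad = set(p.sequence) - AMINO_ACIDS
            if bad:
                raise FormatError(
                    f"illegal amino-acid characters {sorted(bad)} in protein {p.id!r}"
                )

    def __len__(self) -> int:
        return len(self.proteins)

    def __getitem__(self, protein_id: str) -> Protein:
        for p in self.proteins:
            if p.id == protein_id:
                return p
        raise KeyError(protein_id)


class SimilarityMatrix:
    """Symmetric labeled matrix of percent identities (diagonal = 100).

    ``asymmetry`` records the largest directional disagreement folded into the
    stored mean; it is reported, never hidden.
    """

    def __init__(
        self,
        labels: Sequence[str],
        values: np.ndarray,
        kind: str = "custom",
        asymmetry: float = 0.0,
        estimated: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=float)
        labels = list(labels)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(values), 100.0):
            raise ValueError("diagonal must be exactly 100")
        off = values[~np.eye(len(labels), dtype=bool)]
        if off.size and (np.nanmin(off) < 0 or np.nanmax(off) > 100):
            raise ValueError("off-diagonal values must lie in [0, 100]")
        self.labels = labels
        self.values = values
        self.kind = kind
        self.asymmetry = float(asymmetry)
        self.estimated = estimated

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def row_max(self, label: str, exclude_self: bool = True) -> tuple[str, float]:
        """Largest off-diagonal entry in a row; returns (partner, value)."""
        i = self.labels.index(label)
        row = self.values[i].copy()
        if exclude_self:
            row[i] = -np.inf
        j = int(np.nanargmax(row))
        return self.labels[j], float(row[j])

    def is_symmetric(self, tol: float = 1e-6) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=tol, equal_nan=True))


class PhyloTree:
    """Tree with branch lengths and optional percent bootstrap support.

    Thin wrapper over :class:`skbio.TreeNode`; support values are stored as
    internal-node names for Newick round-tripping.
    """

    def __init__(self, root: skbio.TreeNode) -> None:
        self.root = root
        names = self.leaf_names
        if len(names) != len(set(names)):
            raise FormatError("duplicate leaf labels in tree")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side not
        containing the lexicographically smallest leaf."""
        leaves = set(self.leaf_names)
        anchor = min(leaves)
        out: set[frozenset[str]] = set()
        for node in self.root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(leaves - side) < 2:
                continue
            if anchor in side:
                side = frozenset(leaves - side)
            out.add(side)
        return out

    def path_distance(self, a: str, b: str) -> float:
        return float(self.root.find(a).distance(self.root.find(b)))

    def total_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self.root.traverse(include_self=False))
        )

    def support_values(self) -> dict[frozenset[str], float]:
        """Map canonical bipartition -> percent support (internal labels)."""
        leaves = set(self.leaf_names)
        anchor = min(leaves)
        out = {}
        for node in self.root.non_tips(include_self=False):
            if node.name is None:
                continue
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(leaves - side) < 2:
                continue
            if anchor in side:
                side = frozenset(leaves - side)
            out[side] = float(node.name)
        return out

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass
class Alignment:
    """Equal-length aligned rows keyed by label, '-' for gaps."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("duplicate labels in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def drop_gap_columns(self) -> "Alignment":
        """Complete deletion: remove every column containing any gap."""
        keep = [
            i for i in range(self.n_cols) if all(r[i] != "-" for r in self.rows)
        ]
        return Alignment(
            list(self.labels), ["".join(r[i] for i in keep) for r in self.rows]
        )

    def take_columns(self, idx: Iterable[int]) -> "Alignment":
        idx = list(idx)
        return Alignment(
            list(self.labels), ["".join(r[i] for i in idx) for r in self.rows]
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    header = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FormatError(f"empty FASTA header in {path}")
                chunks = []
            elif line:
                if header is None:
                    raise FormatError(f"sequence before header in {path}")
                chunks.append(line)
    if header is None:
        raise FormatError(f"empty FASTA file: {path}")
    yield header, "".join(chunks)


def read_fasta(path: str | Path, kind: str = "auto", id: str | None = None):
    """Read a FASTA file into a :class:`GenomeRecord` or :class:`ProteinSet`.

    ``kind`` is ``nucleotide``, ``protein`` or ``auto`` (alphabet sniffing).
    Sequences are upper-cased; ids are the header token before whitespace.
    """
    entries = []
    seen = set()
    for name, seq in _iter_fasta(path):
        if name in seen:
            raise FormatError(f"duplicate id {name!r} in {path}")
        seen.add(name)
        entries.append((name, seq.upper()))
    if kind == "auto":
        residues = set("".join(s for _, s in entries))
        kind = "nucleotide" if residues <= NUCLEOTIDES else "protein"
    rec_id = id if id is not None else Path(path).stem
    if kind == "nucleotide":
        return GenomeRecord(id=rec_id, replicons=entries)
    return ProteinSet(id=rec_id, proteins=[Protein(n, s) for n, s in entries])


def write_fasta(path: str | Path, entries: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment_fasta(path: str | Path) -> Alignment:
    pairs = list(_iter_fasta(path))
    return Alignment([n for n, _ in pairs], [s.upper() for _, s in pairs])


def write_alignment_fasta(path: str | Path, aln: Alignment) -> None:
    write_fasta(path, zip(aln.labels, aln.rows))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> PhyloTree:
    try:
        root = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"malformed Newick in {path}: {exc}") from exc
    return PhyloTree(root)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: str | Path, kind: str = "custom") -> SimilarityMatrix:
    """Read a labeled square matrix TSV (first row and column are labels)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = header[1:]
        rows = []
        row_labels = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(labels) + 1:
                raise FormatError(f"ragged row in matrix {path}")
            row_labels.append(parts[0])
            rows.append([float(x) if x else math.nan for x in parts[1:]])
    if row_labels != labels:
        raise FormatError(f"row/column label mismatch in {path}")
    return SimilarityMatrix(labels, np.array(rows), kind=kind)


def write_matrix_tsv(path: str | Path, m: SimilarityMatrix) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join([""] + m.labels) + "\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# genome statistics
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """(G+C) / unambiguous bases; N excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N; GC content undefined")
    return gc / denom


def at_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    at = seq.count("A") + seq.count("T")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N; AT content undefined")
    return at / denom


def gc_skew(seq: str, window: int, step: int | None = None) -> list[float]:
    """Windowed (G-C)/(G+C); windows with no G or C yield NaN."""
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step if step is not None else window
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    out = []
    for start in range(0, len(seq) - window + 1, step):
        w = seq[start : start + window]
        g, c = w.count("G"), w.count("C")
        out.append((g - c) / (g + c) if g + c else math.nan)
    return out
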