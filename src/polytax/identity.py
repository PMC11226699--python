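"""Pairwise genome and proteome identity statistics.

Fragment-based ANI (seed-and-extend in place of an external BLAST binary),
reciprocal-best-hit AAI, 16S pairwise identity, and a documented monotone
ANI->DDH approximation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .core_io import GenomeRecord, ProteinSet, SimilarityMatrix

__all__ = [
    "AniParams",
    "AaiParams",
    "AniResult",
    "AaiResult",
    "fragment_ani",
    "rbh_aai",
    "pairwise_16s_identity",
    "ddh_estimate",
    "build_matrix",
]


@dataclass(frozen=True)
class AniParams:
    """Classic fragment-ANI settings: 1020 bp fragments, 30% identity and
    70% coverage filters for a fragment to count as conserved."""

    fragment_length: int = 1020
    min_fragment_identity: float = 30.0
    min_fragment_coverage: float = 70.0
    seed_kmer: int = 15

    def __post_init__(self) -> None:
        if self.fragment_length < self.seed_kmer:
            raise ValueError("fragment_length must be >= seed_kmer")
        for p in (self.min_fragment_identity, self.min_fragment_coverage):
            if not 0 < p <= 100:
                raise ValueError("percent thresholds must be in (0, 100]")


@dataclass(frozen=True)
class AaiParams:
    min_identity: float = 30.0
    min_coverage: float = 70.0
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        for p in (self.min_identity, self.min_coverage):
            if not 0 < p <= 100:
                raise ValueError("percent thresholds must be in (0, 100]")


@dataclass
class AniResult:
    ani: float
    n_conserved_fragments: int
    n_fragments: int
    undefined: bool = False

    def __iter__(self):
        return iter((self.ani, self.n_conserved_fragments))


@dataclass
class AaiResult:
    aai: float | None
    n_orthologs: int
    pairs: list[tuple[str, str, float]]

    def __iter__(self):
        return iter((self.aai, self.n_orthologs, self.pairs))


# ---------------------------------------------------------------------------
# fragment ANI
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def _nt_aligner() -> PairwiseAligner:
    # Local (BLAST-like) extension: fragment ends or deleted spans that do not
    # match are clipped instead of being pushed through as mismatch runs, so
    # the 70% coverage filter sees deletions.  Positive expected column score
    # down to ~50% identity keeps clipping bias small (<0.2 points at 80%).
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -2.0
    return aligner


def _identity_and_coverage(alignment, fragment_len: int) -> tuple[float, float]:
    """Percent identity over aligned fragment columns and percent of the
    fragment covered by the alignment (excluding subject terminal overhang)."""
    counts = alignment.counts()
    matches = counts.identities
    mm = counts.mismatches
    t_blocks, q_blocks = alignment.aligned  # target = window, query = fragment
    if len(q_blocks) == 0:
        return 0.0, 0.0
    covered = int(sum(end - start for start, end in q_blocks))
    # columns between the anchor columns: span_t = M + inner query gaps,
    # span_q = M + inner target gaps, so columns = span_t + span_q - M
    span_t = int(t_blocks[-1][1] - t_blocks[0][0])
    span_q = int(q_blocks[-1][1] - q_blocks[0][0])
    inner_cols = span_t + span_q - (matches + mm)
    identity = 100.0 * matches / inner_cols if inner_cols else 0.0
    coverage = 100.0 * covered / fragment_len
    return identity, coverage


def _best_fragment_identity(
    fragment: str,
    subject: str,
    index: dict[str, list[int]],
    rc_index: dict[str, list[int]],
    subject_rc: str,
    params: AniParams,
    aligner: PairwiseAligner,
) -> tuple[float, float]:
    """Align one query fragment to its best seeded location in the subject
    (both strands). Returns (identity%, coverage%) of the best candidate."""
    k = params.seed_kmer
    best = (0.0, 0.0)
    best_score = -math.inf
    for strand_seq, idx in ((subject, index), (subject_rc, rc_index)):
        votes: dict[int, int] = defaultdict(int)
        for i in range(0, len(fragment) - k + 1, 4):  # stride seeds for speed
            for pos in idx.get(fragment[i : i + k], ()):
                votes[pos - i] += 1
        if not votes:
            continue
        # candidate diagonals: top 2 by votes
        diags = sorted(votes, key=votes.__getitem__, reverse=True)[:2]
        pad = max(50, int(0.2 * params.fragment_length))
        for diag in diags:
            lo = max(0, diag - pad)
            hi = min(len(strand_seq), diag + len(fragment) + pad)
            window = strand_seq[lo:hi]
            aln = aligner.align(window, fragment)[0]
            if aln.score > best_score:
                best_score = aln.score
                best = _identity_and_coverage(aln, len(fragment))
    return best


def fragment_ani(
    query: GenomeRecord, subject: GenomeRecord, params: AniParams | None = None
) -> AniResult:
    """One-directional fragment ANI of ``query`` against ``subject``.

    The query is cut into consecutive fragments of ``fragment_length``; each is
    aligned to its best seeded match in the subject (either strand) and counts
    as conserved when it passes the identity and coverage filters.  ANI is the
    mean identity over conserved fragments; with none passing the result is
    flagged undefined and reported as 0.
    """
    params = params or AniParams()
    qseq = query.sequence
    sseq = subject.sequence
    if not qseq or not sseq:
        raise ValueError("both genomes must be non-empty")
    flen = params.fragment_length
    fragments = [qseq[i : i + flen] for i in range(0, len(qseq) - flen + 1, flen)]
    if not fragments:  # genome shorter than one fragment: single-fragment fallback
        warnings.warn(
            f"genome {query.id!r} shorter than one fragment "
            f"({len(qseq)} < {flen}); using a single short fragment",
            stacklevel=2,
        )
        fragments = [qseq]
    index = _kmer_index(sseq, params.seed_kmer)
    sseq_rc = revcomp(sseq)
    rc_index = _kmer_index(sseq_rc, params.seed_kmer)
    aligner = _nt_aligner()
    identities = []
    for frag in fragments:
        ident, cov = _best_fragment_identity(
            frag, sseq, index, rc_index, sseq_rc, params, aligner
        )
        if ident >= params.min_fragment_identity and cov >= params.min_fragment_coverage:
            identities.append(ident)
    if not identities:
        return AniResult(0.0, 0, len(fragments), undefined=True)
    return AniResult(float(np.mean(identities)), len(identities), len(fragments))


# ---------------------------------------------------------------------------
# RBH AAI
# ---------------------------------------------------------------------------


def _aa_aligner(params: AaiParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.substitution_matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def _protein_pair_stats(aligner: PairwiseAligner, a: str, b: str) -> tuple[float, float, float]:
    """(score, identity%, coverage% of shorter protein) for one pair."""
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return float(aln.score), 0.0, 0.0
    m = counts.identities + counts.mismatches
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    cols = span_a + span_b - m
    identity = 100.0 * counts.identities / cols if cols else 0.0
    aligned_short = sum(e - s for s, e in blocks_b)
    coverage = 100.0 * aligned_short / min(len(a), len(b))
    return float(aln.score), identity, coverage


def rbh_aai(a: ProteinSet, b: ProteinSet, params: AaiParams | None = None) -> AaiResult:
    """Reciprocal-best-hit AAI between two proteomes.

    All-vs-all global alignment with free end gaps; mutual best-scoring pairs
    passing the identity/coverage filters define orthologs.  AAI is the mean
    identity over ortholog pairs, or ``None`` (missing, not 0) if no pair
    passes.
    """
    params = params or AaiParams()
    if not a.proteins or not b.proteins:
        raise ValueError("both proteomes must be non-empty")
    aligner = _aa_aligner(params)
    stats: dict[tuple[str, str], tuple[float, float, float]] = {}
    for pa in a.proteins:
        for pb in b.proteins:
            stats[(pa.id, pb.id)] = _protein_pair_stats(
                aligner, pa.sequence, pb.sequence
            )
    best_ab = {
        pa.id: max(b.proteins, key=lambda pb: stats[(pa.id, pb.id)][0]).id
        for pa in a.proteins
    }
    best_ba = {
        pb.id: max(a.proteins, key=lambda pa: stats[(pa.id, pb.id)][0]).id
        for pb in b.proteins
    }
    pairs = []
    for ida, idb in best_ab.items():
        if best_ba.get(idb) != ida:
            continue
        _, identity, coverage = stats[(ida, idb)]
        if identity >= params.min_identity and coverage >= params.min_coverage:
            pairs.append((ida, idb, identity))
    if not pairs:
        return AaiResult(None, 0, [])
    return AaiResult(float(np.mean([p[2] for p in pairs])), len(pairs), sorted(pairs))


# ---------------------------------------------------------------------------
# 16S identity, DDH
# ---------------------------------------------------------------------------


def pairwise_16s_identity(a: str, b: str, min_length: int = 500) -> float:
    """Global-alignment percent identity, terminal gaps excluded."""
    if len(a) < min_length or len(b) < min_length:
        raise ValueError(f"sequences must be >= {min_length} bp")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    blocks_a, blocks_b = aln.aligned
    m = counts.identities + counts.mismatches
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    cols = span_a + span_b - m
    return 100.0 * counts.identities / cols


def ddh_estimate(ani: float) -> float:
    """Monotone ANI->DDH approximation (flagged as estimated).

    Piecewise-linear map anchored at the conventional paired cutoffs: 95% ANI
    corresponds to the 70% DDH species boundary, and identity maps to
    identity, i.e. (0,0) -> (95,70) -> (100,100).  This is an explicit
    approximation, not a reimplementation of any published regression.
    """
    if not 0 <= ani <= 100:
        raise ValueError("ANI must be in [0, 100]")
    if ani <= 95:
        return ani * 70.0 / 95.0
    return 70.0 + (ani - 95.0) * 30.0 / 5.0


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


def build_matrix(
    items: Sequence, fn: Callable[[object, object], float | tuple], kind: str = "custom"
) -> SimilarityMatrix:
    """Apply a directional pairwise percent-identity function in both
    directions for every unordered pair; store the mean, record the largest
    directional asymmetry, set the diagonal to 100."""
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    labels = [it.id for it in items]
    n = len(items)
    values = np.full((n, n), 100.0)
    asym = 0.0
    for i, j in itertools.combinations(range(n), 2):
        try:
            fwd = fn(items[i], items[j])
            rev = fn(items[j], items[i])
        except Exception as exc:
            raise RuntimeError(
                f"pairwise computation failed for ({labels[i]}, {labels[j]}): {exc}"
            ) from exc
        fwd = _scalar(fwd)
        rev = _scalar(rev)
        asym = max(asym, abs(fwd - rev))
        values[i, j] = values[j, i] = (fwd + rev) / 2.0
    return SimilarityMatrix(labels, values, kind=kind, asymmetry=asym)


def _scalar(result) -> float:
    if isinstance(result, (AniResult,)):
        return result.ani
    if isinstance(result, AaiResult):
        if result.aai is None:
            raise ValueError("AAI missing (no RBH pairs passed the filters)")
        return result.aai
    if isinstance(result, tuple):
        return float(result[0])
    return float(result)
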