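"""Seeded generators for genomes, protein families, and chemotaxonomic
profiles, each returning the ground truth the pipeline is tested against.

One global seed fans out deterministically to per-generator child seeds via
``child_seed(seed, name)`` (CRC32 of the generator name mixed into a
SeedSequence), so adding a generator never shifts existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .core_io import GenomeRecord, Protein, ProteinSet
from .markers import OrthologTable
from .chemotax import ChemProfile
from .phylo import AA_ORDER, load_empirical_model

NT = "ACGT"

__all__ = [
    "EvolveSpec",
    "child_seed",
    "random_genome",
    "evolve_genome",
    "simulate_families",
    "simulate_profiles",
    "evolve_protein_pair",
    "diverged_proteome_pair",
    "true_alignment_identity",
]


def child_seed(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-generator RNG derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class EvolveSpec:
    root_length: int = 100_000
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    indel_mean_length: float = 3.0
    gene_loss_fraction: float = 0.0
    gene_length: int = 1000
    gc_target: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate, self.gene_loss_fraction):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.root_length < 1000:
            raise ValueError("root length must be >= 1 kb")


def random_genome(length: int, gc: float, rng: np.random.Generator, id: str = "root") -> GenomeRecord:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return GenomeRecord(id=id, replicons=[("chr", seq)])


def evolve_genome(
    root: GenomeRecord | None, spec: EvolveSpec
) -> tuple[GenomeRecord, GenomeRecord, tuple[str, str]]:
    """Generate (or accept) a root genome and a mutated copy.

    Returns (root, derived, true_alignment) where true_alignment is the pair
    of gapped strings relating the two sequences site by site, so identity
    oracles are exact.
    """
    rng = child_seed(spec.seed, "evolve_genome")
    if root is None:
        root = random_genome(spec.root_length, spec.gc_target, rng)
    seq = root.sequence
    out: list[str] = []
    row_root: list[str] = []
    row_der: list[str] = []
    i = 0
    n = len(seq)
    # gene loss: delete contiguous blocks ("genes") of gene_length
    lost = np.zeros(n, dtype=bool)
    if spec.gene_loss_fraction > 0:
        n_genes = n // spec.gene_length
        n_lost = int(round(spec.gene_loss_fraction * n_genes))
        if n_lost:
            for g in rng.choice(n_genes, size=n_lost, replace=False):
                lost[g * spec.gene_length : (g + 1) * spec.gene_length] = True
    while i < n:
        base = seq[i]
        if lost[i]:
            row_root.append(base)
            row_der.append("-")
            i += 1
            continue
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            length = max(1, int(rng.poisson(spec.indel_mean_length)))
            if rng.random() < 0.5:  # deletion from derived
                for j in range(i, min(i + length, n)):
                    row_root.append(seq[j])
                    row_der.append("-")
                i += length
                continue
            ins = "".join(rng.choice(list(NT), size=length))
            for ch in ins:
                row_root.append("-")
                row_der.append(ch)
                out.append(ch)
        if rng.random() < spec.substitution_rate:
            alt = rng.choice([b for b in NT if b != base])
            row_root.append(base)
            row_der.append(alt)
            out.append(alt)
        else:
            row_root.append(base)
            row_der.append(base)
            out.append(base)
        i += 1
    derived = GenomeRecord(id=f"{root.id}_derived", replicons=[("chr", "".join(out))])
    return root, derived, ("".join(row_root), "".join(row_der))


def true_alignment_identity(true_alignment: tuple[str, str]) -> float:
    """Percent identity over aligned (gap-free) columns of the true alignment."""
    a, b = true_alignment
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    return 100.0 * sum(x == y for x, y in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------


def _random_protein(length: int, rng: np.random.Generator, freqs: np.ndarray) -> str:
    return "".join(rng.choice(list(AA_ORDER), size=length, p=freqs / freqs.sum()))


def mutate_protein(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < p_sub:
            out.append(rng.choice([a for a in AA_ORDER if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def evolve_protein_pair(
    length: int, t: float, rng: np.random.Generator, model: str = "jtt"
) -> tuple[str, str]:
    """Residue pairs drawn from the stationary joint of an empirical model at
    divergence t (substitutions per site)."""
    m = load_empirical_model(model)
    p = m.transition(t)
    anc_idx = rng.choice(20, size=length, p=m.freqs)
    der_idx = np.array([rng.choice(20, p=p[i] / p[i].sum()) for i in anc_idx])
    return (
        "".join(AA_ORDER[i] for i in anc_idx),
        "".join(AA_ORDER[i] for i in der_idx),
    )


def simulate_families(
    n_strains: int = 5,
    n_families: int = 5,
    family_length: int = 120,
    divergence: float = 0.1,
    tags: dict[str, frozenset[str]] | None = None,
    missing: dict[str, list[str]] | None = None,
    duplicated: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinSet], OrthologTable]:
    """Protein families with controlled divergence, optional per-strain gene
    loss (``missing``: family -> strains) and duplication (``duplicated``).

    Returns the proteomes and the ground-truth ortholog table.
    """
    rng = child_seed(seed, "simulate_families")
    model = load_empirical_model("jtt")
    tags = tags or {}
    missing = missing or {}
    duplicated = duplicated or {}
    strains = [f"strain{i:02d}" for i in range(n_strains)]
    fam_ids = [f"fam{i:04d}" for i in range(n_families)]
    ancestors = {
        fam: _random_protein(family_length, rng, model.freqs) for fam in fam_ids
    }
    proteins: dict[str, list[Protein]] = {s: [] for s in strains}
    truth: dict[str, dict[str, list[str]]] = {fam: {} for fam in fam_ids}
    for fam in fam_ids:
        fam_tags = tags.get(fam, frozenset())
        for strain in strains:
            if strain in missing.get(fam, []):
                continue
            n_copies = 2 if strain in duplicated.get(fam, []) else 1
            for c in range(n_copies):
                pid = f"{strain}_{fam}" + (f"_copy{c}" if n_copies > 1 else "")
                seq = mutate_protein(ancestors[fam], divergence, rng)
                proteins[strain].append(Protein(pid, seq, fam_tags))
                truth[fam].setdefault(strain, []).append(pid)
    proteomes = [ProteinSet(s, proteins[s]) for s in strains]
    table = OrthologTable(
        truth, {f: tags.get(f, frozenset()) for f in fam_ids}, strains
    )
    return proteomes, table


def diverged_proteome_pair(
    n_proteins: int = 20,
    length: int = 300,
    target_identity: float = 0.80,
    seed: int = 0,
) -> tuple[ProteinSet, ProteinSet]:
    """Two proteomes whose one-to-one homologs sit at a planted pairwise
    amino-acid identity (B mutated directly from A, no indels)."""
    rng = child_seed(seed, "diverged_proteome_pair")
    model = load_empirical_model("jtt")
    a_prots, b_prots = [], []
    for i in range(n_proteins):
        seq_a = _random_protein(length, rng, model.freqs)
        seq_b = mutate_protein(seq_a, 1.0 - target_identity, rng)
        a_prots.append(Protein(f"a{i:03d}", seq_a))
        b_prots.append(Protein(f"b{i:03d}", seq_b))
    return ProteinSet("A", a_prots), ProteinSet("B", b_prots)


# ---------------------------------------------------------------------------
# chemotaxonomic profiles
# ---------------------------------------------------------------------------


def simulate_profiles(
    n_strains: int = 4,
    components: tuple[str, ...] = ("Q8", "DMK8", "MK8"),
    conditions: tuple[str, ...] = ("aerobic", "anaerobic"),
    archetypes: list[np.ndarray] | None = None,
    noise_sd: float = 0.0,
    nd_strains: tuple[str, ...] = (),
    seed: int = 0,
) -> dict[str, ChemProfile]:
    """Positive compositional profiles per condition around one or more
    archetype compositions, with additive noise renormalized to percent.

    Strains named in ``nd_strains`` get a single detected component, the rest
    ND (the single-quinone pattern).
    """
    rng = child_seed(seed, "simulate_profiles")
    k = len(components)
    if archetypes is None:
        archetypes = [rng.dirichlet(np.ones(k) * 5, size=len(conditions))]
    profiles: dict[str, ChemProfile] = {}
    for s in range(n_strains):
        strain = f"strain{s:02d}"
        arch = archetypes[s % len(archetypes)]
        prof = ChemProfile(strain)
        for ci, cond in enumerate(conditions):
            base = np.asarray(arch[ci % len(arch)], dtype=float)
            vals = np.clip(base * 100.0 + rng.normal(0, noise_sd, size=k), 1e-6, None)
            vals = 100.0 * vals / vals.sum()
            for comp, v in zip(components, vals):
                prof.values[(cond, comp)] = float(v)
        profiles[strain] = prof
    for strain in nd_strains:
        prof = ChemProfile(strain)
        for cond in conditions:
            prof.values[(cond, components[0])] = 100.0
            for comp in components[1:]:
                prof.nd.add((cond, comp))
        profiles[strain] = prof
    return profiles
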