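"""Loaders for the packaged reference fixtures (printed-table data and the
synthetic five-marker alignment)."""

from __future__ import annotations

from importlib import resources

import numpy as np

from .chemotax import ChemProfile, parse_profiles
from .core_io import Alignment, SimilarityMatrix
from .markers import ConcatenatedAlignment, concatenate
from .synthetic import child_seed, mutate_protein, _random_protein
from .phylo import load_empirical_model

REFERENCE_STRAIN = "PD-1"

# Column counts of the packaged five-marker alignment fixture; they sum to
# the 1587-column concatenated dataset the marker tree is built from.
MARKER_FIXTURE_LENGTHS = {
    "aroB": 362,
    "aroE": 272,
    "aroK": 172,
    "aroA": 427,
    "aroC": 354,
}


def _data(name: str):
    return resources.files("polytax.data") / name


def load_identity_matrix() -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """The packaged 15-strain combined identity table (lower triangle ANI,
    upper triangle AAI) as two symmetric matrices."""
    lines = _data("ani_aai_matrix.tsv").read_text().splitlines()
    labels = lines[0].split("\t")[1:]
    raw = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]])
    n = len(labels)
    ani = np.full((n, n), 100.0)
    aai = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(n):
            if i > j:  # lower triangle: ANI
                ani[i, j] = ani[j, i] = raw[i, j]
            elif i < j:  # upper triangle: AAI
                aai[i, j] = aai[j, i] = raw[i, j]
    return (
        SimilarityMatrix(labels, ani, kind="ANI"),
        SimilarityMatrix(labels, aai, kind="AAI"),
    )


def load_cluster_boxes() -> dict[str, list[str]]:
    """Curated cluster-box membership accompanying the identity table."""
    lines = _data("ani_aai_boxes.tsv").read_text().splitlines()[1:]
    return {
        name: members.split(",") for name, members in (ln.split("\t") for ln in lines)
    }


def box_edges() -> list[tuple[str, str]]:
    """Edges implied by the curated cluster boxes (chain within each box)."""
    edges = []
    for members in load_cluster_boxes().values():
        edges.extend(zip(members, members[1:]))
    return edges


def load_quinone_profiles() -> dict[str, ChemProfile]:
    lines = _data("quinone_profiles.tsv").read_text().splitlines()
    return parse_profiles(lines, "quinone_profiles.tsv")


PRINTED_QUINONE_R = {
    "M_tenebrionis_KCTC72449": 0.619,
    "E_rhapontici_KCTC22740": 0.490,
    "E_coli_MG1655": -0.464,
    "S_Typhimurium_ATCC14028": -0.347,
    "E_pyrinus_KCTC2590": -0.567,
    "E_teleogrylli_SCU-B244": -0.714,
}

ND_QUINONE_STRAINS = (
    "P_agglomerans_KACC15275",
    "P_ananatis_KACC22739",
    "P_stewartii_KACC22737",
)


def load_api_profiles() -> dict[str, list[str]]:
    lines = _data("api_profiles.tsv").read_text().splitlines()
    names = lines[0].split("\t")[1:]
    columns: dict[str, list[str]] = {n: [] for n in names}
    for ln in lines[1:]:
        parts = ln.split("\t")
        for name, val in zip(names, parts[1:]):
            columns[name].append(val)
    return columns


def load_calibration_params() -> dict[str, float]:
    lines = _data("iaa_calibration.tsv").read_text().splitlines()[1:]
    return {k: float(v) for k, v in (ln.split("\t") for ln in lines)}


def marker_alignment_fixture(
    n_strains: int = 8, seed: int = 170,
) -> tuple[list[tuple[str, Alignment]], ConcatenatedAlignment]:
    """Deterministic gapless five-marker alignment fixture whose
    concatenation has exactly 1587 columns."""
    rng = child_seed(seed, "marker_alignment_fixture")
    model = load_empirical_model("jtt")
    strains = [f"strain{i:02d}" for i in range(n_strains)]
    alignments = []
    for marker, length in MARKER_FIXTURE_LENGTHS.items():
        anc = _random_protein(length, rng, model.freqs)
        rows = [mutate_protein(anc, 0.1, rng) for _ in strains]
        alignments.append((marker, Alignment(list(strains), rows)))
    return alignments, concatenate(alignments)
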