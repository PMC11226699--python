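# polytax

Polyphasic prokaryote taxon delineation toolkit: genome/proteome identity
statistics, minimal marker-set phylogenomics, distance-based tree building,
threshold-based species/genus calls, and chemotaxonomic profile statistics.

## What it does

- **`polytax.core_io`** — domain types (`GenomeRecord`, `ProteinSet`,
  `SimilarityMatrix`, `PhyloTree`, `Alignment`), FASTA/Newick/TSV readers and
  writers, GC content and windowed GC skew.
- **`polytax.identity`** — fragment-based ANI (1020 bp fragments, seed-and-
  extend local alignment, 30%/70% identity/coverage filters),
  reciprocal-best-hit AAI over BLOSUM62 global alignments, 16S pairwise
  identity, and an explicitly approximate monotone ANI→DDH mapping.
- **`polytax.markers`** — cross-strain RBH ortholog clustering with in-paralog
  attachment, universal single-copy marker selection by annotation tag,
  progressive multiple alignment (UPGMA guide tree + profile-profile Gotoh),
  and partition-aware concatenation.
- **`polytax.phylo`** — p/Poisson distances and pairwise maximum-likelihood
  distances under packaged empirical JTT/Dayhoff models; UPGMA, neighbor
  joining (Studier–Keppler), minimum evolution (OLS branch lengths,
  nearest-neighbor-interchange search), and seeded nonparametric bootstrap
  with bipartition support.
- **`polytax.delineation`** — threshold clustering of similarity matrices
  (raw strict-threshold mode or a curated edge reading), species calls at the
  95% ANI / 70% DDH cutoffs, and combined cluster+tree novel-genus calls that
  report "ambiguous" on conflicting evidence.
- **`polytax.chemotax`** — calibration-curve fitting and inversion with
  LOD/LOQ at 3×/10× signal-to-noise, quinone molar-ratio normalization with
  ND handling, profile Pearson correlation, FAME similarity, and binary
  phenotype (API-style) similarity indices.
- **`polytax.synthetic`** — seeded generators (genome pairs with known true
  alignments, protein families with controlled divergence/copy number,
  compositional profiles) so every stage is testable offline.
- **`polytax.fixtures`** — loaders for the packaged reference tables
  (identity matrix, quinone profiles, phenotype vectors, calibration
  parameters) under `polytax/data/`.

## CLI

The `polytax` entry point exposes one subcommand per stage:

```sh
polytax ani genomes/*.fasta --out ani.tsv
polytax aai proteomes/*.fasta --out aai.tsv
polytax markers --orthologs orthologs.tsv --tag shikimate
polytax align proteins.fasta --out aligned.fasta
polytax --seed 7 tree aligned.fasta --out tree.nwk \
    --model jtt --method me --bootstrap 1000
polytax delineate --ani ani.tsv --aai aai.tsv --tree tree.nwk --out calls.tsv
polytax chemotax --profiles profiles.tsv --reference PD-1
polytax --seed 3 simulate --out-dir sim/ --length 100000 --rate 0.05
polytax pipeline --config config.yaml
```

All stochastic operations take explicit integer seeds (global `--seed` flag);
reruns with the same config are byte-identical.

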