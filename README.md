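# igsim — intergenomic similarity for viral genomes

`igsim` computes pairwise intergenomic nucleotide similarities between complete
viral genomes from all-vs-all BLASTN alignments, clusters the genomes at
species/genus thresholds, and renders an ordered similarity heatmap.

For every ordered genome pair the identical-base counts of the alignment hits
are summed after de-replicating overlapping aligned regions (every region of
either genome is credited once). The similarity of a pair is normalized to the
sum of **both** genome lengths, not the alignment length:

```
sim(A,B)  = (ident(A→B) + ident(B→A)) × 100 / (len(A) + len(B))
dist(A,B) = 100 − sim(A,B)
```

This keeps partial alignments between distant genomes from inflating the
similarity. Three alignment-quality indicators accompany each pair: the
aligned fraction of each genome and the genome length ratio
(smaller / bigger) — low length ratios flag partial- or nested-genome
comparisons that need a closer look.

## Usage

```sh
igsim run genomes.fasta -o results/
```

writes to `results/`:

| file | content |
|---|---|
| `similarity_matrix.tsv` / `distance_matrix.tsv` | ordered square matrices, 3 decimals |
| `cluster_table.tsv` | per-genome species/genus cluster labels |
| `heatmap.pdf` | similarity (upper right, labels rounded to 1 decimal) + indicator bands (lower left) + genome-length annotation |
| `hits.tsv` | all alignment hits (13-column tabular: standard 12 + identical matches) |
| `pairwise_results.tsv`, `directed_summaries.tsv` | per-pair and per-direction intermediates |
| `run.log` | config echo, aligner version, exact command lines |

Key options:

- `--param-set 1..4` — alignment stringency presets, from relaxed
  (`-word_size 7 -reward 2 -penalty -3 -gapopen 5 -gapextend 2`, the default)
  to very stringent (`-word_size 28 -reward 1 -penalty -2`). Stringent sets are
  much faster but underestimate similarity between distant genomes.
- `--species-thr 95 --genus-thr 70` — similarity thresholds for the cluster
  table (dendrogram cut at `100 − threshold`).
- `--method complete|single|average|ward|mcquitty|centroid|median` —
  agglomeration method for the hierarchical clustering that orders the output.
  The merge tree is used only for ordering and cutting; it is **not** a
  phylogeny.
- `--reuse-hits results/hits.tsv` — skip the alignment step and recompute
  similarities/clustering from a previous run's hit table (e.g. to try another
  clustering method).

Caveats baked into the method: genomes with long `N` runs (draft scaffolds)
are warned about — the aligner skips those regions and similarity is
underestimated; genomes carrying duplicated regions (e.g. double terminal
repeats) are likewise underestimated, so supply single-repeat-copy sequences.

## Library

Each pipeline stage is importable on its own: `igsim.genome_io` (FASTA
reading/validation), `igsim.aligner` (BLAST+ driver, hit-table parser, the
four parameter presets), `igsim.similarity` (de-replication, similarity and
indicators), `igsim.clustering`, `igsim.reporting`, and `igsim.synth`
(deterministic synthetic-genome and hit-table generators used by the tests).

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property-based checks (hypothesis) of the de-replication
algorithm against an independent per-base coverage-painting oracle, and
end-to-end acceptance tests (`tests/test_acceptance.py`) that drive BLAST+ on
synthetic 40 kb fixtures: permutation/reverse-complement invariance,
parameter-stringency behavior, the detection sensitivity floor, and
mutation-rate recovery. Two optional tests that download public genome
records are gated behind `IGSIM_NETWORK_TESTS=1`.

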