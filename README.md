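# genarch

Decompose a genome assembly into its architectural domains — conserved
chromosome cores, repeat-rich subtelomeres, multigene-family arrays,
gene deserts — from the sequence alone, with optional gene-annotation and
user-supplied tracks.

`genarch` is aimed at genome biologists who have a (possibly new) assembly
and want an unsupervised, annotation-light map of its chromosome
organisation, and at methods developers who need a windowed feature
extraction + clustering pipeline that is fully scriptable and
deterministic.

## Method

1. **Windows.** Every scaffold is partitioned into non-overlapping windows
   of *w* bp (default 5 000); the trailing partial window is kept.
2. **Features.** Per window, from sequence alone: GC%, AT/GC skew, CpG
   dinucleotide percentage, stop-codon frequency (TAA/TAG/TGA, any frame),
   telomere-motif and CAG-repeat frequency (reverse complement included),
   N%, a DUST-style low-complexity fraction, a perfect-tandem-repeat
   fraction (unit ≤ 12 bp), *k*-mer deviation (Euclidean distance between
   the window's *k*-mer spectrum and the assembly-wide spectrum, *k* = 3, 4),
   and a mappability depth (error-free fragments tiled at 10× and
   down-weighted by their exact-match multiplicity — unique sequence scores
   ~10, sequence in *m* copies ~10/*m*). A GFF3 adds per-window gene
   densities by type and mean gene length / exon count / exon and intron
   lengths; any bedgraph can be re-binned onto the grid. Motifs, codons and
   *k*-mers straddling a window border are counted in neither window.
3. **Clustering.** Features are min-max scaled to [0, 1], embedded in 2-D
   with UMAP (*n* = `n_neighbours`) and clustered with HDBSCAN
   (*c* = `min_cluster_size`; label −1 = unclassified). A sweep over a grid
   of (*n*, *c*) reports silhouette, Davies–Bouldin and Calinski–Harabasz
   scores, cluster counts and the unclassified percentage; the recommended
   cell minimises unclassified windows first, then maximises silhouette.
4. **Characterisation.** Each cluster × feature is tested with two
   one-sided two-sample Kolmogorov–Smirnov tests against all other
   windows, giving D⁺/D⁻ calls ("∧" higher, "∨" lower, "−" dispersed;
   α = 1e-20). Adjacent-window cluster junctions are tested for enrichment
   with Fisher's exact test (Benjamini–Hochberg corrected), and clusters
   can be intersected with annotated intervals or split at a subtelomere
   distance (default 200 kb from scaffold ends).

A synthetic-genome module plants these architectures (GC-rich
telomere-motif repeat ends, divergently duplicated gene-family arrays,
AT-rich gene-dense cores) with per-base truth labels, so the whole
pipeline can be validated end to end with an adjusted Rand index.

## Worked example

```python
import genarch as ga

genome = ga.simulate_genome(ga.parasite_preset(), seed=0)   # 3 chromosomes, ~3 Mb
grid   = ga.partition_windows(genome.records, 5000)
tracks = ga.extract_seq_features(genome.records, grid)
model  = ga.GenomeDecomposition(ga.merge_tracks(tracks, grid))

res = model.fit(n_neighbours=20, min_cluster_size=50, seed=42)
print(res.summary())
```

```
Genome decomposition results
============================================================
windows:            600  (window size 5000 bp)
features:           13
n_neighbours (n):   20
min_cluster_size:   50
seed:               42
clusters:           3
unclassified:       2.00%
silhouette:         0.8121
davies_bouldin:     0.2528
calinski_harabasz:  3168.2
------------------------------------------------------------
cluster 0: 120 windows (20.0%)
  high: gc_percentage, cpg_percentage, cag_freq
  low:  stop_codon_freq, low_complexity_fraction, tandem_repeat_fraction, mappability_depth
cluster 1: 60 windows (10.0%)
  high: gc_percentage, cpg_percentage, cag_freq, kmer_deviation_kmer_size_3, kmer_deviation_kmer_size_4
  low:  stop_codon_freq, low_complexity_fraction, tandem_repeat_fraction
cluster 2: 408 windows (68.0%)
  high: stop_codon_freq, low_complexity_fraction, tandem_repeat_fraction, mappability_depth
  low:  gc_percentage, cpg_percentage, cag_freq, kmer_deviation_kmer_size_3, kmer_deviation_kmer_size_4
```

The three clusters recover the planted architecture: cluster 0 is the
low-mappability multigene-family arrays, cluster 1 the GC-rich
telomere-adjacent repeat regions, cluster 2 the AT-rich core. Scoring the
labels against the planted truth:

```python
ari, confusion = ga.score_recovery(res.labels, genome.truth, grid)
# ari = 0.992; all 408 core and 120 multigene windows correct,
# 60/72 tare windows correct, 12 unclassified.
```

The same run from a shell:

```bash
genarch simulate --seed 0 -o sim/
genarch extract sim/genome.fasta --gff3 sim/genome.gff3 -o feat/
genarch sweep feat/features.tsv -o sweep/          # metrics for 16 (n, c) cells
genarch cluster feat/features.tsv -n 20 -c 50 -o out/   # BED + TSVs + figures
```

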