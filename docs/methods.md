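# Methods

## The decomposition model

`genarch` treats genome architecture discovery as unsupervised
classification of fixed-size windows. Each window is a sample; its
coordinates in feature space are simple, cheap statistics of its own
sequence (and optionally of a gene annotation or external tracks). The
assumption is that architecturally distinct chromosome domains — cores,
subtelomeric repeat regions, multigene-family arrays, gene deserts —
differ in enough of these statistics simultaneously that they separate as
density modes after dimensionality reduction. No positional information
enters the clustering: windows cluster purely by content, and the
chromosome-level banding emerges only when labels are painted back onto
coordinates. That the clusters are spatially coherent is therefore a
finding, not an artefact of the method.

Windows are non-overlapping so that every part of the genome receives
exactly one label. The trailing window of each scaffold is kept even when
short; frequency features normalise by the window's *effective length*
(its non-N base count), so short or gappy windows remain comparable.
All-N windows receive each feature's degenerate value (0, or 100 for N%)
and are carried through — windows are never dropped.

## Feature definitions and numerical choices

- **GC%** = 100·(G+C)/(A+C+G+T); N excluded from the denominator. Skews
  are (G−C)/(G+C) and (A−T)/(A+T), defined as 0 when the denominator is 0.
- **CpG** = overlapping "CG" count per 100 dinucleotide start positions
  (effective length − 1). **Stop-codon frequency** = overlapping
  TAA/TAG/TGA occurrences on the forward strand, any frame, per position
  (effective length − 2). Forward-only keeps the feature strand-signed,
  like GC skew. Using length−(k−1) rather than length in the denominator
  is the natural "positions where a match could start" normalisation.
- **Motif frequencies** (telomere motif, default TTTAGGG; CAG) count
  overlapping matches plus the reverse complement, per 100 bp. The
  telomere motif is configurable because it is lineage-specific.
- **Border rule.** Every motif/codon/k-mer is counted only if wholly
  inside the window; matches straddling a window border are counted in
  neither window. This follows from computing features on the window's
  substring and is verified by an exact accounting property test.
- **k-mer deviation** is the Euclidean distance between the window's
  normalised k-mer frequency vector and the assembly-wide vector
  (forward strand, N-containing k-mers skipped), for k = 3 and 4.
  Euclidean distance was chosen as the simplest symmetric, bounded
  metric; L1 or cosine could be swapped behind the same operation.
- **Low-complexity fraction** scores 64-bp frames (step 16) by the DUST
  triplet statistic 10·Σc(c−1)/2/(T−1) and masks frames scoring > 20;
  masked frames are merged and the masked fraction reported. Random
  sequence scores ~5 (unmasked), homopolymers ~310. This is a
  deliberately simplified low-complexity detector, not a re-implementation
  of any external masker, and is named accordingly.
- **Tandem-repeat fraction** marks maximal perfect tandem runs: for unit
  u ∈ 1..12, stretches where s[i] = s[i−u] sustained so the repeated
  region spans ≥ 2u bases (two full copies). Note the deliberate
  literalism: with u = 1 any "AA" qualifies, so random sequence has a
  baseline fraction near 0.6. The feature is informative through its
  *contrast* (true repeat regions reach 1.0) rather than its absolute
  level; min-max scaling makes this explicit.
- **Mappability depth** is a deterministic surrogate for simulated-read
  mapping: error-free fragments of length L = 150 are tiled every L/10 bp,
  and each adds 1/(number of exact full-length match loci in the
  assembly, both strands) to per-base depth over its footprint; the
  window value is the mean, bounded by [0, 10]. Unique sequence scores
  ~10; an m-fold duplicated segment ~10/m. Exact-match counting uses a
  double 31-bit polynomial rolling hash (combined 62-bit keys); the
  collision probability at the few-Mb scale is ~1e-6, negligible against
  the 5% calibration tolerance. Scaffolds shorter than L contribute no
  fragments and score 0. This surrogate ignores sequencing error and
  near-exact repeats: copies diverged by more than ~1/L per base look
  fully unique to it, whereas a real read mapper degrades gradually.

## Scaling, embedding, clustering

Features are min-max scaled per column to [0, 1]; constant columns map to
all-0 (stated policy, not an inherited library accident). Window merging
(e.g. 5 kb → 50 kb for large genomes) averages raw values with
window-length weights — conserving length-weighted sums of additive
features — and re-scales afterwards.

UMAP embeds the scaled matrix in 2-D (Euclidean metric,
`min_dist` = 0.1, fixed `random_state`), and HDBSCAN clusters the
embedding coordinates; −1 marks unclassified windows. With a fixed seed
the whole run is bit-reproducible, a contract the test suite enforces on
file bytes. Quality metrics (silhouette, Davies–Bouldin,
Calinski–Harabasz) are computed in embedding space over classified
windows only — embedding space is what HDBSCAN actually clusters; a
configuration switch would allow feature-space silhouettes instead. A
point set with zero spread is assigned a single cluster directly, since
density clustering of identical points is degenerate.

`select_params` ranks sweep cells by (unclassified % ascending,
silhouette descending, number of clusters descending), breaking ties
toward smaller n and c. The ranking deliberately prefers classifying
everything over maximising silhouette: a high-silhouette clustering that
discards a tenth of the genome has hidden part of the architecture. The
recommendation is advisory — the CLI `cluster` command requires an
explicit (n, c), keeping the final choice with the analyst.

## Cluster statistics

Each (cluster, feature) pair is tested with two one-sided two-sample
Kolmogorov–Smirnov tests — cluster windows against all other windows,
unclassified included in the "rest" (they are genomic windows too, just
not a cluster row). D⁺ significant alone ⇒ "higher" (∧), D⁻ alone ⇒
"lower" (∨), both ⇒ "dispersed" (−). The two-one-sided construction (as
opposed to one two-sided test plus direction inspection) is declared
explicitly and validated against exhaustive enumeration of all pooled-
sample assignments on small samples. α defaults to 1e-20, appropriate for
the thousands-of-windows sample sizes this test is run at; p-values are
asymptotic in the pipeline, exact in the small-sample validation path.
KS calls are invariant under monotone transforms of a feature, so raw and
scaled values give identical calls.

Junction enrichment counts unordered label pairs of adjacent windows
within scaffolds (self-pairs included, scaffold boundaries excluded,
−1 a category of its own — this preserves the conservation law
Σ observed = Σ_s (windows_s − 1)). Each pair's count is compared against
its expectation under the marginal label frequencies via Fisher's exact
test on the observed-vs-expected 2×2 table, BH-corrected across pairs.

Subtelomeric windows are those starting within 200 kb of a scaffold's 5'
end or ending within 200 kb of its 3' end; scaffolds shorter than 400 kb
are entirely subtelomeric.

## The synthetic genome generator

Segments draw bases i.i.d. at a target GC — the simplest model under
which GC%, skews, CpG, k-mer deviation and mappability separate segment
types. The default parasite-like preset builds three chromosomes of
0.9–1.1 Mb: GC-rich (0.55) 60-kb ends carrying telomere-motif arrays,
100-kb multigene-family arrays (GC 0.30) built by tandem-duplicating a
10-kb unit, and an AT-rich (GC 0.19) gene-dense core. Duplicated copies
diverge at 0.002/base: perfectly identical copies would make windows
exact duplicates in feature space — degenerate for a nearest-neighbour
graph and unrealistic for recently expanded gene families — while this
divergence leaves the surrogate mappability in multigene segments near
3.5× of the 10× maximum, the regime observed in real parasite genomes.
Genes (1–4 exons, length ~N(1500, 400²)) are placed uniformly without
overlap at the segment's density. Segment lengths are multiples of the
5-kb window so truth labels are unambiguous per window.

What passing tests on this generator do **not** show: robustness to
isochore-scale GC gradients, Markovian base dependence, degraded repeat
families, sequencing gaps, or assembly error — real-genome performance
depends on contrasts this generator idealises. The generator's role is
to verify the pipeline's mechanics (feature math, scaling, clustering,
scoring) under conditions where the right answer is known.

## Problem sizes

The test suite and the acceptance script run on the ~3 Mb preset
(600 windows × 13 features), a 2 Mb mappability-calibration genome, and
3 × 200 kb miniatures for end-to-end determinism checks — sizes chosen so
the full validation cycle completes in about a minute on one CPU while
still exercising every code path at realistic window counts for a small
eukaryotic genome. The pipeline itself is linear in genome size except
for the sweep (one UMAP embedding per n value).

## Known limitations

- The mappability surrogate and the low-complexity/tandem detectors are
  simplified, deterministic definitions; their outputs correlate with,
  but do not equal, read-simulation pipelines or dedicated maskers.
- HDBSCAN never returns the all-points root cluster, so parameter cells
  with c larger than every density mode report 0 clusters and 100%
  unclassified rather than one big cluster; such rows are visible in the
  sweep table and excluded from recommendation.
- Repeat-family, orthology and retrotransposon features are not computed;
  they enter only as user-supplied bedgraph tracks.
- KS p-values in the pipeline are asymptotic; for clusters of only a few
  windows the calls are conservative and a warning is emitted.
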