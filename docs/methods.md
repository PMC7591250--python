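# Methods

## The estimator

`phzquant` estimates what fraction of the bacteria in a shotgun metagenome
carry a functional trait, using phenazine biosynthesis and biodegradation
as the target traits.  The estimator works on translated reads mapped to a
protein reference catalog with best-hit semantics and proceeds in four
steps:

1. **Translated best-hit search.** Each nucleotide read is translated in
   all six frames and assigned to at most one reference protein — the
   highest-scoring local alignment across all frames and proteins, with
   score ties resolved by the first occurrence in the database.  Reads
   mapping with less than 80% amino-acid identity are discarded; the
   boundary (exactly 80%) is retained.
2. **Size normalization.** Filtered hits are pooled per gene family and
   divided by the family's average gene size in kilobases
   (mean amino-acid length × 3 / 1000), giving reads per kilobase (RPK).
   Pooling at the family level makes counts comparable across strain
   variants of the same gene.
3. **Median scores.** The "total-bacteria" score is the median RPK across
   25 universal single-copy marker families (drawn from the most
   ubiquitous bac120 genes in real use); the phenazine score is the median
   RPK across the five core biosynthesis families (`phzA_B`, `phzD`,
   `phzE`, `phzF`, `phzG`; `phzA`/`phzB` are merged because their
   sequences are nearly identical, and `phzC` is excluded because
   near-identical copies occur in non-producer genomes).  Medians make
   both scores robust to non-specific signal concentrated in one or two
   families: the phenazine score is exactly zero unless at least three of
   the five families carry signal.  Each biodegradation gene (`phdA`,
   `podA`) is scored by its own RPK.
4. **Trait fraction.** The trait score divided by the total-bacteria score
   estimates the fraction of bacteria carrying the trait, which is valid
   when the trait genes occur in a single genomic copy (as the core
   phenazine operon almost always does).  Fractions are not clamped at 1;
   values above 1 indicate a catalog or sample pathology and produce a
   warning.  Samples are flagged "phz-rich" at ≥ 0.25% and "high" at
   ≥ 0.5%.

Dividing the culturable count of a trait-positive group (cfu/g) by its
estimated fraction extrapolates the total bacterial load per gram; the
package exposes this as `extrapolate_bacterial_load`.

### Assumptions

* Single-copy trait and marker genes; multi-copy genes inflate fractions
  proportionally.
* DNA abundance is interpreted as organism abundance; with unequal genome
  sizes, the ratio estimates the genome-frequency-weighted (read) fraction
  rather than the cell fraction.
* The catalog spans the environmental sequence diversity to within the
  identity threshold; variants more than ~20% diverged in amino acid space
  are invisible at the default 80% filter.
* DNA signal says nothing about metabolic activity.

## Internal translated search

The internal aligner is a seeded, banded protein search intended for
synthetic and desk-scale data (for production-size surveys an external
translated aligner such as DIAMOND can be used; its tabular best-hit
output is parsed by `parse_hit_table`).

* **Seeding.** Exact amino-acid k-mers (default k = 5) shared between a
  reading frame and a catalog protein nominate (protein, diagonal)
  candidates.  Seeds within 64 diagonals are merged into one candidate
  cluster; ambiguous residues (`X` from N-containing codons, stops) never
  seed and never count as identities.
* **Extension.** Each candidate is scored with a banded affine-gap
  Smith-Waterman (BLOSUM62, gap open 11, gap extend 1) over diagonals
  within `band` (default 10) of the cluster.  For gap-free optima — every
  error-free read drawn from a reference-derived gene — the banded score
  equals the unrestricted Smith-Waterman optimum; the band only matters
  for chance alignments on random sequence, whose best-scoring segment
  can fall outside every seed band.  The search space (seeded pairs,
  band geometry) is therefore part of the documented contract, as it is
  for every seeded aligner.
* **Reporting.** Alignments shorter than 15 columns are dropped (a guard
  against spurious micro-hits on 100–150 nt reads).  An optional raw-score
  reporting floor (`min_report_score`) skips traceback for hopeless
  alignments; since any alignment with ≥ 80% identity over ≥ 15 columns
  scores at least 36 under BLOSUM62, the benchmark pipeline sets 36
  without affecting anything downstream of the identity filter.  Percent
  identity is matches / alignment columns × 100 (BLAST `pident`
  convention).
* **Determinism.** Ties are resolved by catalog order, then frame order
  (+1, +2, +3, then the reverse-complement frames), then the earliest end
  cell in column-major order; gap states prefer opening over extending and
  the H state prefers diagonal over target-gap over query-gap.  Repeated
  runs are byte-identical.

Two implementations share these semantics: a numba reference and a C
extension (SSE2-vectorized score pass) used when available.  The test
suite pins them to each other and to an independently written, exhaustive
pure-python dynamic-programming oracle — unrestricted Smith-Waterman on
reference-derived reads, and the band-restricted equivalent on arbitrary
reads including pure random sequence.

## Synthetic data generator

The simulator emulates the structure of a real validation, not its scale:

* **Catalog.** 25 marker families, the five merged phenazine families and
  the two degradation genes, with random ancestor proteins of 150–450
  amino acids.  Markers carry one catalog sequence per family; trait
  families carry one variant per producer/degrader species (needed for
  species-level attribution), separated by 20% inter-species divergence so
  cross-species hits fall below the identity filter.
* **Genomes.** Each species embeds exactly one copy of every marker
  family; producers additionally embed the five phenazine families and
  degraders the two degradation genes.  Genomic gene copies are mutated at
  `divergence` (default 10%) amino-acid positions relative to their
  catalog sequence, so reads map at ≈ 100 × (1 − divergence) percent
  identity.  Genes are reverse-translated with random codons, embedded on
  random strands and padded with uniform random intergenic sequence to a
  default genome length of 100 kb — a deliberate miniature of real 2–10 Mb
  genomes that keeps marker coverage high enough for stable medians at
  desk-scale library sizes.
* **Communities.** Producer fractions are set exactly (largest-remainder
  rounding of fraction × library size, so ground truth is exact to within
  one read); mixed-producer communities split a fixed total uniformly at
  random; each community carries a log-uniform random degrader fraction
  (0.05–5%); background composition is re-drawn per replicate from a
  symmetric Dirichlet(1).  Reads are error-free 150 nt fragments sampled
  uniformly from both strands (an optional uniform substitution rate is
  available); multinomial read allocation is available behind a flag.

What the simulator does **not** emulate: sequencing errors and quality
profiles, real inter-genome homology and shared gene content, host DNA,
real genome sizes, and catalog holes (environmental lineages absent from
the reference).  Passing benchmarks therefore demonstrate the estimator's
statistical behaviour under its stated assumptions, not its robustness to
every real-world artefact.

## Benchmark design

The full factorial mirrors a complete in-silico validation: coverages
{5, 10, 15, 20}M reads × spiked abundances {0, 0.1, 0.25, 0.5, 1, 1.5,
2.5, 3.5, 5}% × three producer combinations × 12 replicates = 1296
communities (48 per combo × abundance cell pooled over coverages).  The
desk-scale default — coverages {0.5M, 1M}, abundances {0, 0.1, 0.25, 0.5,
1, 2.5, 5}%, 3 replicates, 126 communities — runs on one CPU in minutes
and is what the tests and the acceptance script execute; the full design
remains available through the same API.

Reported metrics: Pearson r over (known, estimated) pairs across all
communities; the per-species error distribution restricted to producers
spiked above 0.1%; the maximum estimate across negative controls (exactly
zero with error-free reads, because background genomes contain no trait
loci and the phenazine median suppresses stray single-family hits); and
the operational detection limit, defined as the lowest designed abundance
whose replicate estimates all strictly exceed every negative-control
estimate — a definition chosen because the underlying claim ("as little
as 0.1% is detectable") states an outcome, not a criterion.

## Survey aggregation

Per-sample quantifications join with sample metadata (habitat class
`soil` or `rhizosphere`, plus a free-text sub-habitat).  Habitat
comparison reports per-class means/medians of the phenazine fraction, the
fold difference of class means (mean-of-samples, not pooled), a two-sided
Wilcoxon rank-sum test (normal approximation with tie correction), and
the enrichment of high-phz samples (≥ 0.5%) in rhizospheres over soils
(undefined, and flagged as such, when no soil sample is high).  The
taxon × habitat matrix pools hit-level size-normalized signal across all
samples of a habitat before renormalizing each column — so deeply
sequenced samples weigh proportionally — with per-sample averaging
available as an option.

## Numerical and design choices

* RPK uses the family mean amino-acid length × 3; the unit convention
  cancels in the trait fraction.
* "Average gene size" is the mean over the hit's *family*, not the
  individual target protein: family pooling is what makes counts
  comparable across strains.
* The phenazine median runs over the five merged families; merging
  `phzA`/`phzB` at the catalog level is equivalent to merging at scoring
  time and simpler.
* Edge effects (reads straddling gene boundaries map only when ≥ 15
  aligned columns survive) bias per-family RPK by a factor ≈ 1 + 60/L for
  gene length L nt; the bias largely cancels between trait and marker
  medians because both draw lengths from the same distribution, and it
  does not affect correlation-based validation.
* Degenerate inputs: an empty read set yields an empty hit table; a
  zero marker score makes the trait fraction an error ("no bacterial
  signal"); a constant known-abundance vector makes the benchmark
  correlation an error rather than a NaN.
* Paired-end data are not modelled; by convention only read-1 files are
  quantified.

## Known limitations

* The internal aligner holds the whole k-mer index in memory and is
  single-threaded; it is not a substitute for DIAMOND on billion-read
  surveys.
* Fractions are ratios of medians; confidence intervals are not reported
  (replicate simulations are the supported way to gauge variance).
* The simulator's background genomes share no homology with the catalog,
  so the false-positive regime it probes is weaker than real soil
  communities with distant phenazine-like sequences; the `phzC` exclusion
  and the median rule are the real-data mitigations.
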