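# Methods

## Model and procedure

The pipeline operates on a panel of recombinant inbred strains (RIS):
every strain is homozygous at every locus and carries one of the two
parental alleles, coded A/B (0/1). Heterozygous genotype calls are
treated as missing — in an inbred panel they are genotyping artifacts,
not states of the model.

**LOD scan.** For each transcript, strain-level log2 expression is
regressed on the allele code at each marker in turn. The test statistic
is the LOD score

    LOD = (n/2) · log10(RSS0 / RSS1),

with RSS0 the residual sum of squares about the grand mean, RSS1 from
the one-way genotype-group-mean fit and *n* the strains with complete
data at that marker. For a biallelic marker this equals
−(n/2)·log10(1 − r²), which the test suite uses as an independent
check. The scan is single-marker by design: at the marker densities the
downstream stages consume, the peak *marker* position is the only
quantity used, and interval mapping between markers would add nothing
the rest of the pipeline can see. Kinship/polygenic correction and
permutation thresholds are out of scope; the genome-wide LOD threshold
is a fixed 3.3.

**Cluster definition.** A cis-eQTL cluster is a maximal run of
cis-eQTL gene starts on one chromosome in which consecutive starts are
separated by at most the window size (250, 500 or 750 kb), with at
least three members. Gaps are measured between transcription starts —
the only coordinate attached to a cis-eQTL — and the cluster span runs
from the first to the last member start (half-open); gene ends are
never used. The greedy left-to-right merge yields the unique maximal
partition, so the result is independent of input order and idempotent.

**Null region sets.** Three comparison sets calibrate every downstream
statistic:

* *Control clusters* — the same max-gap merge applied to **all**
  detected genes, with candidates dropped when their span exceeds the
  largest cis-cluster span for the same window, or when they overlap a
  cis-cluster span. The overlap exclusion makes controls a genuine
  non-cis null; the span cap operationalizes size matching, and every
  run reports two-sample t-tests of span and member count against the
  cis clusters so the match is auditable.
* *Random boxes* — placed uniformly over the genome (chromosome chosen
  with probability proportional to length − size), rejected and
  resampled when overlapping a cis-cluster span. Boxes may overlap one
  another; they are independent draws from the genomic background.
* *Single-eQTL regions* — boxes of the mean cis-cluster span centered
  on each cis-eQTL gene that belongs to no cluster, clipped at
  chromosome edges.

*Minimal haplotype blocks* — intervals between consecutive informative
markers — serve two purposes: showing that high coexpression is a
property of the clusters rather than of whole linkage blocks, and
providing the inside-vs-outside density comparison for feature tracks.

**Coexpression.** The coexpression of a gene group is the mean over
all pairs of the absolute Pearson correlation of strain-level
expression (pairwise-complete over strains; pairs with zero variance
are skipped with a warning). Absolute values are deliberate: members of
an allele-driven cluster may respond in either direction. Random gene
groups (default 500, sizes uniform on 3–11 for the 250 kb window, 3–19
for 500 kb) are *gene sets*, sampled genome-wide without regard to
position. Two groups are compared by Student's t-test, more by one-way
ANOVA followed by Tukey's HSD.

**Enrichment.** Each region is grown by the configured flank (250, 500
or 1000 kb) and clipped at chromosome edges; features overlapping the
grown region by ≥ 1 bp count once each. Density is count per Mb of the
*clipped* length (a clipped region must not be inflated), and all
densities are divided by the mean density over the random boxes, so the
random group averages exactly 1 and other values read as fold
difference. Any-overlap counting (rather than midpoint containment) is
the standard interval-intersection semantic and is what the brute-force
oracle in the tests checks. Group means are reported with SEM; per
track a one-way ANOVA + Tukey HSD across region kinds, and across
tracks a two-way ANOVA (kind × track) with interaction.

**Cross-dataset overlap.** Cluster *spans* (not flank-grown regions)
are intersected with ≥ 1 bp half-open semantics, directionally in both
orders. Imported external eQTL lists are filtered at FDR ≤ 0.2
(inclusive) and never re-thresholded by LOD; cis/trans is assigned by
the same 1 Mb gene-start rule.

## Synthetic study conditions

The generator produces the conditions the analysis is designed for and
is itself a tested, first-class module.

* **Genome** — 5 chromosomes × 100 Mb, a deliberate ~5× scale-down of
  a mammalian autosome set; 1000 markers on an even 0.5 Mb grid.
* **Genotypes** — per strain and chromosome, a two-state Markov chain:
  first marker Bernoulli(1/2), each subsequent marker flips parental
  state with probability `marker_switch_prob` (default 0.10). The RIS
  map expansion (RI genomes carry roughly 4× the F2 recombination
  density) is absorbed into this single parameter rather than modelled
  mechanistically: only the marginal genotype correlation structure
  matters downstream. The default gives adjacent-marker r² ≈ 0.64 and
  LD that decays within the 1 Mb cis window. This is a faster per-Mb
  decay than a real RIS panel shows at multi-Mb marker spacing — the
  choice is dictated by peak localization: with near-perfect LD between
  neighboring grid markers, a transcript's peak marker frequently lands
  more than 1 Mb from the gene and the cis call fails for reasons that
  have nothing to do with the signal.
* **Genes** — 2000 transcription starts, uniform per chromosome;
  baseline log2 expression N(9, 1). Ten planted clusters of 4 genes
  occupy consecutive starts within a 250 kb span centered on an
  informative "driving" marker (so the locus always lies inside the
  span); background genes are kept out of the planted spans.
* **Expression** — for gene *g* in cluster *c* with driving marker
  *m*: y = μ_g + s_g·β·x(m,s) + s_g·ρ·F(c,s) + ε, with per-gene random
  sign s_g (direction of regulation is not uniform within a cluster),
  a shared standard-normal latent factor F per cluster and strain, and
  ε ~ N(0, σ²). The theoretical within-cluster coexpression is
  |r| = (β²/4 + ρ²)/(β²/4 + ρ² + σ²).
* **Effect sizes** — defaults β = 3.2 σ and ρ = √0.44 σ. These are the
  unique knobs that satisfy the two defining properties of the domains
  the method targets: within-cluster |r| = 0.75, and member genes
  individually mappable at LOD ≥ 3.3 with 24 strains (genotype share
  of variance β²/4 / (β²/4 + ρ² + σ²) = 0.64, expected LOD ≈ 5.3). A
  smaller allelic effect with a larger latent loading can produce the
  same coexpression, but its members would not be callable cis-eQTLs
  at this panel size — and a cluster of non-eQTLs is not a cis-eQTL
  cluster.
* **Detection layer** — four replicates per strain; detection
  Bernoulli(0.95) per replicate, with a 5% subset of background genes
  at Bernoulli(0.2) so the >50%-of-replicates filter has real work to
  do. Strain-level means are simulated directly; the replicate layer
  exists only for the filter, since linkage runs on strain means.
* **Feature tracks** — piecewise-homogeneous Poisson processes with
  fixed 200 bp feature length: rate λ_in per Mb inside planted spans
  grown by 250 kb, λ_out elsewhere; overlapping inside intervals are
  merged before emission so no segment is sampled twice. Defaults
  λ_in = 12, λ_out = 4 per Mb — a 3× contrast at densities matching
  observed polymorphic-SINE catalogs (order 10/Mb inside candidate
  regions, 4–5/Mb outside). Each bundle carries one enriched
  ("sine_polymorphic") and one homogeneous ("sine_fixed") track.

**What the generator does not emulate:** clustered (gene-rich/poor)
gene placement, distance-dependent recombination, array noise models,
sequence-level feature structure, paralog clusters, and the very high
adjacent-marker LD of sparse real maps. Consequences: control clusters
drawn from the uniform gene background are slightly *thinner* in member
count than planted clusters (the span match holds; the member-count
t-test can flag the difference at some seeds), and minimal haplotype
blocks are grid-spacing sized (0.5 Mb) rather than multi-Mb, so the
inside-vs-outside-block density comparison in the full pipeline is
informative but tighter than in a sparse-map panel. Passing tests
demonstrate correctness of the machinery and recoverability of planted
structure under these idealized conditions, not performance on any real
panel.

## Numerical choices

* Coordinates are 0-based half-open everywhere; 1-based annotation
  starts are converted once on load. Chromosome names are taken
  verbatim from inputs.
* Perfect (zero-residual) fits are reported as LOD = 50 — finite, far
  above any threshold in use — and logged.
* Peak ties are broken toward the lowest (chromosome, position):
  deterministic output.
* Missing data: per-marker complete-case in the scan,
  pairwise-complete in correlations; markers with one genotype class
  after missing-removal score LOD 0; monomorphic marker pairs get r² =
  NaN.
* A one-way ANOVA whose between-group sum of squares is exactly zero
  can produce a numerically negative F and an undefined p in floating
  point; this no-effect case is reported as p = 1.
* All thresholds follow declared boundary conventions, exercised in
  the tests: detection filter strictly > 0.5; LOD ≥ 3.3 inclusive; cis
  window ≤ 1 Mb inclusive; probe-SNP score strictly > 100; external
  FDR ≤ 0.2 inclusive; interval overlap requires ≥ 1 bp (abutment is
  not overlap).
* Every run logs the fully resolved configuration, and pipeline output
  is a pure function of (inputs, config, seed); reruns are
  byte-identical.

## Problem sizes

The default study conditions are 24 strains, 1000 markers, 2000 genes
and 10 planted clusters of 4 genes — sizes at which a full pipeline run
takes a few seconds, so the statistical test battery (20 replicate
seeds for recovery/separation/enrichment, 100 seeds for the null
battery) runs in minutes. The acceptance script uses 10 replicate
bundles.

## Known limitations

* Interval mapping, mixed-model kinship correction and
  permutation-based thresholds are not implemented.
* Control-cluster matching controls span directly and member count
  only indirectly; on backgrounds with uniform gene density the member
  count of controls is systematically slightly lower than that of
  planted clusters.
* The probe-SNP artifact check is exposed as a library function and
  reported alongside clusters, but the default pipeline does not
  auto-exclude flagged genes; exclusion is the caller's decision.
* Cross-assembly liftover and acquisition of real TE/ChIP-seq/eQTL
  catalogs are out of scope; external lists must already be on the
  panel's assembly.
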