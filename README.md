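# eqtlclust

Detection and characterization of **cis-eQTL clusters** — gene
coexpression domains under local genetic control — in panels of
recombinant inbred strains (RIS).

## The problem

In a RIS panel, each strain is a fixed homozygous mosaic of two
parental genomes. Mapping each transcript's abundance against the
genotype yields expression QTLs (eQTLs); an eQTL is *cis* when its peak
marker lies within 1 Mb of the gene's transcription start. Usually a
cis-eQTL is treated as a property of one gene. But if a local
polymorphism (for instance a polymorphic SINE retrotransposon carrying
regulatory or chromatin-organizing motifs) influences a whole
neighborhood, several neighboring genes will map to the *same* small
region — a cluster of cis-eQTLs whose members are strongly coexpressed.
This package finds such clusters and asks whether the underlying
regions are structurally distinctive.

## The method

For gene *g* with strain-level expression *y* and a biallelic marker
with allele code *x* ∈ {0, 1} over *n* strains, the single-marker
evidence is the LOD score

    LOD = (n/2) · log10(RSS0 / RSS1) = −(n/2) · log10(1 − r²)

where RSS0/RSS1 are residual sums of squares about the grand mean and
the genotype-group means, and *r* is the Pearson correlation of *y*
with *x*. The pipeline:

1. **Detection filter** — keep genes detected in >50% of replicates in
   at least one strain.
2. **Scan** — per-gene LOD at every marker; eQTL when peak LOD ≥ 3.3;
   *cis* when the peak marker is within 1 Mb of the gene start.
3. **Clusters** — merge cis-eQTL gene starts left to right while
   consecutive gaps ≤ 250/500/750 kb; keep runs of ≥ 3 genes. The
   cluster span runs from the first to the last member gene start.
4. **Null region sets** — size-matched *control clusters* (same merge
   over all detected genes, capped at the largest cis span, excluding
   cis-overlapping candidates), *random boxes* (uniform over the
   genome) and *single-eQTL regions* (boxes centered on unclustered
   cis-eQTLs); *minimal haplotype blocks* (intervals between
   consecutive informative markers).
5. **Coexpression** — per group, mean pairwise |Pearson r| across
   strains; groups compared by t-test / one-way ANOVA + Tukey HSD.
6. **Enrichment** — features per Mb of each flank-augmented region,
   normalized by the random-group mean (random group ≡ 1), compared by
   one- and two-way ANOVA + Tukey HSD.
7. **Overlap** — directional ≥1 bp intersection of cluster-region sets
   across tissues or panels; externally computed eQTL lists can be
   imported at an FDR ≤ 0.2 cutoff and clustered the same way.

A first-class synthetic-data module generates a complete RIS bundle —
Markov-mosaic genotypes, expression with planted allele-driven
coexpression clusters, Poisson feature tracks with elevated density
inside the planted regions — plus the ground truth, so the whole
pipeline is testable end to end without external data.

## Worked example

```python
import eqtlclust as ec

bundle = ec.simulate_bundle(seed=7)          # 24 strains, 2000 genes,
result = ec.run_pipeline_on_bundle(bundle)   # 10 planted clusters of 4
```

prints nothing by itself; querying the result object:

```text
genes detected:      1951 / 2000
eQTLs at LOD >= 3.3: 334 (38 cis)
cis-eQTL clusters:   10
control clusters:    76
coexpression |r|:    cis 0.752 +/- 0.040, control 0.171 +/- 0.066, random 0.169 +/- 0.034
cis vs control Tukey p: 0.00e+00
polymorphic-SINE fold enrichment in cis regions: 3.67
two-way ANOVA region-kind effect p: 1.14e-16
planted clusters recovered: 10 / 10
```

Read: the detection filter kept 1951 genes; 38 genes are cis-eQTLs, of
which the max-gap merge (250 kb window) forms 10 clusters — all 10
planted coexpression domains, whose members correlate at |r| ≈ 0.75
while matched control clusters and random gene groups sit near the
n = 24 null expectation (≈ 0.17). The polymorphic-SINE track, planted
at 3× density inside the cluster regions, is recovered at 3.7-fold
(Poisson noise around 3) with a decisive region-kind effect.

The same stages are available from the shell:

```sh
eqtlclust simulate --seed 7 --out-dir sim/
eqtlclust run --genotypes sim/genotypes.tsv --expression sim/expression.tsv \
    --detection sim/detection.tsv --annotation sim/annotation.tsv \
    --chrom-sizes sim/chrom.sizes --track sim/track_sine_polymorphic.bed \
    --track sim/track_sine_fixed.bed --seed 1 --out-dir run/
eqtlclust overlap --set-a run/clusters_cis.bed --set-b other/clusters_cis.bed \
    --out-dir overlap/
```

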