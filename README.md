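# repadapt

Tools for asking how the *same* adaptation arose repeatedly across separate
populations — from multi-population SNP data, did a beneficial allele arise
independently in each population, spread between them by gene flow, or sweep
from shared standing variation?

The package grew out of the population-genomics workflow used to dissect
repeated herbicide (glyphosate) resistance in the common morning glory
*Ipomoea purpurea*: several geographically separate populations evolved high
resistance, and the question is whether they did it the same way. It is
aimed at population geneticists with a multi-population VCF, a phenotype
panel, and a gene annotation.

## What it computes

**Scans.** Windowed (25-SNP) nucleotide diversity π, Tajima's D, unnormalized
Fay & Wu's H (θ_π − θ_H, requires ancestral alleles) and Nei's
G_ST = 1 − H_S/H_T for samples pooled by phenotype class; per-SNP pairwise
Weir–Cockerham F_ST (θ̂, 1984 variance components, negatives set to 0) with
locus-bootstrap confidence intervals; composite genotype-correlation r² LD
summaries per chromosome.

**Outliers and regions.** A joint empirical-quantile outlier criterion per
SNP — top 1% of a pooled R-vs-S G_ST differentiation score AND top 5% of
|Spearman ρ| between population allele frequency and the phenotype — on a
1-SNP-per-kb thinned marker set, followed by gap-based region delimitation,
a randomized-regrouping null, and gene-family enrichment of the regions by
resampling same-size region sets from the annotated genome.
(The differentiation score is a documented stand-in for Bayes-factor-based
outlier callers, which are deliberately not reimplemented.)

**Haplotype groups.** Per region: pairwise genetic distance between
individuals → classical MDS to 2-D → k-means (k=2) → the cluster holding the
minority of susceptible-population individuals is the resistant ('R')
haplotype group.

**Convergence mode.** A composite-likelihood comparison of four models of
repeated adaptation. Population allele frequencies x at a site distance d
from the selected site are modelled as MVN with mean ε and covariance
ε(1−ε)F′(d), where F is the neutral coancestry matrix and F′ encodes
hitchhiking with probability y = exp(−r·d·τ), τ = log(1/p₀)/s:

- *independent mutation*: each selected population sweeps on its own
  background (only F′_ii inflated);
- *migration*: a source population seeds the others with lag
  δ = log(1/m)/s, correlating selected populations (y_i y_j cross terms);
- *standing variation*: lineages recombine off or coalesce on the standing
  haplotype during t generations, giving a distance-dependent
  between-population decay y²e^(−2 r d t).

Parameters (s, g, t, m, source, selected position) are grid-searched and
models ranked by maximum composite log-likelihood ratio against the neutral
model, with a dense-t refinement of the standing fit.

**Synthetic truth.** A seeded generator builds the whole study design —
8 populations (4 resistant averaging 89% survival, 4 susceptible averaging
16%), 10 diploids each, 5 chromosomes, one injected sweep per convergence
mode, and a toy annotation with clustered detoxification-family genes
(cytochrome P450s, glycosyltransferases, ABC transporters, glutathione
S-transferases) — so every stage can be tested against known ground truth.

## Worked example

```python
from repadapt import synthetic, outliers, regions
from repadapt.haplogroups import haplotype_groups_for_region

gm, panel, genes, truth = synthetic.make_default_scenario(seed=1)
thinned = outliers.thin_snps(gm, seed=2)
scan = outliers.resistance_scan(thinned, panel)
regs = regions.delimit_regions(scan)
print(f"{int(scan.table.outlier.sum())} outlier SNPs of {len(scan.table)}; "
      f"{len(regs)} regions; "
      f"{100*regions.fraction_in_regions(scan, regs):.0f}% of outliers inside")
for r in regs:
    ga = haplotype_groups_for_region(gm, panel, r, seed=3)
    print(r.region_id, r.chrom, truth.sweep_for_chrom(r.chrom).model,
          [round(ga.r_proportion[p], 2) for p in panel.of_class("R")])
```

prints

```
116 outlier SNPs of 13493; 3 regions; 78% of outliers inside
region_1 chr2 independent [0.0, 0.0, 0.0, 1.0]
region_2 chr3 migration [1.0, 1.0, 1.0, 1.0]
region_3 chr4 standing [0.0, 0.0, 0.0, 1.0]
```

All three injected sweep regions are recovered. The migration-mode sweep —
the analogue of a resistance allele spread by gene flow — puts the resistant
haplotype group in 100% of individuals of all four resistant populations,
while the independent-origin and old-standing sweeps leave each resistant
population on its own haplotype (only one population ends up in the
"R" cluster), exactly the contrast the haplotype rule is designed to expose.

There is also a CLI: `repadapt simulate | scan | regions | windows | ld |
popstats | haplogroups | converge | all` (see `repadapt --help`), driven by
a YAML config with explicit per-stage seeds and a JSON run manifest.

## Caveats

The generator is a truncated-MVN frequency model matched to the inference
model's own assumptions (self-consistency, not realism): it has no
within-haplotype linkage and its site-frequency spectrum is not the neutral
coalescent one. `docs/methods.md` spells out what this does and does not
validate.
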