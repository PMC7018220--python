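# Methods

## The model of repeated adaptation

The convergence test treats per-population alt-allele frequencies at each
SNP as draws from a multivariate normal. At a neutral site with (unknown)
ancestral frequency ε, the K-vector of population frequencies x has mean
ε·1 and covariance ε(1−ε)F, where F is the K×K coancestry matrix describing
how drift is shared among populations. A sweep at physical distance d from
the site distorts F into a model-specific F′(d) through the hitchhiking
probability

    y = exp(−r·d·τ),   τ = log(1/p₀)/s,

the chance a neutral lineage stays attached to the beneficial haplotype
through a sweep of (deterministic) duration τ; p₀ is the frequency the
beneficial allele starts from — 1/(2Ne) for a new mutation, the standing
frequency g for a standing variant. The three non-neutral models differ in
which entries of F are inflated:

- **independent**: F′_ii = y² + (1−y²)F_ii for each selected population i;
  off-diagonal entries untouched (each population sweeps its own
  haplotype).
- **migration**: the source population c uses y_c = exp(−r_d·τ); recipients
  use y_i = exp(−r_d(τ+δ)) with migration lag δ = log(1/m)/s; every
  selected pair mixes as F′_ij = y_i y_j + (1 − y_i y_j)F_ij.
- **standing**: during the t generations the variant stood before
  selection, two lineages either coalesce on it (rate K_s = 1/(2Ne·g)) or
  recombine off (rate 2r_d):
  P_coal = K_s/(K_s+2r_d)·(1−e^(−(K_s+2r_d)t)), P_through = e^(−(K_s+2r_d)t);
  within selected populations the sweep weight is y²(P_coal+P_through),
  between them y²e^(−2r_d·t).

These are deliberately simple normative forms — deterministic sweep
duration, no staggered onsets, migration folded into a single lag — and the
package's own simulator (which draws sites from exactly these covariances)
is the self-consistency surface. No agreement with any external
convergence-inference software is claimed or tested.

Composite likelihood: per SNP the across-population mean frequency is the
plug-in for ε; the observation is centered and projected to K−1 dimensions
(removing the direction the plug-in makes uninformative), the model
covariance ε̂(1−ε̂)F′(d) + diag(ε̂(1−ε̂)/2n_k) is projected the same way, and
Gaussian log-densities are summed over SNPs as if independent. Composite
likelihoods rank models; they are not χ²-calibrated and no p-values are
attached to ratios.

### Model ranking and the independent/standing overlap

As t → ∞ the standing model's between-population term dies at any distance
and its covariance converges to the independent-mutation model; the two
hypotheses are then mathematically indistinguishable (the data genuinely
cannot separate "very old standing variant" from "separate origins").
Ranking is therefore maximum composite log-likelihood ratio with one
interpretation rule: if the standing fit sits at the top of its t grid, or
its fitted between-population decay length 1/(2·r·t̂) is shorter than the
median marker spacing (no pair of sampled sites could resolve a shared
origin), and its lead over the independent model is under 10
log-likelihood units, the independent model — the simpler origin story —
is ranked first. A standing signal resolvable at the data's marker density
is never reordered.

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| Ne | 7.5×10⁵ | effective size used throughout the convergence machinery |
| split_time | 2.89×10⁵ gen | population-split context constant for interpreting t̂ |
| r | 10⁻⁷ /bp/gen | recombination rate; chosen so sweep footprints are local at the ~1 Mb scale (at 10⁻⁸ a strong sweep's hitchhiking probability is still ~0.5 five Mb away, and no statistic would be "far" from a sweep on a 30 Mb chromosome) |
| s grid | 0.01…1 | weak to maximal selection |
| g grid | 10⁻⁶…0.1 | new-mutation-like to common standing frequency |
| t grid | 0…10⁴ gen | immediate to effectively-independent standing times |
| m grid | 10⁻⁴…1 | rare migrants to free exchange |
| window | 25 SNPs | non-overlapping, within-chromosome; trailing partial windows dropped |
| outlier rule | top 1% score ∧ top 5% \|ρ\| | joint empirical quantiles on the thinned set |
| thinning | 1 SNP / 1 kb | keeps empirical quantiles from being driven by local marker redundancy |
| max_gap | 500 kb | region delimitation gap, calibrated on the bundled scenario (below) |
| min_outliers | 5 | minimum cluster size for a region |
| r² span rule | windowed mean r² > 0.25 | elevated-LD spans |
| n_resample / n_rand / n_boot | 1000 / 100 / 1000 | enrichment, regrouping null, F_ST CIs |

Region delimitation replaces a by-eye judgement with single-linkage
clustering of outlier positions. The gap parameter is a genuine free
choice; it was calibrated once on the bundled synthetic scenario so that
the injected sweep regions are recovered exactly while flagged background
SNPs (whose typical spacing at a 1% flag rate over these marker densities
is ~1.5 Mb) do not chain into spurious multi-Mb regions. A 2 Mb gap — a
natural first guess — fails the second requirement badly.

## What the synthetic generator is, and is not

`synthetic.make_default_scenario` draws ε ~ Uniform(0.05, 0.95) per site,
population frequencies MVN(ε, ε(1−ε)F) truncated to [0.01, 0.99], redraws
sites near each sweep center from the model covariance F′(d) above, and
samples diploid genotypes binomially under within-population HWE. The
default design: 8 populations (survival 0.83/1.0/1.0/0.71 resistant,
0.10/0.18/0.15/0.20 susceptible — means 89% and 16%), 10 diploids each,
five 30 Mb chromosomes at ~3000 markers apiece with a dense 800-marker
core (±400 kb) around each sweep, emulating a targeted-capture design;
sweeps: migration (m=1, s=0.65) — the strongly shared region; old standing
(g=10⁻⁶, t=3000, s=1) — the regime that shadows independent mutation;
independent (s=0.8). The coancestry matrix has diagonals 0.12–0.20
(resistant populations slightly more drifted, one connected pair) and
off-diagonals 0.03.

Three structural gaps matter for interpreting green tests:

1. **No linkage.** Sites are drawn independently given the sweep
   covariance, so the only LD in the data is stratification LD between
   differentiated sites. Windowed mean r² in the strongest sweep core is
   ~3× the neutral background (≈0.05 vs ≈0.017) but never approaches the
   0.25 elevated-span rule that real haplotype structure would produce;
   the elevated-LD span check on synthetic data fails for this reason and
   is expected to.
2. **No coalescent SFS.** The uniform ε spectrum has far more
   high-frequency derived alleles than neutrality, so the generator's own
   "neutral" background has D ≈ +2.3 and strongly negative H by
   construction. Neutral-centering checks of D and H therefore run on
   msprime constant-size coalescent simulations (which also makes them an
   independent cross-check of the implementations); sweep effects on D/H
   in the scenario are assessed against the generator's own background,
   not against zero.
3. **Truncation bias.** Clipping frequencies to [0.01, 0.99] compresses
   variance near a sweep center relative to the unbounded MVN the
   likelihood assumes; the fit absorbs this as a faster decay, biasing ŝ
   low by one to two grid cells for the symmetric (independent, standing)
   models. Mode *ranking* is robust to this; point estimates of s are
   reliable only where an asymmetric structure anchors the decay scale
   (migration). Removing the truncation restores ŝ recovery, confirming
   the mechanism.

F is identifiable only up to row/column centering (the per-site mean
frequency stands in for the unknown ε), which is harmless because the
likelihood only ever sees the centered projection; the moment-recovery
test accordingly uses a mean-centered F.

## Numerical choices

- Frequencies are clipped to [0.01, 0.99] before likelihood evaluation;
  singular projected covariances get a 10⁻⁸ ridge (logged).
- Covariance batches are Cholesky-factorized per SNP (vectorized), which
  keeps a reduced-grid model comparison on a 200-SNP region near one
  second.
- Tajima's constants use n = the rounded mean non-missing allele count
  over a window's sites; windows with no segregating sites report D and H
  as NaN, never 0. H sums run over ancestral-known sites only.
- Negative classical-MDS eigenvalues (non-Euclidean distances) are
  discarded with a logged notice; k-means uses k-means++ with 20 restarts
  and a fixed seed; an exact tie in the susceptible-minority rule marks a
  region's haplotype assignment ambiguous rather than picking a side.
- Survival exactly 0.5 classifies susceptible (ties to S), with a warning.
- Percent summaries round half-up.
- Enrichment p-values use the plus-one correction (1 + #{null ≥ obs}) /
  (n + 1); resampled regions are placed uniformly and non-overlapping,
  which reproduces region sizes but not gene-density variation — p-values
  for families that track gene-dense regions are optimistic.
- One global seed expands into per-stage seeds via `numpy.random
  .SeedSequence`; identical configs give byte-identical outputs.

## Problem sizes

Default test and analysis sizes were chosen for interactive desk-scale
runs: 15k markers × 80 samples for the scenario; 50k sites for moment
recovery; 200-SNP regions, 20 replicates per mode at reduced grids for the
recovery experiment; 200 replicates for null-uniformity checks. The full
default pipeline completes in about a minute on one CPU.

## Known limitations

- The empirical-quantile outlier rule always flags a fixed fraction of
  markers, so — unlike evidence-thresholded outlier callers — the
  randomized-regrouping null cannot return "no outliers"; with balanced
  8-population designs roughly half of admissible random splits share
  three of the four selected populations and retain genuine (partial)
  sweep signal. The null summary is reported, not tested against zero.
- Outliers flagged by the pooled-G_ST score are biased toward sites where
  the selected populations moved coherently; among-selected F_ST contrasts
  should therefore be computed over all SNPs in a region, not over flagged
  sites (the region-level contrast is what the pipeline reports).
- Composite-likelihood ratios are not calibrated test statistics; the
  neutral-data ratio distribution is seed-stable but model-dependent.
- Very recent standing variation (t of a few generations) is
  operationally indistinguishable from migration, and very old standing
  variation from independent mutation; the package resolves these limits
  by explicit, documented conventions rather than pretending to separate
  them.
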