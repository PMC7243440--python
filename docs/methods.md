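# Methods

This note records the models implemented, the conventions adopted where the
standard metrics are underspecified, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Null models

### βMNTD and the phylogeny-pool null

βMNTD is always abundance-weighted: counts are converted to per-sample
relative abundances before weighting, and taxa present in both samples
contribute a nearest-taxon distance of zero. The null ("phylogeny pool")
preserves each sample's richness and its observed abundance vector and
reassigns the vector to a uniformly random subset of the regional pool's
tips, independently per sample and per randomization. The regional pool is
the union of taxa present in the analyzed sample set; per-timescale
analyses therefore recompute the null on their own sub-dataset. βNTI uses
the sample (n−1) standard deviation of the null distribution. Pairs whose
null distribution has zero spread — which happens when both samples contain
every pool taxon, so βMNTD is identically zero under any relabeling — are
reported as NaN and excluded from partitions, with a logged count.

Default ensemble size: 1000 randomizations (configurable, minimum 99).
Every pair draws its nulls from an independent counter-based substream
keyed by (seed, pair indices), so results do not depend on iteration order
and subsets of samples can be recomputed without perturbing other pairs.

### RC_bray

The Raup–Crick null fixes each sample's richness S and total reads N;
builds a null sample by drawing S taxa without replacement with probability
proportional to regional occupancy (number of occupied samples), giving
each drawn taxon one read, and distributing the remaining N−S reads
multinomially in proportion to regional relative abundance restricted to
the drawn taxa; and compares the observed Bray–Curtis value against the
null distribution: RC = 2·[(#null < obs) + ½(#null = obs)]/n_null − 1.
Default 999 randomizations. RC_bray is computed on rarefied counts (equal
N makes the null's fixed-total constraint meaningful).

A property worth knowing when interpreting RC_bray: the two-phase null
(presence draw, then abundance fill) has more between-sample variance than
a single multinomial draw whenever many taxa sit near the detection
boundary of the sequencing depth. Datasets that are plain multinomial
samples of one metacommunity are therefore scored slightly
"more-similar-than-null" (RC < 0) when the rank-abundance tail is broad,
and the metric is only approximately calibrated there. The calibration
check in the test suite uses a moderate lognormal σ = 0.8 rank-abundance
curve at 5000 reads, where the exceedance rate |RC| > 0.95 stays below
10%; at σ ≥ 1 with hundreds of borderline-rare taxa it can exceed that.
This is a property of the metric's standard construction, not of this
implementation.

### Classification and partitioning

The (βNTI, RC) plane is partitioned exactly as in the standard two-step
framework: selection is judged on βNTI alone (> +2 variable, < −2
homogeneous, RC ignored); within |βNTI| < 2, RC > +0.95 is dispersal
limitation and RC < −0.95 homogenizing dispersal; everything else is
undominated. Boundary convention: values exactly at ±2 or ±0.95 are
non-significant (strict inequalities); a flag flips this. Process
fractions are class counts over classified pairs; deterministic =
variable + homogeneous selection, stochastic = dispersal limitation +
homogenizing dispersal, and the three aggregates sum to one.

Across-era analyses default to using **all** pairs of the sub-dataset
(cross-era and within-era alike); `cross_pairs_only=True` restricts to
cross-era pairs. Both are provided because either reading of "separately
conducted by sub-datasets" is defensible. The stochasticity-vs-timescale
trend is an ordinary least-squares fit of the stochastic fraction on the
span in years.

## Phylogenetic signal

Niche optima are abundance-weighted means of each environmental variable
over samples (optimum_iv = Σ_s f_is·env_sv / Σ_s f_is); niche distance is
Euclidean over z-scored optima across all twelve chemistry variables
(z-scoring prevents unit dominance; the variable set and metric are
package conventions, as the upstream literature leaves them open).
The Mantel correlogram partitions the phylogenetic-distance range into
equal-width classes (Sturges' rule on the pair count by default); the
per-class statistic is the Pearson correlation between niche distances and
the class-membership indicator, negated so positive r means within-class
niche similarity. Significance is a two-sided permutation test (taxon
labels of the niche matrix permuted, default 999 permutations), with
progressive Bonferroni correction across classes. Classes with fewer than
3 pairs are reported NaN; sparsely populated classes are conservative
because the permutation distribution is discrete. The pipeline's signal
gate warns — it does not abort — when no significant positive
shortest-class r is found, since βNTI interpretation presupposes niche
conservatism.

## Supporting statistics

Bray–Curtis, NMDS (scikit-learn non-metric MDS, Kruskal stress-1, 10
random restarts by default, best configuration centered), PERMANOVA and
Mantel tests (scikit-bio, seeded, free permutation, p ≥ 1/(n_perm+1)),
Pearson (default) or Spearman alpha–environment correlations with the
conventional significance stars. Alpha diversity: observed richness,
classic Chao1 S_obs + F1²/(2F2) (F2 = 0 → S_obs + F1(F1−1)/2 — the
uncorrected estimator appropriate to rarefied counts), Shannon in nats,
Faith's PD including the path to the root. Environmental variable groups:
all 12; soil fertility {TN, TP, Na, Ca, Cu, K, Mg, Zn, SOC}; redox
{Fe, Mn}; nutrient defaults to {SOC, TN, TP} (the fertility-positive
macronutrient trio) — the nutrient membership is a package default and is
configurable, since no standard definition exists.

## Biomarker selection

Family-level relative abundances are regressed against successional time
with a random-forest regressor (500 trees, mtry = p/3 — the classic
regression defaults). The era is encoded as its age midpoint in years
(ordinal regression; a categorical mode can be had by passing any other
response). Importance is permutation importance (mean increase in MSE,
10 shuffles), the analog of %IncMSE, chosen over impurity importance,
which is biased for correlated compositional features. Because importance
is evaluated on the fitted data, null features retain a small positive
offset; rankings, not absolute values, are the interface. The
cross-validated elimination curve repeatedly keeps the top half of
features by importance (re-ranked each stage) and records k-fold CV MSE;
biomarkers are the top-k families (k = 13 by default, or the smallest
ladder point within 5% of the curve minimum when k = "auto").

## Synthetic chronosequence generator

The generator emulates the target study design: layers at 2-cm intervals
mapped to five successional eras (default full-size shape: 23 layers × 3
replicates = 69 samples, eras holding 5/4/3/3/8 layers over 0–630 years,
65,000 reads per sample, a few thousand taxa). A Yule tree provides the
phylogeny (the simulator adds the standard Exp(nλ) hang time after the
n-th tip, so the expected root-to-tip depth is Σ_{k=2..n} 1/(λk));
Brownian motion on that tree provides a single standardized niche trait,
giving phylogenetically conserved niches. Per layer, a Gaussian niche
filter exp(−(trait − z_l)²/2w²) reweights a lognormal metacommunity; the
community then mixes a fraction `mig` of this filtered regional pool with
the previous layer's community (optionally passed through a drift
bottleneck), and reads are multinomial. The chemistry table embeds the
latent niche axis in an SOC/TN/TP fertility ramp and an Fe/Mn redox
switch, with replicate-level noise, so environmental attribution has
realistic structure.

The five presets are scaled to run the full pipeline in minutes
(10 layers × 3 replicates = 30 samples, 200–250 taxa, 5000–10,000 reads)
and each plants one regime:

* **neutral** — full mixing, no selection, moderate (σ = 1) lognormal
  metacommunity: both nulls are approximately calibrated and pairs are
  predominantly undominated.
* **variable_selection** — strong filter (w = 0.35) with the niche axis
  spanning ±1.8 trait SD across layers: cross-environment pairs exceed
  βNTI +2.
* **homogeneous_selection** — the same filter with a constant environment:
  all samples concentrate on the same clade and βNTI falls below −2.
* **dispersal_limitation** — no selection; the community is re-founded
  from the metacommunity (40-individual bottleneck, near-flat σ = 0.2
  metacommunity) at four historical turnover layers. Taxa are clumped into
  layer segments, so cross-segment pairs share fewer taxa than the
  occupancy-weighted RC null expects (RC → +1) while founder identities
  remain phylogenetically random (|βNTI| < 2). Independent per-sample
  bottlenecks would *not* work here: they reproduce the RC null's own
  generative process and score RC ≈ 0.
* **homogenizing_dispersal** — full mixing of a broad-tailed (σ = 2)
  metacommunity sampled at 10,000 reads: the shared core saturates the
  pool (βMNTD cannot be inflated by the phylogeny null, keeping
  |βNTI| < 2) while the borderline-rare tail gives the RC null its
  subset variance, scoring observed pairs as far more similar than null
  (RC → −1). Internally *identical* communities would instead drive
  βNTI ≪ −2 (observed βMNTD ≡ 0) and be read as homogeneous selection —
  an instructive property of the two-step framework.

Ground-truth pair labels follow from the scenario structure (selection
regimes by environmental difference; segment membership for dispersal
limitation; mixing breadth for homogenizing dispersal). What passing the
recovery experiment shows is that the pipeline identifies the dominant
planted regime under these idealized conditions — single niche axis,
noiseless phylogeny, no sequencing error, no compositional artifacts. It
does not show that real chronosequence data meet the metrics' assumptions;
in particular the generator does not emulate taxonomic mis-annotation,
primer bias, DNA persistence/degradation in buried layers, or multivariate
niches.

## Numerical choices and degenerate inputs

Rarefaction is a single seeded multivariate-hypergeometric draw (without
replacement); samples below depth are dropped with a warning. Harmonization
intersects taxa between matrix and tree and samples across tables, and is
idempotent. Trees must carry a branch length on every edge (no silent
zero-length default); trees need not be ultrametric. Zero-variance
variables are dropped before z-scoring with a warning. Permutation
p-values are (exceedances + 1)/(n_perm + 1). All stochastic operations
take explicit seeds; per-pair substreams make null ensembles
order-independent. The pipeline writes versioned output directories
(never overwriting a previous run) and a manifest with the package
version, config hash and seeds.

## Known limitations

* RC_bray's approximate calibration under broad rank-abundance tails
  (above) means the undominated/dispersal split inherits that bias on very
  deep or very shallow sequencing.
* βNTI is undefined for sample pairs that jointly saturate the regional
  pool; such pairs are excluded rather than imputed.
* The correlogram's later distance classes are conservative at small taxon
  counts.
* Biomarker importance is computed on the fitted data (no out-of-bag
  variant) and the CV elimination curve re-ranks on the full data within
  each stage rather than per fold; both choices favor speed and
  determinism over strict nesting, and affect the error curve's absolute
  level more than the ranking.
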