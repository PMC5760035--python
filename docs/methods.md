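# Methods

## Study design being emulated

The pipeline targets a two-platform time-course design: one miRNA and
one mRNA expression matrix measured from the same animals, in three
brain regions (AMY, NAC, PFC) at three times after the last chronic
intermittent ethanol exposure (0, 8, 120 h), with 8 treated and 8
control animals per (region, time) group — 144 samples per platform.
Each region is analyzed independently throughout.

## Differential expression model

For each (region, time) contrast and probe *g*:

- β_g = mean(treated) − mean(control) on the log2 scale;
- s²_g = pooled within-group variance, d_g = n₁ + n₂ − 2;
- v = 1/n₁ + 1/n₂.

The variances are modeled hierarchically: s²_g | σ²_g ~ σ²_g·χ²_d/d and
1/σ²_g ~ χ²_{d₀}/(d₀·s₀²). The hyperparameters are estimated by the
method of moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2):
the excess of var(e) over mean(ψ′(d_g/2)) equals ψ′(d₀/2), inverted by
Newton iteration on the trigamma function (tolerance 1e-8); then
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the moment estimate of
the excess variance is ≤ 0 the prior is degenerate: d₀ = ∞, every probe
shrinks fully to s₀², which is then taken as the arithmetic mean of the
observed variances (the convention of the Bioconductor reference
implementation, against which the whole fit is cross-checked to ~1e-14
in the test suite), and tails are normal instead of Student-t.

The moderated statistic is t̃_g = β_g/√(s̃²_g·v) with
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) on d₀ + d_g degrees of freedom.
d₀ = 0 is accepted as the classical-t limit for validation. Zero-variance
probes (possible after quantile normalization of synthetic data) are
excluded from hyperparameter estimation with a warning but retained and
shrunk; a probe with β = 0 always reports t = 0, p = 1.

Thresholds (all inclusive): miRNAs DE at nominal p ≤ 0.05 at every
time; mRNA targets at BH-FDR ≤ 0.05 for the 0 and 8 h contrasts and
nominal p ≤ 0.05 at 120 h (the late contrast is statistically weakest
and would otherwise be lost entirely). Duplicate probes per annotation
are resolved by minimum p. Signed linear fold change is 2^β when ≥ 1,
else −2^(−β), so −1.35 means control/treated = 1.35.

## Preprocessing

Outlier arrays are scored per region by each sample's median
inter-array Spearman correlation over all probes; a sample is removed
when its score falls below median − max(3·MAD, 0.1), with MAD scaled by
1.4826. The absolute 0.1 guard exists because highly reproducible
arrays make the MAD tiny (~1e-4 here), at which point plain 3·MAD flags
ordinary treatment-group structure; a genuinely corrupted array loses
most of its correlation (≈ 1 → ≈ 0), while treatment effects shift it
by a few thousandths, so the two scales are unambiguous.

Detection filtering keeps probes flagged mature + mouse whose detection
p is strictly < 0.06 on ≥ 80% (inclusive) of the region's remaining
arrays; it runs after outlier removal and is idempotent. Quantile
normalization maps every sample's sorted vector to the across-sample
mean of sorted vectors; ties receive the mean of their tied target
quantiles. Note a consequence visible in the pipeline output: with
planted effects present, quantile normalization slightly redistributes
group shifts across all probes, inflating nominal-α DE counts above
α·G; on null data (the calibration setting) it is benign and the
moderated t's type-I error is within [0.04, 0.06] at α = 0.05.

## Temporal pairing

Interactions are kept when experimentally observed, or predicted with
high confidence: conserved miRNA AND (≥ 1 conserved target site OR
total context score ≤ −0.4, boundary inclusive). miRNAs DE at time X
pair with confidence-passing targets DE at Y ≥ X (regulation cannot
precede its cause); for three time points this gives exactly six named
datasets per region, all emitted even when empty. The temporal overlap
statistic between two target sets is 100·|shared| / |earlier set|,
absent when the earlier set is empty.

## Clustering

Each DE miRNA contributes its (0, 8, 120 h) log-ratio triple, centered
and scaled per miRNA (sample sd, n−1; constant triples map to zeros
with a warning). Scaled triples live on a circle, which is why a
handful of well-separated temporal shapes is the natural planted
structure. Distance is Euclidean; candidate algorithms are hierarchical
average/complete/Ward linkage (scipy) and k-means (deterministic,
n_init = 10, fixed state); k ranges over 2..8, bracketing the 5–6
cluster solutions typical for this kind of data. Internal validation:
connectivity (L = 10 nearest neighbors, penalty 1/j for the j-th
neighbor outside the cluster; lower better), Dunn index (min
inter-cluster distance / max intra-cluster diameter) and mean
silhouette (singleton clusters contribute 0). The winning (algorithm,
k) minimizes the mean rank across the three measures; ties go to
smaller k, then earlier algorithm. Exact distance ties in agglomeration
are resolved by scipy's deterministic merge order; they have measure
zero for continuous profiles.

## Networks

The knowledgebase is an undirected simple graph of molecules (genes,
miRNAs, other) with optional gene-family labels; confidence-passing
miRNA→target edges are injected before construction so miRNAs can
appear in networks. For a dataset's molecules (its "focus" set, after
dropping molecules absent from the graph):

- **Construction** is greedy: seed with the unused focus molecule of
  highest degree-to-focus, then repeatedly add the connected candidate,
  preferring focus molecules first, then most edges into the current
  members, then higher total knowledgebase degree, then lexicographic
  id, until 35 molecules or no connected candidate. Focus molecules
  used by one network are barred from later ones (three networks per
  dataset by default), keeping ranks meaningful. Focus-first ordering
  is deliberate: these networks are built *around* the dataset, with
  knowledgebase molecules acting as linkers; ordering by raw edge count
  lets high-degree background molecules crowd the dataset out.
- **Score** = −log10 P(X ≥ f), X ~ Hypergeometric(N = knowledgebase
  size, K = dataset size in the knowledgebase, n = network size) — the
  right-tailed Fisher exact test of focus enrichment. Networks are
  ranked by score.
- **Grow** adds the top-n (default 10) candidates by edges into the
  network (ties: total degree, lexicographic); candidates without an
  edge are never added.
- **Critical network genes**: the top-3 networks of the
  0h-miRNA/120h-target and 8h-miRNA/120h-target datasets are merged by
  union, any family-labeled member pulling in all same-family dataset
  molecules; critical genes are the 120 h DE genes present in both
  merges.
- **Hubs**: molecules with top-3 within-network (induced-subgraph)
  degree in networks from ≥ 2 distinct datasets. The top-k cutoff (3)
  is configurable; "high connectivity" has no canonical value.
- **Enrichment**: right-tailed Fisher exact test of dataset genes
  against each cell-type list within the knowledgebase gene universe.
  Exact-test p-values on a discrete null are conservative (stochastically
  larger than uniform): the correct null property, asserted in tests,
  is validity P(p ≤ α) ≤ α, not uniformity.
- **Direction z-score**: (n_consistent − n_inconsistent)/√n between
  annotated expected signs and observed DE signs — a simplified
  directional-consistency score, not a full regulator-activation
  z-score, and labeled as such.

## Synthetic-data generator

The generator is the package's test bed and defines the study
conditions; all of its randomness flows from one seed and identical
config + seed gives bit-identical output.

- **Intensities**: probe baselines ~ Normal(7, 1.5) log2 units, i.i.d.
  sample noise ~ Normal(0, noise_sd); detection p is the upper tail of
  each intensity under the array-background distribution Normal(4, 1),
  so ~15% of probes genuinely fail the 0.06/80% detection rule.
- **noise_sd = 0.04** log2 units by construction: the smallest planted
  target effect (|FC| = 1.03–1.11, i.e. β ≈ 0.043–0.15) must be
  detectable at n = 8/8 — at |FC| = 1.05 the noncentrality is
  log2(1.05)/(0.04·0.5) ≈ 3.5, two-sided power ≈ 0.92 at α = 0.05.
  Real arrays are noisier; the generator trades realism of the noise
  floor for crisp recovery oracles at the planted effect sizes.
- **Planted effects**: per region and time, 12 mature mouse miRNA
  probes (baseline ≥ 6 so detection cannot erase them) get signed
  uniform fold changes in ±[1.2, 1.6]; each DE miRNA regulates 4 genes
  (a global miRNA→gene map), whose changes appear with opposite sign
  (a same-sign fraction is configurable) in ±[1.03, 1.11] at lagged
  times — default lag: 0 h miRNAs → targets at {8, 120} h, 8 h → {120},
  120 h → {120} (included so the same-time dataset is exercised).
- **Outliers**: corrupted arrays have their intensities permuted across
  probes — the marginal distribution is preserved but inter-array
  correlation is destroyed, which is the signature QC outlier screens
  respond to. (A constant additive shift, the obvious alternative, is
  invisible to any correlation- or rank-based detector.)
- **Interactions**: every planted regulation appears with
  confidence-passing evidence; decoys (round(fraction·n_true), default
  fraction 0.5) are added, half deliberately failing the filter
  (predicted_low, non-conserved miRNA, or weak context score without a
  conserved site).
- **Knowledgebase**: a preferential-attachment (heavy-tailed) graph
  over all simulated genes and miRNAs plus filler molecules (3000
  total, mean degree 6), with gene families of size 2–3 on ~5% of
  genes. Planted hubs are extra connector molecules wired to ~60% of
  each region's late-time planted target sets (≥ 20 dataset molecules
  in total): a planted "hub" must actually dominate the dysregulated
  sets' connectivity, otherwise the graph's natural high-degree
  molecules out-compete it and the truth label would be meaningless.
- **Cell-type lists**: five GMT sets of ~100 genes; the neuron list is
  seeded with 40% of the planted 120 h targets (the planted
  enrichment), the rest are random non-planted genes.

What the generator does *not* emulate: probe-level effects and
normalization artifacts of real arrays, correlated noise across probes,
realistic miRNA target-set sizes and overlap structure, and a
knowledgebase with curated edge semantics. Passing recovery tests here
therefore demonstrates correctness of the machinery under the stated
model, not field performance on raw array data.

## Problem sizes and numerical choices

Tests and the acceptance script use the default study size (600 miRNA
probes, 2000 mRNA probes, 144 samples per platform, 3000-molecule
knowledgebase) for end-to-end runs, 20 seeds for recovery rates, 50 ×
2000 probes for type-I calibration and G = 5000 for hyperparameter
recovery — sizes chosen so every planted quantity is estimated with
comfortable margin while a full run stays within a few seconds.
Trigamma inversion runs Newton to a 1e-8 relative tolerance. Network
score p-values are floored at 1e-300 before the log. All tie-breaks
(duplicate-probe resolution, greedy candidate choice, hub ranking,
model selection) are deterministic and documented at the function
level.

## Known limitations

- The greedy network construction is a documented reinterpretation of a
  proprietary pathway-tool algorithm; its scores are comparable only
  within this implementation, and published network scores computed in
  a different universe are not reproducible or compared.
- The direction z-score is a consistency statistic only.
- The nominal-α miRNA threshold deliberately admits false positives
  (the analysis trades specificity for downstream network information);
  counts at nominal α on normalized planted data additionally exceed
  α·G because of the quantile-normalization redistribution noted above.
- Three-point profiles constrain cluster geometry to a circle after
  scaling; more time points would require no code change but would
  change which pattern counts are distinguishable.
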