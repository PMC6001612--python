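# Methods

## The question and the data model

Compact genomes keep functionally related genes next to each other more
often than chance, and neighbouring genes influence each other's
transcription. The package quantifies this in three linked steps: *is* a
family's genomic arrangement non-random, *does* adjacency come with tighter
co-expression, and *is* the exact pairing retained across species.

The data model is deliberately small. A `GenomeLayout` is an ordered list
of genes per chromosome; all adjacency is rank adjacency in that order.
Dubious ORFs are excluded before ranking (they are annotation artifacts, not
regulatory insulators), so the genome size *N* is the non-dubious gene
count and an intervening dubious ORF does not break a cluster. Strand is
ignored for adjacency — convergent, divergent and tandem neighbours all
count, since co-regulation of neighbours is observed in every orientation —
but orientation is classified and reported. Overlapping genes are ordered
by (start, end, gene_id) for determinism.

## Clustering significance

For a family of *M* genes among *N*, the probability that a given member
has at least one of its two flanking positions occupied by another member
is, by inclusion–exclusion, P = (M/N)(2 − M/N). Treating members as
independent Bernoulli(P) trials, the chance of *j* or more clustered genes
is a binomial tail. Two conventions are implemented:

* `greater_exclusive` (default): 1 − Σ_{k=0..j} C(M,k) P^k (1−P)^{M−k}
  = Pr(K > j), the literal closed form;
* `greater_inclusive`: Pr(K ≥ j), the standard p-value for the observed
  count.

Both are always reported. Tails are evaluated through the regularized
incomplete beta function (`scipy.stats.binom.sf`), which is stable to the
~10⁻¹³ p-values produced by large, tightly clustered families; the test
suite checks every M ≤ 50 against exact `Fraction` arithmetic at relative
error < 10⁻¹².

**Known limitation (verified by simulation).** The independence assumption
is wrong in a specific, predictable way: in genuine uniform placements a
chance adjacency event creates *two* clustered genes at once, so the true
null of *j* is concentrated on even values and is heavier-tailed than
Binomial(M, P). `placement_null` (M positions drawn uniformly without
replacement, j recomputed exactly) makes this measurable: at N = 1000,
M = 30 the model's inclusive tail is accurate at j ≤ 2 (≈ 9% relative) but
underestimates by roughly two-fold at j = 4 and worse beyond. Conclusions
should therefore rest on the model only for strongly clustered families
(where p-values are many orders of magnitude below any threshold), with
`placement_null` as the exact-null fallback near the significance boundary.
Relatedly, the literal `greater_exclusive` form excludes the observed count
from its own tail and is anti-conservative for small j: a family with a
single chance adjacent pair (j = 2, M = 40, N = 5000) already gets
Pr(K > 2) ≈ 0.026 < 0.05, while the proper Pr(K ≥ 2) ≈ 0.13. Calibration
statements in the tests use the inclusive form for this reason.

## Offset-anchored similarity

S(X, Y) = (1/N) Σ ((Xᵢ − X₀)/φ_X)((Yᵢ − Y₀)/φ_Y) with
φ_G = √(Σ (Gᵢ − G₀)²/N) is a product-moment correlation whose centre is a
fixed biological reference (the unperturbed t = 0 state) rather than the
sample mean: two genes score 1 exactly when their *departures from rest*
are proportional, which is the notion of co-response wanted here. With
offsets set to the sample means it reduces to the textbook Pearson
coefficient (checked to 10⁻¹⁰); |S| ≤ 1 by Cauchy–Schwarz.

Pipeline conventions:

* replicates are averaged first (masked mean over missing cells), then each
  condition is anchored to its reference — log2 ratios by subtraction,
  intensities by log2(v/v_ref); the reference value becomes exactly 0;
* composite scores concatenate condition blocks, each carrying its own zero
  offset, making the composite invariant to block order. A `composite="mean"`
  mode (average of per-condition scores) is available since the choice
  between the two is a genuinely open design point;
* a pair's S is computed over positions observed in both genes; pairs with
  < 3 shared positions, or with φ = 0 (a vector constant at its offset,
  undefined score), are excluded from family means and counted — never
  coerced to 0;
* the cluster score averages *all* within-cluster pairs by default
  (clusters of ≥ 3 genes are a single co-regulated block, and all-pairs is
  the natural block coherence); `cluster_pairing="adjacent"` restricts to
  directly adjacent pairs;
* cluster−singleton differences > 0.05 are flagged "higher" and > 0.1
  "markedly higher" — conventional reporting thresholds for this analysis,
  not inferential statements.

## Bootstrap null of the cluster score

Each of n ≥ 10,000 iterations draws a grouping of the same size as the
paired subset with replacement from the *whole* family, pairs members
consecutively, and records the mean within-pair S — the distribution of
coherence over pairings that could have evolved. 10,000 iterations is
enough for this statistic to stabilise (two independent 10,000-iteration
nulls on a 50-gene family have KS distance ≈ 0.01; a first-half/second-half
KS check is always emitted). Numerical choices:

* a draw pairing a gene with itself would trivially score 1 and inflate the
  null upward; such pairs are redrawn and the event counted;
* the empirical percentile of the observed score uses (r+1)/(n+1), so no
  p-value is ever exactly 0; both one-sided percentiles are reported since
  the direction of the comparison is a reporting choice;
* per-gene selection counts are exported with min/max/CV and a chi-square
  uniformity test (bias flag at p < 0.001 or a never-selected gene), so a
  biased sampler is detectable from the output alone;
* histograms clamp scores below −0.1 into the floor bin, keeping rare deep
  anticorrelations from stretching the axis.

## Pair conservation

A pair conserved in species *s* means: both genes have orthologs in *s*
(from the pillar table; orthology is input, never inferred) and some
ortholog combination is directly adjacent in the gene order of *s*.
Strict adjacency (window = 0) is the default because the question is
conservation of the *exact* pairing; a window parameter admits up to *w*
intervening genes for sensitivity analysis. For post-WGD species carrying
two paralog tracks per pillar cell, any copy combination counts — the
question is whether the pairing survives, not which copy carries it. Only
anchor-genome pairings are scored; novel pairings arising elsewhere are out
of scope.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
defaults shaped like the motivating study: five stress/nutritional
time courses of six points (0–60 min) with duplicate arrays, log2 ratios
anchored at t = 0, a 5,000-gene 16-chromosome genome, and one strongly
clustered regulon of 80 genes with 40 members in 20 adjacent pairs (family
sizes in such screens span roughly 18–343; the default sits mid-range, with
half its members paired so cluster and singleton scores have comparable
precision, as in the heavily clustered ribosomal-protein-style regulons
that motivate the method).

* **Genome.** Members are placed by rejection sampling: runs of 2 (one run
  of 3 for odd planted counts, or an explicit `run_lengths` decomposition)
  on a single chromosome with flanks free of the same family; singletons
  with no same-family neighbour. The realized partition is recorded as
  truth and is recovered *exactly* by the partitioner (tested over random
  configurations).
* **Expression.** Per condition, each family shares a smooth latent
  response curve (a random quadratic anchored at 0 at t = 0, unit RMS);
  each planted run shares an additional block-level curve; singletons get
  private curves of the same amplitude, so every gene has equal variance
  and only *shared* structure differs. Gene values are a·family + b·block +
  Gaussian noise per time point per replicate, with t = 0 forced to 0.
  Amplitudes start from the closed-form variance shares
  a² = ρ_fam·T, a²+b² = ρ_pair·T, T = (σ²/replicates)/(1 − ρ_pair), and a
  pilot simulation (150 draws) applies a damped odds-ratio correction only
  when the measured similarity misses its target by > 0.03 — the anchoring
  and φ-normalisation make the exact expectation closed-form-resistant, and
  the damping (step clamped to [√0.6, √1.6]) keeps pilot sampling noise
  from destabilising the amplitudes. Calibration tolerance is ±0.05.
* **Pillars.** Per species, each planted pair stays adjacent with its
  conservation probability; otherwise one member (never one shared with a
  conserved pair) is deleted with the loss probability or relocated to a
  position that neither rejoins its partner nor splits a conserved pair.
  Background genes are lost independently at the same rate. Truth is
  recomputed from the final realized order, so generator and analyzer agree
  by construction even in rare interference cases.

What the generator does **not** emulate: microarray noise physics (dye
bias, saturation, intensity-dependent variance), missing-value patterns,
correlated noise across genes, gene-length or expression-level effects on
annotation, and tandem-duplication mechanisms that make real adjacent pairs
sequence-similar. Passing tests therefore demonstrate the statistics behave
as designed under their own assumptions — planted structure is recovered at
the stated tolerances — not that real microarray data meet those
assumptions.

## Problem sizes and determinism

Statistical tests run at sizes chosen to make their tolerances meaningful:
10⁵ placements for the null comparison, 10,000 bootstrap iterations, 50
independent bundles (genome size 1,000 for speed; coherence scores do not
depend on genome size) for coherence recovery, 200 pairs for conservation
recovery, 200 replicates for null calibration. All randomness flows from
explicit seeds through `numpy.random.default_rng`; every output table
embeds the seed and a config hash, and a full pipeline run is byte-for-byte
reproducible.
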