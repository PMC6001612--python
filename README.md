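# coregulon

Analysis of **adjacent-gene coregulation**: do members of a functional gene
family (a regulon) that sit directly next to each other in the genome show
tighter transcriptional coordination than the family's scattered members,
and is the exact pairing preserved across related species?

The package is aimed at comparative/functional genomicists working with
yeast-style compact genomes. It takes gene annotations, family membership
lists, stress-response expression time courses, and ortholog "pillar"
tables, and provides:

1. **Cluster partitioning** — each family is split into *functional
   clusters* (maximal runs of ≥ 2 members at consecutive positions in the
   gene order of one chromosome) and *singletons*. Adjacency is positional
   (rank order of non-dubious genes), strand-independent; pair orientation
   (convergent / divergent / tandem) is recorded separately.

2. **Clustering significance.** With a family of *M* genes in an *N*-gene
   genome, the chance that one member has an adjacent family member is
   approximated by

   *P* = (*M*/*N*)(2 − *M*/*N*),

   and the significance of observing *j* clustered genes is the binomial
   tail 1 − Σₖ₌₀ʲ C(*M*, *k*) *P*ᵏ(1 − *P*)^(*M*−*k*). Both the literal
   "greater than *j*" form (default) and the standard "at least *j*" form
   are computed; a uniform-placement simulation oracle
   (`placement_null`) quantifies how well the independence approximation
   holds.

3. **Transcriptional coherence.** Similarity between two expression vectors
   *X*, *Y* over *N* conditions is the offset-anchored Pearson-style score

   S(*X*, *Y*) = (1/*N*) Σᵢ ((*Xᵢ* − *X*₀)/φ_X)((*Yᵢ* − *Y*₀)/φ_Y),
   φ_G = √(Σᵢ (*Gᵢ* − *G*₀)²/*N*),

   anchored at the unperturbed reference state (t = 0, which is 0 after
   normalization) instead of the sample mean. The *cluster score* averages
   within-cluster pairwise S; the *singleton score* averages S over every
   possible singleton pairing. Composite scores concatenate all conditions,
   each anchored to its own reference.

4. **Bootstrap null.** The observed cluster score is located within the
   distribution of mean within-pair S over ≥ 10,000 random same-size
   groupings drawn with replacement from the family, with selection-
   frequency uniformity diagnostics, a half-vs-half convergence check, and
   histogram export (anticorrelations below −0.1 clamped into the −0.1 bin).

5. **Pair conservation.** An adjacent pair is conserved in another species
   when both orthologs (from the pillar table) are directly adjacent in that
   species' gene order; post-WGD paralog tracks count if *any* copy
   combination is adjacent. The result is a pairs × species 0/1 matrix.

A fully tested synthetic-data generator (`coregulon.simulate`) plants known
clusters, known pair/family correlation structure, and known per-species
conservation, so the whole pipeline is exercisable without any downloads.

## Worked example

```python
from coregulon import AdjacentGeneCoregulation
from coregulon.simulate import SimulationConfig, SpeciesSpec, simulate_bundle

cfg = SimulationConfig(
    n_genes=1000, n_chromosomes=8, family_sizes=(30,), planted_clustered=(10,),
    conditions=5, time_points_per_condition=6, replicates=2,
    species=(SpeciesSpec("Spar", 0.9, 0.02), SpeciesSpec("Klac", 0.2, 0.1)),
    seed=7,
)
bundle = simulate_bundle(cfg)
res = AdjacentGeneCoregulation.from_bundle(bundle).fit(n_bootstrap=10_000, seed=7)
print(res.summary())
```

```
Adjacent-gene coregulation analysis
========================================================================
Genome: 1000 genes (8 chromosomes), tail convention: greater_exclusive, composite: concat

family_id  set_size  n_clustered   p_value  singleton_score  cluster_score  difference            flag  boot_percentile_high
    fam01        30           10 5.849e-07           0.4635         0.8579      0.3943 markedly_higher             9.999e-05

Pair conservation (fraction of anchor pairs conserved):
          Scer   1.000  (5/5)
          Spar   1.000  (5/5)
          Klac   0.000  (0/5)
```

Reading the output: the 30-gene family has 10 members in adjacent clusters —
far more than chance in a 1,000-gene genome (binomial p ≈ 6 × 10⁻⁷); the
clustered pairs are markedly more coherent than the singletons across the
five stress time courses (composite S 0.86 vs 0.46, difference > 0.1); the
observed cluster score sits in the extreme upper tail of the bootstrap null
(upper percentile 10⁻⁴); and the planted conservation ladder (90% in the
close species, 20% in the distant one) is recovered in the conservation
matrix.

The same workflow is available from the shell:

```sh
coregulon simulate --out demo --seed 7 --n-genes 1000 --family-size 30 --planted 10
coregulon all --annotation demo/annotation.tsv --families demo/families.tsv \
    --expression demo/expression.tsv --pillars demo/pillars.tsv \
    --orders-dir demo/orders --seed 7 --out demo/results
```

Subcommands `scan`, `correlate`, `bootstrap` and `conserve` run the stages
independently; all tables are TSV with `#` comment headers carrying the tool
version, seed and config hash, so repeated runs are byte-identical and
diff-friendly.

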