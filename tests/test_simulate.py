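"""Generator/analyzer closure: planted structure is recovered by the pipeline."""

import numpy as np
import pytest

from coregulon.coherence import pairwise_similarity_matrix, similarity
from coregulon.conservation import conservation_matrix
from coregulon.expression import concatenate_conditions, prepare
from coregulon.genome import partition_family
from coregulon.simulate import (
    ANCHOR_SPECIES,
    GenerationError,
    SimulationConfig,
    SpeciesSpec,
    planted_pairs,
    simulate_bundle,
    simulate_genome,
    truth_partition,
    write_fixtures,
)


def small_config(**kw):
    base = dict(
        n_genes=300, n_chromosomes=4, family_sizes=(24,), planted_clustered=(8,),
        conditions=2, time_points_per_condition=5, replicates=2,
        species=(SpeciesSpec("SpA", 1.0, 0.0), SpeciesSpec("SpB", 0.0, 0.0)),
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenome:
    def test_planted_null_recovers_zero_clusters(self):
        cfg = small_config(planted_clustered=(0,))
        bundle = simulate_bundle(cfg)
        part = partition_family(bundle.layout, bundle.families[0])
        assert part.j_clustered == 0

    def test_family_covering_whole_chromosome(self):
        cfg = small_config(
            n_genes=40, n_chromosomes=4, family_sizes=(10,), planted_clustered=(10,),
            run_lengths=((10,),),
        )
        rng = np.random.default_rng(cfg.seed)
        layout, families, truth = simulate_genome(cfg, rng)
        part = partition_family(layout, families[0])
        assert len(part.clusters) == 1 and part.j_clustered == 10

    @pytest.mark.parametrize("seed", range(12))
    def test_planted_j_recovered_across_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(6, 30))
        j = int(rng.integers(0, m // 2 + 1))
        if j == 1:
            j = 2
        cfg = small_config(
            n_genes=int(rng.integers(150, 400)),
            n_chromosomes=int(rng.integers(2, 6)),
            family_sizes=(m,), planted_clustered=(j,), seed=seed,
        )
        g = np.random.default_rng(cfg.seed)
        layout, families, truth = simulate_genome(cfg, g)
        part = partition_family(layout, families[0])
        rec = truth["families"][families[0].family_id]
        assert part.j_clustered == j == rec["j"]
        tp = truth_partition(truth, families[0].family_id)
        assert sorted(map(tuple, part.clusters)) == sorted(map(tuple, tp.clusters))
        assert sorted(part.singletons) == sorted(tp.singletons)

    def test_odd_planted_count_uses_a_run_of_three(self):
        cfg = small_config(planted_clustered=(7,))
        rng = np.random.default_rng(cfg.seed)
        layout, families, truth = simulate_genome(cfg, rng)
        part = partition_family(layout, families[0])
        assert part.j_clustered == 7
        assert sorted(len(c) for c in part.clusters) == [2, 2, 3]

    def test_infeasible_packing_raises(self):
        with pytest.raises((GenerationError, ValueError)):
            cfg = small_config(n_genes=12, n_chromosomes=6,
                               family_sizes=(12,), planted_clustered=(0,))
            simulate_genome(cfg, np.random.default_rng(0))


class TestExpression:
    def test_near_perfect_pair_correlation_limit(self):
        # as pair_correlation -> 1 the within-pair score approaches 1
        cfg = small_config(noise_sd=1e-6, pair_correlation=0.99, family_correlation=0.2)
        bundle = simulate_bundle(cfg)
        prepared = prepare(bundle.expression)
        for a, b in planted_pairs(bundle.truth):
            s = similarity(
                concatenate_conditions(prepared, a)[0],
                concatenate_conditions(prepared, b)[0],
            )
            assert s > 0.95

    def test_calibration_hits_planted_targets(self):
        cfg = SimulationConfig(n_genes=1200, n_chromosomes=8, seed=4)
        bundle = simulate_bundle(cfg)
        prepared = prepare(bundle.expression)
        part = truth_partition(bundle.truth, "fam01")
        pair_s = []
        for a, b in planted_pairs(bundle.truth):
            pair_s.append(similarity(
                concatenate_conditions(prepared, a)[0],
                concatenate_conditions(prepared, b)[0],
            ))
        singles = sorted(part.singletons)
        S = pairwise_similarity_matrix(prepared, singles)
        iu = np.triu_indices(len(singles), k=1)
        # calibration tolerance 0.05 plus sampling noise of the finite family
        assert np.mean(pair_s) == pytest.approx(cfg.pair_correlation, abs=0.08)
        assert np.mean(S[iu]) == pytest.approx(cfg.family_correlation, abs=0.08)

    def test_reference_time_point_is_exactly_zero(self):
        bundle = simulate_bundle(small_config())
        for s in bundle.expression.series:
            for v in s.values.values():
                np.testing.assert_array_equal(v[:, 0], 0.0)

    def test_exchangeable_limit_scores_comparable(self):
        # equal planted correlations: clusters are no more coherent than singletons
        from coregulon.coherence import family_scores

        diffs = []
        for seed in range(8):
            cfg = small_config(
                family_sizes=(30,), planted_clustered=(12,),
                pair_correlation=0.6, family_correlation=0.6, seed=seed,
            )
            bundle = simulate_bundle(cfg)
            prepared = prepare(bundle.expression)
            part = partition_family(bundle.layout, bundle.families[0])
            res = family_scores(part, prepared)
            diffs.append(res.difference)
        assert abs(np.mean(diffs)) < 0.1


class TestPillars:
    def test_full_conservation_and_full_shuffle_recovered(self):
        bundle = simulate_bundle(small_config())
        pairs = planted_pairs(bundle.truth)
        matrix = conservation_matrix(
            pairs, bundle.pillars.species_ids, bundle.pillars,
            bundle.species_orders, ANCHOR_SPECIES,
        )
        assert matrix.species_fraction(ANCHOR_SPECIES) == 1.0
        assert matrix.species_fraction("SpA") == 1.0  # conservation prob 1, loss 0
        assert matrix.species_fraction("SpB") == 0.0  # conservation prob 0, loss 0

    def test_truth_matches_pipeline_matrix(self):
        cfg = small_config(species=(SpeciesSpec("SpC", 0.5, 0.1),), seed=3)
        bundle = simulate_bundle(cfg)
        pairs = planted_pairs(bundle.truth)
        matrix = conservation_matrix(
            pairs, ["SpC"], bundle.pillars, bundle.species_orders, ANCHOR_SPECIES
        )
        for (a, b), row in zip(matrix.pairs, matrix.conserved):
            assert row[0] == bundle.truth["conservation"]["SpC"][f"{a}--{b}"]


class TestFixtures:
    def test_write_then_read_reproduces_bundle(self, tmp_path):
        from coregulon.conservation import load_pillars
        from coregulon.expression import load_expression
        from coregulon.genome import load_annotation, load_families

        bundle = simulate_bundle(small_config())
        paths = write_fixtures(bundle, tmp_path / "fix")
        layout = load_annotation(paths["annotation_tsv"])
        assert layout.chromosomes == bundle.layout.chromosomes
        gff = load_annotation(paths["annotation_gff3"], format="gff3")
        assert gff.chromosomes == bundle.layout.chromosomes
        fams = load_families(paths["families"])
        assert {f.family_id: f.members for f in fams} == {
            f.family_id: f.members for f in bundle.families
        }
        expr = load_expression(paths["expression"])
        for s1, s2 in zip(bundle.expression.series, expr.series):
            for g in s1.values:
                np.testing.assert_allclose(s1.values[g], s2.values[g], rtol=1e-8)
        pillars = load_pillars(paths["pillars"])
        assert pillars.species_ids == bundle.pillars.species_ids
        assert pillars.pillars == bundle.pillars.pillars

    def test_same_config_byte_identical_different_seed_differs(self, tmp_path):
        cfg = small_config()
        p1 = write_fixtures(simulate_bundle(cfg), tmp_path / "a")
        p2 = write_fixtures(simulate_bundle(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
        cfg2 = small_config(seed=99)
        p3 = write_fixtures(simulate_bundle(cfg2), tmp_path / "c")
        assert p1["expression"].read_bytes() != p3["expression"].read_bytes()
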