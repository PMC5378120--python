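"""Properties of the synthetic SSD-population generator."""

import math

import numpy as np
import pytest

from namkit import genetics
from namkit.io import CODE_NA
from namkit.simulate import (SDL, ChromosomeSpec, GenomeSpec, Inversion,
                             SelectionSpec, SimulationConfig,
                             StructuralVariantSpec, Translocation,
                             apply_observation_noise, simulate_meiosis,
                             simulate_ssd_population, uniform_genome,
                             wheat_like_genome)


def het_diplotype(genome):
    return {c.name: (np.zeros(len(c.marker_names), np.uint8),
                     np.ones(len(c.marker_names), np.uint8))
            for c in genome.chromosomes}


class TestMeiosis:
    def test_zero_length_chromosome_never_recombines(self):
        g = GenomeSpec((ChromosomeSpec("c", 0.0, (0.0,), ("m",)),))
        rng = np.random.default_rng(0)
        gametes = {simulate_meiosis(het_diplotype(g), g, rng)[0]["c"][0]
                   for _ in range(200)}
        assert gametes <= {0, 1}
        counts = [simulate_meiosis(het_diplotype(g), g, rng)[1] for _ in range(200)]
        assert set(counts) == {0}

    def test_poisson_mean_one_per_morgan(self):
        g = GenomeSpec((ChromosomeSpec("c", 100.0, (50.0,), ("m",)),))
        rng = np.random.default_rng(1)
        n = 100_000
        counts = np.array([simulate_meiosis(het_diplotype(g), g, rng)[1]
                           for _ in range(n)])
        assert counts.mean() == pytest.approx(1.00, abs=0.01)

    def test_adjacent_markers_follow_haldane(self):
        # 1 cM apart -> r = (1 - exp(-0.02))/2 = 0.00995
        g = GenomeSpec((ChromosomeSpec("c", 100.0, (50.0, 51.0), ("a", "b")),))
        rng = np.random.default_rng(2)
        n = 100_000
        rec = 0
        dip = het_diplotype(g)
        for _ in range(n):
            gam, _ = simulate_meiosis(dip, g, rng)
            rec += gam["c"][0] != gam["c"][1]
        expected = genetics.haldane_inverse(1.0)
        assert rec / n == pytest.approx(expected, abs=3 * math.sqrt(expected / n))


class TestSSDPopulation:
    def test_f4_genotype_frequencies(self):
        cfg = SimulationConfig(genome=uniform_genome(2, 5, 80.0),
                               n_individuals=10_000, generation=4, seed=3)
        m, _ = simulate_ssd_population(cfg)
        freqs = [(m.calls == g).mean() for g in (0, 1, 2)]
        assert freqs[0] == pytest.approx(0.4375, abs=0.01)
        assert freqs[1] == pytest.approx(0.125, abs=0.01)
        assert freqs[2] == pytest.approx(0.4375, abs=0.01)

    def test_f2_genotype_frequencies(self):
        cfg = SimulationConfig(genome=uniform_genome(1, 5, 80.0),
                               n_individuals=8_000, generation=2, seed=4)
        m, _ = simulate_ssd_population(cfg)
        assert (m.calls == 1).mean() == pytest.approx(0.5, abs=0.015)

    def test_fully_inbred_has_no_heterozygotes(self):
        cfg = SimulationConfig(genome=uniform_genome(2, 6, 100.0),
                               n_individuals=200, generation=math.inf, seed=5)
        m, _ = simulate_ssd_population(cfg)
        assert np.sum(m.calls == 1) == 0

    def test_lethal_class_eliminated(self):
        cfg = SimulationConfig(
            genome=uniform_genome(1, 5, 60.0), n_individuals=400,
            generation=4, seed=6,
            selection=SelectionSpec(sdl=(SDL("C1", 0.0, (1, 1, 0)),)))
        m, truth = simulate_ssd_population(cfg)
        sdl_row = truth.marker_names.index("MC1_000")
        assert np.sum(m.calls[sdl_row] == 2) == 0

    def test_observed_rf_matches_selfing_recursion(self):
        # simulator (Haldane meiosis + SSD) vs the independent two-locus
        # recursion: observed recombinant fraction at F4 between markers 20
        # cM apart
        g = GenomeSpec((ChromosomeSpec("c", 40.0, (10.0, 30.0), ("a", "b")),))
        cfg = SimulationConfig(genome=g, n_individuals=20_000, generation=4,
                               seed=7)
        m, _ = simulate_ssd_population(cfg)
        r = genetics.haldane_inverse(20.0)
        expected = genetics.joint_selfing(r, 4)
        counts = np.zeros((3, 3))
        np.add.at(counts, (m.calls[0], m.calls[1]), 1)
        freq = counts / counts.sum()
        assert np.allclose(freq, expected, atol=0.01)

    def test_seeded_runs_are_bit_reproducible(self):
        cfg = SimulationConfig(genome=uniform_genome(2, 6, 90.0),
                               n_individuals=50, generation=4, seed=11,
                               missing_rate=0.05, error_rate=0.01)
        m1, t1 = simulate_ssd_population(cfg)
        m2, t2 = simulate_ssd_population(cfg)
        assert np.array_equal(m1.calls, m2.calls)
        assert np.array_equal(t1.xo_counts, t2.xo_counts)

    def test_truth_record_round_trips_json(self, tmp_path):
        cfg = SimulationConfig(genome=uniform_genome(1, 4, 50.0),
                               n_individuals=10, generation=4, seed=12)
        _, truth = simulate_ssd_population(cfg)
        p = tmp_path / "t.json"
        truth.to_json(p)
        back = type(truth).from_json(p)
        assert np.array_equal(back.true_genotypes, truth.true_genotypes)
        assert back.true_map == truth.true_map


class TestStructuralVariants:
    def test_reciprocal_translocation_swaps_marker_locations(self):
        sv = StructuralVariantSpec(translocations=(
            Translocation("C1", (0.0, 30.0), "C2", 0.0, reciprocal=True),))
        cfg = SimulationConfig(genome=uniform_genome(2, 6, 100.0),
                               n_individuals=10, generation=4, seed=13,
                               variants=sv)
        _, truth = simulate_ssd_population(cfg)
        # first two markers of each chromosome (at 0 and 20 cM) swapped
        assert truth.true_map["C1"]["markers"][:2] == ["MC2_000", "MC2_001"]
        assert truth.true_map["C2"]["markers"][:2] == ["MC1_000", "MC1_001"]
        # a-priori assignments keep the original chromosome
        assert truth.assigned_chromosome["MC1_000"] == "C1"

    def test_inversion_reverses_local_order(self):
        sv = StructuralVariantSpec(inversions=(Inversion("C1", (20.0, 80.0)),))
        cfg = SimulationConfig(genome=uniform_genome(1, 6, 100.0),
                               n_individuals=10, generation=4, seed=14,
                               variants=sv)
        _, truth = simulate_ssd_population(cfg)
        # markers at 20,40,60,80 reversed in place
        assert truth.true_map["C1"]["markers"] == [
            "MC1_000", "MC1_004", "MC1_003", "MC1_002", "MC1_001", "MC1_005"]

    def test_overlapping_variants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StructuralVariantSpec(inversions=(
                Inversion("C1", (10.0, 50.0)), Inversion("C1", (40.0, 60.0))))


class TestObservationNoise:
    def test_zero_rates_identity(self, tiny_matrix):
        rng = np.random.default_rng(0)
        out = apply_observation_noise(tiny_matrix, 0.0, 0.0, rng)
        assert np.array_equal(out.calls, tiny_matrix.calls)

    def test_full_missing(self, tiny_matrix):
        rng = np.random.default_rng(0)
        out = apply_observation_noise(tiny_matrix, 1.0, 0.0, rng)
        assert np.all(out.calls == CODE_NA)

    def test_error_count_is_binomial(self):
        from namkit.io import GenotypeMatrix, MarkerInfo
        n_calls = 100_000
        calls = np.zeros((1000, 100), dtype=np.int8)
        m = GenotypeMatrix("p", [MarkerInfo(f"m{i}") for i in range(1000)],
                           [f"i{j}" for j in range(100)], calls, generation=4)
        rng = np.random.default_rng(21)
        out = apply_observation_noise(m, 0.0, 0.01, rng)
        flipped = int(np.sum(out.calls != 0))
        assert flipped == pytest.approx(1000, abs=120)  # ~4 sigma

    def test_original_matrix_untouched(self, tiny_matrix):
        rng = np.random.default_rng(1)
        before = tiny_matrix.calls.copy()
        apply_observation_noise(tiny_matrix, 0.5, 0.5, rng)
        assert np.array_equal(tiny_matrix.calls, before)


def test_wheat_like_genome_shape():
    g = wheat_like_genome(seed=0)
    names = [c.name for c in g.chromosomes]
    assert len(names) == 21
    assert names[:3] == ["1A", "1B", "1D"]
    for c in g.chromosomes:
        n = len(c.marker_names)
        if c.name.endswith("D"):
            assert 2 <= n <= 8
        else:
            assert 8 <= n <= 31
        assert np.all(np.diff(c.positions) > 0)
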