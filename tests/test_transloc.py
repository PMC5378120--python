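"""Mapped and estRF translocation callers, merging, enrichment."""

import numpy as np
import pytest
from scipy import stats

from namkit.linkage import EstRFMatrix, GeneticMap, LinkageGroup, build_map
from namkit.simulate import (SimulationConfig, StructuralVariantSpec,
                             Translocation, simulate_ssd_population,
                             uniform_genome)
from namkit.transloc import (ancestral_enrichment, classify_and_merge,
                             estrf_translocations, mapped_translocations)


def gmap_with_lgs(*lgs):
    return GeneticMap("pop", list(lgs))


class TestMappedCalls:
    def test_minority_markers_generate_call(self):
        markers = [f"a{i}" for i in range(10)] + ["x1", "x2"]
        lg = LinkageGroup("LG1", markers, np.arange(12) * 5.0, "5B")
        assignments = {m: "5B" for m in markers[:10]} | {"x1": "7B", "x2": "7B"}
        calls = mapped_translocations(gmap_with_lgs(lg), assignments)
        assert len(calls) == 1
        assert calls[0].type_label == "T5B:7B"
        assert calls[0].statistic == 2
        assert not calls[0].reciprocal

    def test_pure_lg_no_call(self):
        lg = LinkageGroup("LG1", ["a", "b", "c"], [0, 5, 10], "1A")
        assert mapped_translocations(gmap_with_lgs(lg),
                                     {m: "1A" for m in "abc"}) == []

    def test_mirror_conflicts_are_reciprocal(self):
        lg1 = LinkageGroup("LG1", ["a1", "a2", "b1"], [0, 5, 10], "1A")
        lg2 = LinkageGroup("LG2", ["b2", "b3", "a3"], [0, 5, 10], "2B")
        assignments = {"a1": "1A", "a2": "1A", "a3": "1A",
                       "b1": "2B", "b2": "2B", "b3": "2B"}
        calls = mapped_translocations(gmap_with_lgs(lg1, lg2), assignments)
        assert len(calls) == 1  # same chromosome pair, merged
        assert calls[0].reciprocal

    def test_min_minority_threshold(self):
        markers = [f"a{i}" for i in range(5)] + ["x"]
        lg = LinkageGroup("LG1", markers, np.arange(6) * 4.0, "1A")
        assignments = {m: "1A" for m in markers[:5]} | {"x": "3D"}
        assert len(mapped_translocations(gmap_with_lgs(lg), assignments)) == 1
        assert mapped_translocations(gmap_with_lgs(lg), assignments,
                                     min_minority=2) == []


class TestEstRFCalls:
    def make_est(self, lod_value):
        markers = ["a1", "a2", "b1", "b2"]
        lod = np.zeros((4, 4))
        lod[0, 2] = lod[2, 0] = lod_value  # a1 (1A) vs b1 (2B)
        rf = np.full((4, 4), 0.5)
        np.fill_diagonal(rf, 0)
        return EstRFMatrix(markers, rf, lod, np.ones(4, bool)), \
            {"a1": "1A", "a2": "1A", "b1": "2B", "b2": "2B"}

    def test_exceedance_generates_single_call(self):
        est, chrom = self.make_est(9.0)
        calls = estrf_translocations(est, chrom, 7.0, population="p")
        assert len(calls) == 1
        assert calls[0].chromosomes == ("1A", "2B")
        assert calls[0].statistic == 9.0

    def test_threshold_is_strict(self):
        est, chrom = self.make_est(7.0)
        assert estrf_translocations(est, chrom, 7.0) == []

    def test_threshold_monotonicity(self):
        est, chrom = self.make_est(9.0)
        low = estrf_translocations(est, chrom, 5.0)
        high = estrf_translocations(est, chrom, 9.5)
        assert len(low) >= len(high)

    def test_screen_lod_two_stage(self):
        est, chrom = self.make_est(9.0)
        assert estrf_translocations(est, chrom, 7.0, screen_lod=10.0) == []

    def test_uninformative_markers_ignored(self):
        est, chrom = self.make_est(9.0)
        est.informative[:] = False
        assert estrf_translocations(est, chrom, 7.0) == []

    def test_simulated_reciprocal_translocation_detected(self):
        sv = StructuralVariantSpec(translocations=(
            Translocation("C1", (20.0, 50.0), "C2", 40.0, reciprocal=True),))
        cfg = SimulationConfig(genome=uniform_genome(3, 10, 100.0),
                               n_individuals=94, generation=4, seed=61,
                               variants=sv)
        m, _ = simulate_ssd_population(cfg)
        _gmap, est, _ = build_map(m)
        assignments = {mk.name: mk.assigned_chromosome for mk in m.markers}
        calls = estrf_translocations(est, assignments, 7.0, population="p")
        assert any(c.chromosomes == ("C1", "C2") for c in calls)
        assert max(c.statistic for c in calls) > 7.0


class TestMergeAndTypes:
    def make_calls(self):
        from namkit.transloc import TranslocationCall
        return [
            TranslocationCall("p1", "mapped", ("5B", "7B"), ["x"], 1.0),
            TranslocationCall("p1", "estrf", ("5B", "7B"), ["x", "y"], 12.0),
            TranslocationCall("p2", "estrf", ("5B", "7B"), ["z"], 8.0),
            TranslocationCall("p3", "mapped", ("3B", "7B"), ["w"], 1.0),
        ]

    def test_same_pair_both_methods_counted_once(self):
        merged, types, counts = classify_and_merge(self.make_calls())
        assert len(merged) == 3
        row = merged[(merged.population == "p1") & (merged.type == "T5B:7B")]
        assert row.method.item() == "both"
        assert counts["p1"] == 1

    def test_type_carrier_counts(self):
        _, types, _ = classify_and_merge(self.make_calls())
        assert types.set_index("type").loc["T5B:7B", "carrier_count"] == 2
        assert types.set_index("type").loc["T3B:7B", "carrier_count"] == 1

    def test_empty(self):
        merged, types, counts = classify_and_merge([])
        assert len(merged) == 0 and len(types) == 0 and len(counts) == 0


class TestEnrichment:
    def panel_groups(self):
        # 55 accessions, 9 ancestral groups of sizes 11,10,8,7,6,5,4,2,2
        sizes = [11, 10, 8, 7, 6, 5, 4, 2, 2]
        groups = {}
        i = 0
        for g, s in enumerate(sizes):
            for _ in range(s):
                groups[f"acc{i:02d}"] = f"G{g + 1}"
                i += 1
        return groups

    def test_uniform_carriers_not_significant(self):
        groups = self.panel_groups()
        by_group = {}
        for acc, g in groups.items():
            by_group.setdefault(g, []).append(acc)
        carriers = [v[0] for v in by_group.values()]  # one per group
        res = ancestral_enrichment(carriers, groups, seed=1)
        p = res["p_monte_carlo"] if res["p_monte_carlo"] is not None else \
            res["p_asymptotic"]
        assert p > 0.05

    def test_concentrated_carriers_significant(self):
        groups = self.panel_groups()
        carriers = [a for a, g in groups.items() if g == "G1"][:6]
        res = ancestral_enrichment(carriers, groups, seed=2)
        p = res["p_monte_carlo"] if res["p_monte_carlo"] is not None else \
            res["p_asymptotic"]
        # oracle on the 2x2 collapse (G1 vs rest): hypergeometric tail
        p_exact = stats.hypergeom.sf(5, 55, 11, 6)
        assert p_exact < 0.001
        assert p <= 0.05
        assert res["per_group"]["G1"]["observed"] == 6

    def test_needs_two_carriers(self):
        with pytest.raises(ValueError):
            ancestral_enrichment(["acc00"], self.panel_groups())
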