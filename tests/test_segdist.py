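"""HMM imputation, distortion scanning, BH adjustment, allele-ratio QC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from namkit import genetics
from namkit.io import GenotypeMatrix, MarkerInfo, CODE_NA
from namkit.linkage import GeneticMap, LinkageGroup
from namkit.segdist import (impute_genotypes, qc_allele_ratio, sdl_hotspots,
                            segdist_scan)
from namkit.simulate import (SDL, SelectionSpec, SimulationConfig,
                             simulate_ssd_population, uniform_genome)
from statsmodels.stats.multitest import multipletests

from conftest import truth_map


def matrix_and_map(calls, positions, k=4):
    n_markers, n_ind = calls.shape
    markers = [MarkerInfo(f"m{i}", "1A") for i in range(n_markers)]
    m = GenotypeMatrix("p", markers, [f"i{j}" for j in range(n_ind)],
                       calls, generation=k)
    gmap = GeneticMap("p", [LinkageGroup("LG1", [f"m{i}" for i in range(n_markers)],
                                         np.asarray(positions, float), "1A")])
    return m, gmap


class TestImputation:
    def test_identity_on_clean_data(self, small_population):
        m, truth = small_population
        imp = impute_genotypes(m, truth_map(truth))
        idx = {mk: i for i, mk in enumerate(m.marker_names)}
        rows = [idx[mk] for mk in imp.markers]
        assert np.array_equal(imp.calls, m.calls[rows])

    def test_flanked_miscall_handling(self):
        # one middle call flipped AA->BB between tight (1 cM) flanks.  At a
        # realistic scoring error rate the flip is corrected; at the very
        # conservative 1e-4 default the F4 genotype chain assigns the flip
        # appreciable probability of being a real double junction, so the
        # call is neither confirmed nor corrected but left missing.
        calls = np.zeros((3, 20), dtype=np.int8)
        calls[1, 0] = 2
        m, gmap = matrix_and_map(calls, [0.0, 1.0, 2.0])
        imp = impute_genotypes(m, gmap, error_prob=0.01, min_posterior=None)
        assert imp.calls[1, 0] == 0
        imp_strict = impute_genotypes(m, gmap, error_prob=1e-4,
                                      min_posterior=0.95)
        assert imp_strict.calls[1, 0] == CODE_NA
        # posterior agrees with direct marginalisation of the 3-marker chain
        r = genetics.kosambi_inverse(1.0)
        joint = genetics.joint_selfing(r, 4)
        t = joint / joint.sum(axis=1, keepdims=True)
        prior = genetics.marginal_selfing(4)
        e_aa = np.array([1 - 1e-4, 5e-5, 5e-5])
        e_bb = e_aa[::-1]
        w = np.array([
            sum(prior[a] * e_aa[a] * t[a, b] * e_bb[b] * t[b, c] * e_aa[c]
                for a in range(3) for c in range(3))
            for b in range(3)
        ])
        assert np.allclose(imp_strict.posteriors[1, 0], w / w.sum(), atol=1e-9)

    def test_isolated_marker_posterior_is_prior_weighted_emission(self):
        calls = np.full((1, 10), CODE_NA, dtype=np.int8)
        calls[0, 0] = 1
        m, gmap = matrix_and_map(calls, [0.0])
        imp = impute_genotypes(m, gmap, error_prob=1e-4, min_posterior=None)
        prior = genetics.marginal_selfing(4)
        emis = np.array([5e-5, 1 - 1e-4, 5e-5])
        expected = prior * emis / np.sum(prior * emis)
        assert np.allclose(imp.posteriors[0, 0], expected, atol=1e-12)
        # missing observation -> posterior equals the prior
        assert np.allclose(imp.posteriors[0, 1], prior, atol=1e-12)

    def test_low_confidence_calls_left_missing(self):
        calls = np.full((1, 5), CODE_NA, dtype=np.int8)
        m, gmap = matrix_and_map(calls, [0.0])
        imp = impute_genotypes(m, gmap, min_posterior=0.95)
        assert np.all(imp.calls == CODE_NA)


class TestSegdistScan:
    def scan_counts(self, n_aa, n_ab, n_bb, k=4):
        calls = np.array([[0] * n_aa + [1] * n_ab + [2] * n_bb], dtype=np.int8)
        m, gmap = matrix_and_map(calls, [0.0], k=k)
        imp = impute_genotypes(m, gmap, min_posterior=None)
        return segdist_scan(imp, exclude_no_het=False)

    def test_expected_ratio_not_significant(self):
        df = self.scan_counts(41, 12, 41)
        assert df["chi2"].item() < 0.2
        assert not df["significant"].item()

    def test_chi2_matches_direct_formula(self):
        df = self.scan_counts(60, 10, 24)
        exp = np.array([0.4375, 0.125, 0.4375]) * 94
        chi2 = np.sum((np.array([60, 10, 24]) - exp) ** 2 / exp)
        assert df["chi2"].item() == pytest.approx(chi2)
        assert df["p_raw"].item() == pytest.approx(stats.chi2.sf(chi2, 2))
        assert df["direction"].item() == "Par_excess"

    def test_no_het_markers_excluded(self):
        calls = np.array([[0] * 50 + [2] * 44,
                          [0] * 41 + [1] * 12 + [2] * 41], dtype=np.int8)
        m, gmap = matrix_and_map(calls, [0.0, 50.0])
        imp = impute_genotypes(m, gmap, min_posterior=None)
        df = segdist_scan(imp)
        assert list(df["marker"]) == ["m1"]

    def test_inbred_uses_one_to_one(self):
        df = self.scan_counts(30, 0, 60, k=math.inf)
        chi2 = (30 - 45) ** 2 / 45 + (60 - 45) ** 2 / 45
        assert df["chi2"].item() == pytest.approx(chi2)

    def test_bh_adjustment_matches_step_up_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=57)

        def brute_force_bh(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            adj = np.empty(m)
            prev = 1.0
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                val = min(prev, pvals[i] * m / rank_from_top)
                adj[i] = val
                prev = val
            return adj

        expected = brute_force_bh(p)
        got = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(got, expected, atol=1e-12)
        # the worked 4-value example
        p4 = np.array([0.001, 0.01, 0.02, 0.05])
        assert np.allclose(multipletests(p4, method="fdr_bh")[1],
                           [0.004, 0.02, 0.0267, 0.05], atol=1e-4)


class TestQC:
    def test_neutral_panel_not_flagged(self):
        cfg = SimulationConfig(genome=uniform_genome(3, 8, 100.0),
                               n_individuals=400, generation=4, seed=50)
        m, _ = simulate_ssd_population(cfg)
        qc = qc_allele_ratio(m)
        assert qc["mean_par_homozygote"] == pytest.approx(0.4375, abs=0.03)
        assert not qc["flagged"]

    def test_selection_toward_par_flagged(self):
        sdl = tuple(SDL(f"C{c}", p, (1.5, 1.0, 1.0))
                    for c in (1, 2, 3) for p in (20.0, 80.0))
        cfg = SimulationConfig(genome=uniform_genome(3, 8, 100.0),
                               n_individuals=300, generation=4, seed=51,
                               selection=SelectionSpec(sdl=sdl))
        m, _ = simulate_ssd_population(cfg)
        qc = qc_allele_ratio(m)
        assert qc["mean_par_homozygote"] > 0.4375
        assert qc["flagged"]

    def test_inbred_expectation_is_half(self):
        calls = np.array([[0] * 50 + [2] * 50], dtype=np.int8)
        markers = [MarkerInfo("m0", "1A")]
        m = GenotypeMatrix("p", markers, [f"i{j}" for j in range(100)], calls,
                           generation=math.inf)
        qc = qc_allele_ratio(m)
        assert qc["chi2"] == pytest.approx(0.0)
        assert not qc["flagged"]


class TestHotspots:
    def make_consensus(self):
        from namkit.consensus import ConsensusMap
        return {"1A": ConsensusMap("1A", [f"m{i}" for i in range(5)],
                                   np.arange(5) * 10.0, 1, ["g"], np.zeros(1))}

    def sdl_table(self, sig_markers):
        rows = [dict(marker=f"m{i}", significant=(f"m{i}" in sig_markers),
                     direction="Par_excess") for i in range(5)]
        return pd.DataFrame(rows)

    def test_recurrent_marker_is_hotspot(self):
        tables = {f"p{j}": self.sdl_table({"m2"}) for j in range(7)}
        marker_df, bin_df = sdl_hotspots(tables, self.make_consensus())
        row = marker_df[marker_df.marker == "m2"].iloc[0]
        assert row.n_populations == 7 and row.hotspot

    def test_no_significant_sdl_empty(self):
        tables = {"p1": self.sdl_table(set())}
        marker_df, bin_df = sdl_hotspots(tables, self.make_consensus())
        assert len(marker_df) == 0 and len(bin_df) == 0

    def test_simulated_hotspot_recovered(self):
        tables = {}
        for j in range(10):
            sig = {"m1"} if j < 5 else set()
            tables[f"p{j}"] = self.sdl_table(sig)
        marker_df, _ = sdl_hotspots(tables, self.make_consensus(), min_pops=3)
        assert marker_df[marker_df.marker == "m1"].hotspot.item()
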