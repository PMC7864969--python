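"""Hierarchical F-statistics, heterozygosity, LD medians and matched nulls."""

import numpy as np
import pytest

import hzadapt as hz
from hzadapt import MISSING, PopulationMap
from hzadapt.diffstats import (
    hierarchical_fstats,
    matched_bootstrap_null,
    median_ld,
    r2_matrix,
)

from conftest import geno, two_pop_map


def hier_map(n_per_pop=4):
    """Two groups x two populations each."""
    inds, pops, groups = [], {}, {}
    coords = {}
    for g, pref in (("P1", "x"), ("P2", "y")):
        for p in range(2):
            pop = f"{pref}{p}"
            groups[pop] = g
            coords[pop] = (35.0 + p, -108.0, 2400.0)
            for i in range(n_per_pop):
                ind = f"{pop}_i{i}"
                inds.append(ind)
                pops[ind] = pop
    return inds, PopulationMap(pops, groups, coords)


class TestFstats:
    def test_identical_populations_near_zero(self, rng):
        # duplicated genotype blocks: F_ST should vanish up to the
        # moment-estimator sampling term, which shrinks with sample size
        inds, pmap = two_pop_map(60)
        block = rng.binomial(2, 0.4, size=(60, 60))
        G = geno(np.vstack([block, block]), inds=inds)
        d = hierarchical_fstats(G, pmap)
        assert abs(d.fst) < 0.02

    def test_fixed_difference_gives_one(self):
        inds, pmap = two_pop_map(5)
        vals = np.vstack([np.zeros((5, 10)), np.full((5, 10), 2)])
        d = hierarchical_fstats(geno(vals, inds=inds), pmap)
        assert d.fst == pytest.approx(1.0)

    def test_multilocus_equals_single_locus_when_one_locus(self, rng):
        inds, pmap = two_pop_map(6)
        vals = rng.choice([0, 1, 2], size=(12, 1))
        d = hierarchical_fstats(geno(vals, inds=inds), pmap)
        assert d.fst == pytest.approx(d.fst_per_locus[0])

    def test_group_with_one_population_rejected(self, rng):
        inds, pops, groups, coords = [], {}, {}, {}
        for pop, grp in (("a", "P1"), ("b", "P1"), ("c", "P2")):
            groups[pop] = grp
            coords[pop] = (35.0, -108.0, 2000.0)
            for i in range(3):
                ind = f"{pop}{i}"
                inds.append(ind); pops[ind] = pop
        pmap = PopulationMap(pops, groups, coords)
        G = geno(rng.choice([0, 1, 2], size=(9, 5)), inds=inds)
        with pytest.raises(ValueError):
            hierarchical_fstats(G, pmap, groups=("P1", "P2"))

    def test_island_model_recovery(self, rng):
        # populations drawn from a Balding-Nichols island model with known F
        F_true, n_pops, n_ind, L = 0.1, 8, 30, 400
        pi = rng.uniform(0.2, 0.8, L)
        sc = (1 - F_true) / F_true
        inds, pops, groups, coords = [], {}, {}, {}
        blocks = []
        for p in range(n_pops):
            f = rng.beta(pi * sc, (1 - pi) * sc)
            blocks.append(rng.binomial(2, f, size=(n_ind, L)))
            pop = f"p{p}"
            groups[pop] = "HYB"; coords[pop] = (35.0, -108.0, 2000.0)
            for i in range(n_ind):
                ind = f"{pop}_{i}"; inds.append(ind); pops[ind] = pop
        G = geno(np.vstack(blocks), inds=inds)
        d = hierarchical_fstats(G, PopulationMap(pops, groups, coords))
        assert d.fst == pytest.approx(F_true, abs=0.02)

    def test_hierarchical_fct_zero_when_groups_equivalent(self, rng):
        inds, pmap = hier_map(12)
        # all four populations exchangeable: no group-level differentiation
        vals = rng.binomial(2, 0.5, size=(48, 300))
        d = hierarchical_fstats(geno(vals, inds=inds), pmap, groups=("P1", "P2"))
        assert abs(d.fct) < 0.02
        assert d.hierarchical

    def test_hierarchical_fct_detects_group_split(self, rng):
        inds, pmap = hier_map(12)
        f_by_group = {"P1": 0.2, "P2": 0.8}
        rows = []
        for ind in inds:
            grp = pmap.pop_group[pmap.individual_to_pop[ind]]
            rows.append(rng.binomial(2, f_by_group[grp], size=300))
        d = hierarchical_fstats(geno(np.array(rows), inds=inds), pmap,
                                groups=("P1", "P2"))
        assert d.fct > 0.2
        assert d.fst >= d.fct


class TestHeterozygosity:
    def test_all_homozygous(self):
        inds, pmap = two_pop_map(3)
        het = hz.heterozygosities(geno(np.full((6, 4), 2), inds=inds), pmap)
        assert (het["H_o"] == 0).all()

    def test_he_half_at_half_frequency(self):
        inds, pmap = two_pop_map(2)
        vals = np.array([[0], [2], [0], [2]])
        het = hz.heterozygosities(geno(vals, inds=inds), pmap)
        assert het["H_e"].iloc[0] == pytest.approx(0.5)

    def test_hardy_weinberg_ho_matches_he(self, rng):
        inds, pmap = two_pop_map(200)
        f = rng.uniform(0.2, 0.8, 200)
        vals = rng.binomial(2, f, size=(400, 200))
        het = hz.heterozygosities(geno(vals, inds=inds), pmap)
        assert het["H_o"].iloc[0] == pytest.approx(het["H_e"].iloc[0], abs=0.01)


class TestMedianLD:
    def test_duplicated_and_complement_loci(self, rng):
        x = rng.choice([0, 1, 2], size=40)
        vals = np.column_stack([x, x, 2 - x])
        G = geno(vals)
        r2 = r2_matrix(vals)
        assert r2[0, 1] == pytest.approx(1.0)
        assert r2[0, 2] == pytest.approx(1.0)  # sign invariance
        assert median_ld(G, G.locus_ids) == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        # six individuals, complete data: r^2 from the textbook formula
        x = np.array([0, 1, 2, 2, 1, 0], dtype=float)
        y = np.array([0, 0, 1, 2, 2, 1], dtype=float)
        r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        G = geno(np.column_stack([x, y]).astype(int))
        assert median_ld(G, G.locus_ids) == pytest.approx(r_hand**2, abs=1e-12)

    def test_pairwise_complete_handling(self):
        vals = np.array([[0, MISSING], [1, 1], [2, 2], [MISSING, 0], [1, 1]])
        r2 = r2_matrix(vals)
        x = np.array([1.0, 2.0, 1.0]); y = np.array([1.0, 2.0, 1.0])
        r = np.corrcoef(x, y)[0, 1]
        assert r2[0, 1] == pytest.approx(r**2)

    def test_matrix_symmetric_and_order_invariant(self, rng):
        vals = rng.choice([0, 1, 2, MISSING], size=(30, 8))
        r2 = r2_matrix(vals)
        assert np.allclose(r2, r2.T, equal_nan=True)
        perm = rng.permutation(30)
        assert np.allclose(r2, r2_matrix(vals[perm]), equal_nan=True)


class TestMatchedNull:
    def test_zero_bootstraps_rejected(self, small_filtered):
        G, pmap = small_filtered["G_hyb"], small_filtered["pmap"]
        with pytest.raises(ValueError):
            matched_bootstrap_null(G, pmap, G.locus_ids[:3], [], "fst", n_boot=0)

    def test_reproducible_and_valid_p(self, small_filtered):
        G, pmap = small_filtered["G_hyb"], small_filtered["pmap"]
        loci = G.locus_ids[5:13]
        a = matched_bootstrap_null(G, pmap, loci, [], "fst", n_boot=49, seed=3)
        b = matched_bootstrap_null(G, pmap, loci, [], "fst", n_boot=49, seed=3)
        assert np.array_equal(a.null_values, b.null_values)
        assert 0 < a.p <= 1
        assert a.n_boot == 49

    def test_observed_uses_same_estimator_code_path(self, small_filtered):
        G, pmap = small_filtered["G_hyb"], small_filtered["pmap"]
        loci = G.locus_ids[:6]
        mn = matched_bootstrap_null(G, pmap, loci, [], "fst", n_boot=19, seed=1)
        assert mn.observed == pytest.approx(
            hierarchical_fstats(G, pmap, loci=loci).fst)

    def test_planted_selection_detected(self, small_filtered):
        # outlier sets on planted freeze loci should sit in the upper tail of
        # the matched neutral null for F_ST
        truth = small_filtered["truth"]
        G, pmap = small_filtered["G_hyb"], small_filtered["pmap"]
        planted = [l for l in truth.loci_of_class("adaptive_introgressed")
                   if l in set(G.locus_ids)]
        mn = matched_bootstrap_null(G, pmap, planted, planted, "fst",
                                    n_boot=199, seed=2)
        assert mn.p < 0.05
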