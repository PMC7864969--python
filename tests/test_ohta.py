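"""Ohta two-locus LD components, EM gamete frequencies and MMRR."""

import itertools

import numpy as np
import pytest

import hzadapt as hz
from hzadapt import MISSING, PopulationMap
from hzadapt.mmrr import env_distance_matrix, mmrr_partition
from hzadapt.ohta import gamete_freq_em, ohta_components, pairwise_d_matrices

from conftest import geno


def two_pop_geno(vals_a, vals_b):
    vals = np.vstack([vals_a, vals_b])
    na, nb = len(vals_a), len(vals_b)
    inds = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    pmap = PopulationMap(
        {i: ("A" if i.startswith("a") else "B") for i in inds},
        {"A": "HYB", "B": "HYB"},
        {"A": (34.0, -107.0, 2000.0), "B": (36.0, -108.0, 2200.0)},
    )
    return geno(vals, inds=inds), pmap


def brute_force_components(hap_a, hap_b):
    """Components evaluated directly from phased gamete counts."""
    def stats(h):
        h = np.asarray(h)
        x = np.mean((h[:, 0] == 1) & (h[:, 1] == 1))
        return x, h[:, 0].mean(), h[:, 1].mean()
    x1, p1, q1 = stats(hap_a)
    x2, p2, q2 = stats(hap_b)
    pq1, pq2 = p1 * q1, p2 * q2
    pbar, qbar = (p1 + p2) / 2, (q1 + q2) / 2
    d2_is = ((x1 - pq1) ** 2 + (x2 - pq2) ** 2) / 2
    d2_st = ((pq1 - pbar * qbar) ** 2 + (pq2 - pbar * qbar) ** 2) / 2
    return d2_is, d2_st


class TestGameteEM:
    def test_phase_known_data_exact(self):
        # no double heterozygotes: EM equals direct gamete counting
        gA = np.array([2, 2, 0, 0, 2, 1])
        gB = np.array([2, 0, 0, 2, 2, 2])
        x, p, q, fb = gamete_freq_em(gA, gB)
        # gametes: (1,1)x2,(1,0)x2,(0,0)x2,(0,1)x2,(1,1)x2,(1,1)+(0,1)
        assert not fb
        assert p == pytest.approx(gA.mean() / 2)
        assert q == pytest.approx(gB.mean() / 2)
        assert x == pytest.approx(5 / 12, abs=1e-8)

    def test_double_het_only_uses_burrows(self):
        gA = np.ones(6, dtype=int)
        gB = np.ones(6, dtype=int)
        x, p, q, fb = gamete_freq_em(gA, gB)
        assert fb
        assert p == q == pytest.approx(0.5)

    def test_em_recovers_truth_statistically(self, rng):
        # genotypes built from known phased gametes under random pairing
        x_true, p, q = 0.35, 0.5, 0.6
        probs = [x_true, p - x_true, q - x_true, 1 - p - q + x_true]
        draws = rng.choice(4, size=(800, 2), p=probs)
        hapA = (draws < 2).astype(int)          # carries allele at locus 1
        hapB = ((draws == 0) | (draws == 2)).astype(int)
        gA, gB = hapA.sum(axis=1), hapB.sum(axis=1)
        x, _, _, fb = gamete_freq_em(gA, gB)
        assert not fb
        assert x == pytest.approx(x_true, abs=0.04)


class TestComponents:
    def test_monomorphic_gives_zero(self):
        G, pmap = two_pop_geno(np.zeros((4, 2), int), np.zeros((4, 2), int))
        c = ohta_components(G, pmap, ("A", "B"), ("l0:1", "l1:1"))
        assert c.d2_is == 0.0 and c.d2_st == 0.0

    def test_equilibrium_within_but_divergent_products(self):
        # both pops in linkage equilibrium (x_i = p_i q_i by construction,
        # phase-known), but p1 q1 != p2 q2 -> D2_IS = 0, D2_ST > 0
        a = np.array([[2, 2], [2, 2], [2, 2], [2, 2]])        # p=q=1, x=pq=1
        b = np.array([[0, 2], [0, 2], [0, 2], [0, 2]])        # p=0, q=1, x=0
        G, pmap = two_pop_geno(a, b)
        c = ohta_components(G, pmap, ("A", "B"), ("l0:1", "l1:1"))
        assert c.d2_is == pytest.approx(0.0, abs=1e-12)
        assert c.d2_st > 0

    def test_exhaustive_oracle_on_phased_haplotypes(self, rng):
        # <=20 haplotypes per population; pair gametes WITHOUT double hets so
        # the EM estimate equals the phased gamete count exactly
        for trial in range(5):
            def draw_pop(n_hap):
                haps = rng.integers(0, 2, size=(n_hap, 2))
                # pair each haplotype with an identical partner: genotype
                # 2*h has no heterozygotes, phase fully observed
                geno_rows = 2 * haps
                return haps, geno_rows
            ha, ga = draw_pop(8)
            hb, gb = draw_pop(10)
            G, pmap = two_pop_geno(ga, gb)
            c = ohta_components(G, pmap, ("A", "B"), ("l0:1", "l1:1"))
            want_is, want_st = brute_force_components(ha, hb)
            assert c.d2_is == pytest.approx(want_is, abs=1e-8)
            assert c.d2_st == pytest.approx(want_st, abs=1e-8)

    def test_too_few_individuals_rejected(self):
        G, pmap = two_pop_geno(np.array([[1, 1]]), np.array([[1, 1], [0, 0]]))
        with pytest.raises(ValueError):
            ohta_components(G, pmap, ("A", "B"), ("l0:1", "l1:1"))


class TestPairwiseMatrices:
    def _three_pop(self, rng):
        blocks = [rng.choice([0, 1, 2], size=(5, 3)) for _ in range(3)]
        inds, pops, groups, coords = [], {}, {}, {}
        for k, b in enumerate(blocks):
            pop = f"p{k}"
            groups[pop] = "HYB"; coords[pop] = (34.0 + k, -107.0, 2000.0)
            for i in range(5):
                ind = f"{pop}_{i}"; inds.append(ind); pops[ind] = pop
        G = geno(np.vstack(blocks), inds=inds)
        return G, PopulationMap(pops, groups, coords)

    def test_matches_per_pair_components(self, rng):
        G, pmap = self._three_pop(rng)
        loci = G.locus_ids
        D_is, D_st = pairwise_d_matrices(G, pmap, loci)
        pops = pmap.populations
        for a, b in itertools.combinations(pops, 2):
            vals_is, vals_st = [], []
            for lp in itertools.combinations(loci, 2):
                c = ohta_components(G, pmap, (a, b), lp)
                vals_is.append(c.d2_is); vals_st.append(c.d2_st)
            assert D_is.loc[a, b] == pytest.approx(np.median(vals_is), abs=1e-10)
            assert D_st.loc[a, b] == pytest.approx(np.median(vals_st), abs=1e-10)

    def test_locus_order_invariance(self, rng):
        G, pmap = self._three_pop(rng)
        a = pairwise_d_matrices(G, pmap, G.locus_ids)
        b = pairwise_d_matrices(G, pmap, list(reversed(G.locus_ids)))
        assert np.allclose(a[0].values, b[0].values, equal_nan=True)

    def test_cloned_population_zero_dst(self, rng):
        block = rng.choice([0, 1, 2], size=(6, 3))
        inds = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        pmap = PopulationMap(
            {i: ("A" if i.startswith("a") else "B") for i in inds},
            {"A": "HYB", "B": "HYB"},
            {"A": (34.0, -107.0, 2000.0), "B": (34.0, -107.0, 2000.0)},
        )
        G = geno(np.vstack([block, block]), inds=inds)
        _, D_st = pairwise_d_matrices(G, pmap, G.locus_ids)
        assert D_st.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)


class TestMMRR:
    def _mats(self, rng, n=15):
        v = rng.normal(size=n)
        E = np.abs(v[:, None] - v[None, :])
        g = rng.normal(size=n)
        Gd = np.abs(g[:, None] - g[None, :])
        return E, Gd

    def test_constructed_response_recovered(self, rng):
        E, Gd = self._mats(rng)
        res = mmrr_partition(E.copy(), E, Gd, n_perm=99, seed=1)
        assert res.r2_full > 0.99
        assert res.r2_pure_env > 0.8
        assert res.p_full <= 0.05

    def test_decomposition_identity(self, rng):
        E, Gd = self._mats(rng)
        R = 0.5 * E + 0.5 * Gd + 0.1 * np.abs(rng.normal(size=E.shape))
        R = (R + R.T) / 2; np.fill_diagonal(R, 0)
        res = mmrr_partition(R, E, Gd, n_perm=0, seed=0)
        total = res.r2_pure_env + res.r2_pure_geo + res.r2_confounded
        assert total == pytest.approx(res.r2_full, abs=1e-10)

    def test_relabeling_invariance(self, rng):
        E, Gd = self._mats(rng)
        R = 0.7 * E + 0.3 * Gd
        perm = rng.permutation(15)
        res1 = mmrr_partition(R, E, Gd, n_perm=0)
        res2 = mmrr_partition(R[np.ix_(perm, perm)], E[np.ix_(perm, perm)],
                              Gd[np.ix_(perm, perm)], n_perm=0)
        assert res1.r2_full == pytest.approx(res2.r2_full, abs=1e-10)

    def test_constant_response_rejected(self, rng):
        E, Gd = self._mats(rng)
        with pytest.raises(ValueError):
            mmrr_partition(np.zeros_like(E), E, Gd, n_perm=0)


class TestLDPartitionSignature:
    def test_freeze_dis_vs_water_ordering(self):
        # ancestry-correlated (freeze) outlier sets should out-score
        # ancestry-independent (water) sets on within-population LD (D_IS),
        # and the relative standing must reverse for the among-population
        # component (D_ST); medians over three replicate simulations
        from hzadapt.simulate import SimParams, simulate_hybrid_zone
        r2is = {"freeze": [], "water": []}
        r2st = {"freeze": [], "water": []}
        for seed in (1, 2, 3):
            G, pmap, env, truth = simulate_hybrid_zone(SimParams(seed=seed))
            G_hyb = hz.filter_biallelic(G, pmap, {"HYB"})
            F = hz.hybrid_freq_table(G_hyb, pmap)
            outs, _ = hz.gea_scan(F, env, seed=seed, subset_size=1000)
            hybp = pmap.populations_of_group("HYB")
            D_geo = hz.geographic_distance_matrix(pmap).loc[hybp, hybp]
            for g, s in outs.items():
                D_is, D_st = pairwise_d_matrices(G_hyb, pmap, s.loci, hybp)
                D_env = env_distance_matrix(env, g, hybp)
                cls = env.gradient_class(g)
                r2is[cls].append(
                    mmrr_partition(D_is, D_env, D_geo, n_perm=0).r2_full)
                r2st[cls].append(
                    mmrr_partition(D_st, D_env, D_geo, n_perm=0).r2_full)
        med = lambda v: float(np.median(v))
        assert med(r2is["freeze"]) > med(r2is["water"])
        assert med(r2st["water"]) > med(r2st["freeze"])
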