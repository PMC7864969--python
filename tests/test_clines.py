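"""Hybrid index, genomic clines, neutral envelopes and introgression calls."""

import numpy as np
import pandas as pd
import pytest

import hzadapt as hz
from hzadapt import MISSING, PopulationMap
from hzadapt.clines import (
    call_introgressed_snps,
    fit_genomic_clines,
    hybrid_index,
    neutral_cline_envelope,
    parental_freqs,
)

from conftest import geno


def parental_system(n_loci=60, n_each=10, mid_rows=None):
    """Fixed-difference parents plus optional hybrid rows."""
    inds, pops, groups, coords = [], {}, {}, {}
    rows = []
    for pref, grp, g in (("s", "P1", 0), ("f", "P2", 2)):
        pop = pref + "0"
        groups[pop] = grp
        coords[pop] = (33.0 if grp == "P1" else 41.0, -108.0, 2400.0)
        for i in range(n_each):
            ind = f"{pref}{i}"
            inds.append(ind); pops[ind] = pop
            rows.append(np.full(n_loci, g))
    if mid_rows is not None:
        groups["h0"] = "HYB"
        coords["h0"] = (37.0, -108.0, 2400.0)
        for k, r in enumerate(mid_rows):
            ind = f"h{k}"
            inds.append(ind); pops[ind] = "h0"
            rows.append(r)
    G = geno(np.array(rows), inds=inds)
    return G, PopulationMap(pops, groups, coords)


class TestHybridIndex:
    def test_pure_and_heterozygous_individuals(self):
        n_loci = 80
        mids = [np.full(n_loci, 0), np.full(n_loci, 2), np.full(n_loci, 1)]
        G, pmap = parental_system(n_loci, mid_rows=mids)
        hi = hybrid_index(G, pmap, min_informative=10).set_index("individual")
        assert hi.loc["h0", "h"] == pytest.approx(0.0, abs=1e-3)
        assert hi.loc["h1", "h"] == pytest.approx(1.0, abs=1e-3)
        assert hi.loc["h2", "h"] == pytest.approx(0.5, abs=1e-3)

    def test_low_confidence_flag(self):
        G, pmap = parental_system(60, mid_rows=[np.full(60, MISSING)])
        hi = hybrid_index(G, pmap, min_informative=50).set_index("individual")
        assert bool(hi.loc["h0", "low_confidence"])

    def test_recovery_against_truth(self):
        # trees simulated with known ancestry; 1000+ informative loci
        from hzadapt.simulate import SimParams, simulate_hybrid_zone
        p = SimParams(n_hyb_pops=10, trees_per_pop=(6, 6), n_loci=2500,
                      parental_divergence=0.35, n_adaptive_introgressed=0,
                      n_adaptive_background=0, missing_rate=0.05, seed=17)
        G, pmap, env, truth = simulate_hybrid_zone(p)
        hyb = pmap.individuals_of_groups(["HYB"])
        hi = hybrid_index(G, pmap, individuals=hyb).set_index("individual")
        q = truth.tree_ancestry
        err = np.mean([abs(hi.loc[i, "h"] - q[i]) for i in hyb])
        assert err < 0.03


class TestClineFits:
    def test_constant_hybrid_index_refused(self, small_filtered):
        G, pmap = small_filtered["G_hyb"], small_filtered["pmap"]
        f1, f2 = parental_freqs(G, pmap)
        with pytest.raises(ValueError):
            fit_genomic_clines(G, np.full(G.n_individuals, 0.5), f1, f2)

    def test_planted_excess_detected_at_moderate_sample(self, rng):
        # spec-style power construction: P2-allele probability h + 0.3
        n = 500
        h = rng.uniform(0, 0.7, n)
        f1, f2 = 0.05, 0.95
        pi_neutral = h * f2 + (1 - h) * f1
        pi_shift = np.clip(pi_neutral + 0.3, 0, 1)
        S = 400  # pretend family size for Bonferroni
        vals = np.column_stack([
            rng.binomial(2, pi_shift),              # planted
            rng.binomial(2, pi_neutral),            # neutral
        ]).astype(np.int16)
        inds = [f"i{k}" for k in range(n)]
        G = geno(vals, inds=inds)
        f1v = np.array([f1, f1]); f2v = np.array([f2, f2])
        fits = fit_genomic_clines(G, h, f1v, f2v, individuals=inds)
        p_planted = fits.table["p"].iloc[0]
        assert p_planted < 0.05 / S
        assert fits.table["p"].iloc[1] > 1e-4

    def test_neutral_mixture_p_uniformish(self, rng):
        n, L = 200, 300
        h = rng.uniform(0, 1, n)
        f1 = rng.uniform(0.05, 0.3, L)
        f2 = rng.uniform(0.7, 0.95, L)
        pi = h[None, :] * f2[:, None] + (1 - h[None, :]) * f1[:, None]
        vals = rng.binomial(2, pi).T.astype(np.int16)
        G = geno(vals)
        fits = fit_genomic_clines(G, h, f1, f2)
        p = fits.table["p"]
        assert 0.35 < p.mean() < 0.65
        assert (p < 0.01).mean() < 0.05

    def test_collapsed_binomial_when_class_absent(self, rng):
        n = 100
        h = rng.uniform(0, 1, n)
        vals = rng.integers(0, 2, size=(n, 1)).astype(np.int16)  # never 2
        G = geno(vals)
        fits = fit_genomic_clines(G, h, np.array([0.2]), np.array([0.6]))
        assert bool(fits.table["collapsed"].iloc[0])
        assert fits.table["df"].iloc[0] == 3


class TestEnvelope:
    def _setup(self, rng, n=120):
        h = np.sort(rng.uniform(0, 1, n))
        pairs = np.column_stack([rng.uniform(0.02, 0.2, 40),
                                 rng.uniform(0.8, 0.98, 40)])
        return h, pairs

    def test_level_one_is_maximum_and_seeded(self, rng):
        h, pairs = self._setup(rng)
        e1 = neutral_cline_envelope(h, pairs, n_sim=120, level=1.0, seed=5)
        e2 = neutral_cline_envelope(h, pairs, n_sim=120, level=0.95, seed=5)
        e3 = neutral_cline_envelope(h, pairs, n_sim=120, level=0.95, seed=5)
        assert np.all(e1 >= e2 - 1e-12)
        assert np.array_equal(e2, e3)

    def test_raw_scale_envelope_rises_with_h(self, rng):
        # the neutral P2-homozygote probability grows with hybrid index, so
        # the phi-scale envelope must too (checked on binned means)
        h, pairs = self._setup(rng, n=200)
        env = neutral_cline_envelope(h, pairs, n_sim=300, seed=6, scale="phi")
        bins = np.array_split(np.argsort(h), 4)
        means = [env[b].mean() for b in bins]
        assert all(np.diff(means) > -0.02)
        assert means[-1] > means[0]

    def test_minimum_simulations_enforced(self, rng):
        h, pairs = self._setup(rng)
        with pytest.raises(ValueError):
            neutral_cline_envelope(h, pairs, n_sim=50)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    n, L = 200, 120
    h = rng.uniform(0, 1, n)
    f1 = rng.uniform(0.02, 0.1, L)
    f2 = rng.uniform(0.9, 0.98, L)
    pi = h[None, :] * f2[:, None] + (1 - h[None, :]) * f1[:, None]
    # loci 0-9 planted with a strong P2-ward excess,
    # loci 10-19 planted with a P1-ward deficit (opposite direction)
    pi[:10] = np.clip(pi[:10] + 0.35, 0, 1)
    pi[10:20] = np.clip(pi[10:20] - 0.35, 0, 1)
    vals = rng.binomial(2, pi).T.astype(np.int16)
    G = geno(vals)
    fits = fit_genomic_clines(G, h, f1, f2)
    pairs = np.column_stack([f1, f2])
    env = neutral_cline_envelope(h, pairs, n_sim=200, seed=9)
    return fits, env


class TestCalls:
    def test_direction_asymmetry(self, fitted):
        fits, env = fitted
        calls = call_introgressed_snps(fits, env)
        called = set(calls.loci)
        p2_planted = {fits.table["locus"].iloc[i] for i in range(10)}
        p1_planted = {fits.table["locus"].iloc[i] for i in range(10, 20)}
        assert len(called & p2_planted) >= 8
        assert not (called & p1_planted)

    def test_monotone_in_thresholds(self, fitted):
        fits, env = fitted
        base = set(call_introgressed_snps(fits, env, tree_frac=0.2).loci)
        stricter_frac = set(call_introgressed_snps(fits, env, tree_frac=0.5).loci)
        stricter_alpha = set(
            call_introgressed_snps(fits, env, alpha_family=0.001).loci)
        assert stricter_frac <= base
        assert stricter_alpha <= base

    def test_zero_tree_frac_reduces_to_bonferroni(self, fitted):
        fits, env = fitted
        calls = call_introgressed_snps(fits, env, tree_frac=0.0)
        thr = 0.05 / len(fits.table)
        bonf = set(fits.table.loc[fits.table["p"] < thr, "locus"])
        assert set(calls.loci) == bonf
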