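"""Ohta's within/among-population partitioning of two-locus LD.

For a locus pair and a set of S subpopulations with gamete (haplotype)
frequency x_i of the counted-counted haplotype and counted-allele
frequencies p_i, q_i at the two loci:

    D2_IS = (1/S) * sum_i (x_i - p_i q_i)^2      (within-population LD)
    D2_ST = (1/S) * sum_i (p_i q_i - pbar qbar)^2 (among-population part)

Elevated D2_IS for loci tied to an ancestry-correlated gradient is the
signature of recent introgression/selection along the cline, whereas
elevated D2_ST tracks locally divergent allele-frequency products.

Gamete frequencies are estimated from unphased genotypes by an EM
algorithm under Hardy–Weinberg (only double heterozygotes have ambiguous
phase); data consisting solely of double heterozygotes are
non-identifiable and fall back to the Burrows composite estimate,
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap, logger

EM_TOL = 1e-8
EM_MAX_ITER = 100


@dataclass
class OhtaComponents:
    """Components for one locus pair over S subpopulations."""

    x: np.ndarray  # gamete-frequency estimate per subpop
    p: np.ndarray  # counted-allele frequency, locus 1
    q: np.ndarray  # counted-allele frequency, locus 2
    d2_is: float
    d2_st: float
    em_fallback: np.ndarray  # True where Burrows composite was used


def gamete_freq_em(
    gA: np.ndarray, gB: np.ndarray
) -> tuple[float, float, float, bool]:
    """EM gamete frequency for one locus pair in one population.

    ``gA``/``gB`` are 012 genotypes (MISSING allowed); individuals missing
    at either locus are dropped. Returns ``(x, p, q, fallback)`` where x
    is the frequency of the haplotype carrying the counted allele at both
    loci.
    """
    x, p, q, fb = _gamete_freq_em_batch(gA[:, None], gB[:, None])
    return float(x[0]), float(p[0]), float(q[0]), bool(fb[0])


def _gamete_freq_em_batch(
    gA: np.ndarray, gB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM over locus pairs (columns of gA/gB)."""
    valid = (gA != MISSING) & (gB != MISSING)
    a = np.where(valid, gA, 0).astype(float)
    b = np.where(valid, gB, 0).astype(float)
    n = valid.sum(axis=0).astype(float)
    if (n < 2).any():
        raise ValueError("locus pair with fewer than 2 complete individuals")
    p = a.sum(axis=0) / (2.0 * n)
    q = b.sum(axis=0) / (2.0 * n)
    # phase-known counted-counted haplotypes per individual
    known = (np.where(valid & (gA == 2), b, 0.0).sum(axis=0)
             + (valid & (gA == 1) & (gB == 2)).sum(axis=0))
    n_dh = (valid & (gA == 1) & (gB == 1)).sum(axis=0).astype(float)

    x = p * q  # linkage-equilibrium start
    lo = np.maximum(0.0, p + q - 1.0)
    hi = np.minimum(p, q)
    for _ in range(EM_MAX_ITER):
        x00 = 1.0 - p - q + x
        x10 = p - x
        x01 = q - x
        num = x * x00
        den = num + x10 * x01
        with np.errstate(invalid="ignore", divide="ignore"):
            prob = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        x_new = np.clip((known + n_dh * prob) / (2.0 * n), lo, hi)
        if np.max(np.abs(x_new - x)) < EM_TOL:
            x = x_new
            break
        x = x_new
    # non-identifiable: every informative individual is a double het
    fallback = (n_dh == n) & (n > 0)
    if fallback.any():
        # Burrows composite: Delta = sum(gA*gB)/(2n) - 2 p q ; x ~ pq + Delta/2
        delta = (a * b).sum(axis=0) / (2.0 * n) - 2.0 * p * q
        x_bur = np.clip(p * q + delta / 2.0, lo, hi)
        x = np.where(fallback, x_bur, x)
    return x, p, q, fallback


def ohta_components(
    G: GenotypeMatrix,
    pmap: PopulationMap,
    pops: tuple[str, str] | list[str],
    locus_pair: tuple[str, str],
) -> OhtaComponents:
    """D2_IS and D2_ST for one locus pair over the given subpopulations."""
    cols = G.locus_index(list(locus_pair))
    xs, ps, qs, fbs = [], [], [], []
    for pop in pops:
        rows = pmap.row_indices(G, pmap.individuals_of_pops([pop]))
        gA, gB = G.values[rows, cols[0]], G.values[rows, cols[1]]
        x, p, q, fb = gamete_freq_em(gA, gB)
        if fb:
            logger.info(
                "ohta_components: Burrows fallback for %s in %s", locus_pair, pop
            )
        xs.append(x); ps.append(p); qs.append(q); fbs.append(fb)
    x, p, q = map(np.asarray, (xs, ps, qs))
    pq = p * q
    d2_is = float(np.mean((x - pq) ** 2))
    d2_st = float(np.mean((pq - p.mean() * q.mean()) ** 2))
    return OhtaComponents(x, p, q, d2_is, d2_st, np.asarray(fbs))


def pairwise_d_matrices(
    G: GenotypeMatrix,
    pmap: PopulationMap,
    outlier_loci: list[str],
    pops: list[str] | None = None,
    min_ind: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median D2_IS and D2_ST over locus pairs, for every population pair.

    Entry (p, p') is the median over all unordered pairs of
    ``outlier_loci`` of the respective component computed with S = 2
    subpopulations {p, p'}; locus pairs with fewer than ``min_ind``
    complete individuals in either population are skipped, and a
    population pair with no valid locus pair gets NaN (excluded from the
    downstream regression). Diagonals are 0 by convention.
    """
    if len(outlier_loci) < 2:
        raise ValueError("need at least 2 outlier loci")
    pops = pops if pops is not None else pmap.populations_of_group("HYB")
    cols = G.locus_index(outlier_loci)
    L = len(cols)
    jj, kk = np.triu_indices(L, k=1)

    # per-population genotype blocks restricted to the outlier loci
    blocks = {}
    for p in pops:
        rows = pmap.row_indices(G, pmap.individuals_of_pops([p]))
        blocks[p] = G.values[np.ix_(rows, cols)]

    def per_pop_stats(pop: str):
        V = blocks[pop]
        gA, gB = V[:, jj], V[:, kk]
        valid = (gA != MISSING) & (gB != MISSING)
        nv = valid.sum(axis=0)
        usable = nv >= min_ind
        x = np.full(jj.size, np.nan)
        p_ = np.full(jj.size, np.nan)
        q_ = np.full(jj.size, np.nan)
        if usable.any():
            xs, ps, qs, _ = _gamete_freq_em_batch(gA[:, usable], gB[:, usable])
            x[usable], p_[usable], q_[usable] = xs, ps, qs
        return x, p_, q_

    stats = {p: per_pop_stats(p) for p in pops}
    n = len(pops)
    D_is = np.zeros((n, n))
    D_st = np.zeros((n, n))
    for i in range(n):
        x1, p1, q1 = stats[pops[i]]
        for j in range(i + 1, n):
            x2, p2, q2 = stats[pops[j]]
            ok = np.isfinite(x1) & np.isfinite(x2)
            if not ok.any():
                D_is[i, j] = D_is[j, i] = np.nan
                D_st[i, j] = D_st[j, i] = np.nan
                continue
            pq1, pq2 = p1[ok] * q1[ok], p2[ok] * q2[ok]
            d2_is = 0.5 * ((x1[ok] - pq1) ** 2 + (x2[ok] - pq2) ** 2)
            pbar = 0.5 * (p1[ok] + p2[ok])
            qbar = 0.5 * (q1[ok] + q2[ok])
            pq_bar = pbar * qbar
            d2_st = 0.5 * ((pq1 - pq_bar) ** 2 + (pq2 - pq_bar) ** 2)
            D_is[i, j] = D_is[j, i] = float(np.median(d2_is))
            D_st[i, j] = D_st[j, i] = float(np.median(d2_st))
    return (
        pd.DataFrame(D_is, index=pops, columns=pops),
        pd.DataFrame(D_st, index=pops, columns=pops),
    )
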