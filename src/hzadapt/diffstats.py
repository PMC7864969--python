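"""Hierarchical F-statistics, heterozygosities, LD medians and matched nulls.

Differentiation is estimated by a moment (ANOVA) decomposition of allele
indicator variance over a nested design with up to four strata: groups,
populations within groups, individuals within populations, and gene
copies within individuals. Unbalanced sample sizes and per-locus
missingness are handled with Searle-type expected-mean-square
coefficients. F_CT is the among-group variance fraction and F_ST the
among-population (groups + populations-within-groups) fraction;
multilocus values are ratios of summed variance components.

Outlier SNP sets are tested against matched bootstrap nulls: putatively
neutral SNPs resampled from the same two-dimensional bins of minor allele
frequency and missing-data proportion as the focal set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap, logger


@dataclass
class DiffStats:
    """Variance-component differentiation estimates.

    ``components`` holds per-locus variance components with rows
    (groups, pops-within-groups, individuals, within-individual); the
    group level is absent (zeros) for a single-group design.
    """

    fst: float
    fct: float
    fst_per_locus: np.ndarray
    fct_per_locus: np.ndarray
    components: np.ndarray  # 4 x n_loci
    hierarchical: bool


@dataclass
class MatchedNull:
    """Bootstrap null for one statistic of one outlier set."""

    statistic: str
    observed: float
    null_values: np.ndarray
    p: float
    n_boot: int
    n_widened: int  # outlier SNPs whose matching bin had to be widened


# ---------------------------------------------------------------------------
# Nested ANOVA machinery
# ---------------------------------------------------------------------------


def _design_arrays(
    G: GenotypeMatrix, pmap: PopulationMap, groups: Sequence[str] | None
):
    """Row indices, population index per row, and group index per population."""
    if groups is None:
        groups_used = None
        pops = pmap.populations
    else:
        pops = [p for g in groups for p in pmap.populations_of_group(g)]
        groups_used = groups
        for g in groups:
            if len(pmap.populations_of_group(g)) < 2:
                raise ValueError(
                    f"group {g!r} has fewer than 2 populations: F_CT undefined"
                )
    inds = pmap.individuals_of_pops(pops)
    rows = pmap.row_indices(G, inds)
    pop_of = {p: i for i, p in enumerate(pops)}
    pop_idx = np.array(
        [pop_of[pmap.individual_to_pop[i]] for i in inds], dtype=int
    )
    if groups_used is None:
        grp_of_pop = np.zeros(len(pops), dtype=int)
        n_groups = 1
    else:
        gidx = {g: i for i, g in enumerate(groups_used)}
        grp_of_pop = np.array([gidx[pmap.pop_group[p]] for p in pops], dtype=int)
        n_groups = len(groups_used)
    return rows, pop_idx, grp_of_pop, len(pops), n_groups


def _anova_components(
    vals: np.ndarray, pop_idx: np.ndarray, grp_of_pop: np.ndarray,
    n_pops: int, n_groups: int,
) -> np.ndarray:
    """Per-locus variance components (4 x L) of the nested allele-indicator ANOVA.

    ``vals`` is individuals x loci in 012 coding with MISSING sentinels.
    Rows of the result: among groups, among populations within groups,
    among individuals within populations, within individuals.
    """
    obs = (vals != MISSING)
    V = np.where(obs, vals, 0).astype(float)
    O = obs.astype(float)
    n_ind, L = vals.shape

    Pm = np.zeros((n_pops, n_ind))
    Pm[pop_idx, np.arange(n_ind)] = 1.0
    Gm = np.zeros((n_groups, n_pops))
    Gm[grp_of_pop, np.arange(n_pops)] = 1.0

    S_p = Pm @ V          # counted-allele copies per pop
    O_p = Pm @ O          # observed individuals per pop
    N_p = 2.0 * O_p       # allele copies per pop
    S_g, O_g = Gm @ S_p, Gm @ O_p
    N_g = 2.0 * O_g
    S_t, O_t = S_g.sum(axis=0), O_g.sum(axis=0)
    N_t = 2.0 * O_t

    def safe_div(a, b):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(b > 0, a / np.where(b > 0, b, 1.0), 0.0)

    m_p = safe_div(S_p, N_p)
    m_g = safe_div(S_g, N_g)
    m_t = safe_div(S_t, N_t)

    het = (vals == 1)
    ss_w = 0.5 * het.sum(axis=0).astype(float)
    mp_ind = m_p[pop_idx]  # pop mean broadcast to individuals
    ss_c = (O * 2.0 * (V / 2.0 - mp_ind) ** 2).sum(axis=0)
    mg_pop = m_g[grp_of_pop]
    ss_b = (N_p * (m_p - mg_pop) ** 2).sum(axis=0)
    ss_a = (N_g * (m_g - m_t) ** 2).sum(axis=0)

    # cell counts actually carrying data at each locus
    pops_nz = (N_p > 0)
    grps_nz = (N_g > 0)
    n_pops_l = pops_nz.sum(axis=0).astype(float)
    n_grps_l = grps_nz.sum(axis=0).astype(float)

    sum_Np2_by_g = Gm @ (N_p**2)
    # Expected-mean-square coefficients (Searle), per locus
    mWW = N_t - O_t
    mCC = N_t - safe_div(4.0 * O_p, N_p).sum(axis=0)
    mCW = O_t - n_pops_l
    mBB = N_t - safe_div(sum_Np2_by_g, N_g).sum(axis=0)
    mBC = safe_div(4.0 * O_p, N_p).sum(axis=0) - safe_div(4.0 * O_g, N_g).sum(axis=0)
    mBW = n_pops_l - n_grps_l
    mAA = N_t - safe_div(N_g**2, N_t[None, :] * np.ones_like(N_g)).sum(axis=0)
    mAB = safe_div(sum_Np2_by_g, N_g).sum(axis=0) - safe_div(
        (N_p**2).sum(axis=0), N_t
    )
    mAC = safe_div(4.0 * O_g, N_g).sum(axis=0) - safe_div(4.0 * O_t, N_t)
    mAW = n_grps_l - 1.0

    sig_w = safe_div(ss_w, mWW)
    sig_c = safe_div(ss_c - mCW * sig_w, mCC)
    sig_b = safe_div(ss_b - mBW * sig_w - mBC * sig_c, mBB)
    sig_a = safe_div(ss_a - mAW * sig_w - mAC * sig_c - mAB * sig_b, mAA)
    if n_groups == 1:
        sig_a = np.zeros(L)
    return np.vstack([sig_a, sig_b, sig_c, sig_w])


def hierarchical_fstats(
    G: GenotypeMatrix,
    pmap: PopulationMap,
    groups: Sequence[str] | None = None,
    loci: Sequence[str] | None = None,
) -> DiffStats:
    """Hierarchical (or flat) F-statistics by nested variance components.

    With ``groups`` given (e.g. ``("P1", "P2", "HYB")``), F_CT is the
    among-group and F_ST the among-population differentiation relative to
    the total; every group must contain >= 2 populations. With
    ``groups=None`` all populations form one stratum and only F_ST is
    defined. Multilocus estimates are ratios of summed components.
    """
    rows, pop_idx, grp_of_pop, n_pops, n_groups = _design_arrays(G, pmap, groups)
    vals = G.values[rows]
    if loci is not None:
        # duplicates allowed: bootstrap draws are with replacement
        vals = vals[:, G.locus_index(list(loci))]
    comp = _anova_components(vals, pop_idx, grp_of_pop, n_pops, n_groups)
    sig_a, sig_b, sig_c, sig_w = comp
    tot = comp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst_l = np.where(tot != 0, (sig_a + sig_b) / tot, np.nan)
        fct_l = np.where(tot != 0, sig_a / tot, np.nan)
    denom = tot.sum()
    fst = float((sig_a + sig_b).sum() / denom) if denom != 0 else np.nan
    fct = float(sig_a.sum() / denom) if denom != 0 else np.nan
    if n_groups == 1:
        fct = np.nan
        fct_l = np.full_like(fst_l, np.nan)
    return DiffStats(fst, fct, fst_l, fct_l, comp, hierarchical=n_groups > 1)


def heterozygosities(
    G: GenotypeMatrix, pmap: PopulationMap, groups: Sequence[str] | None = None
) -> pd.DataFrame:
    """Observed and expected heterozygosity per group (mean over loci).

    H_o is the fraction of heterozygotes among non-missing calls and
    H_e = 2 f (1 - f) with f the group-wide allele frequency; loci with
    no data in a group are excluded from that group's mean.
    """
    groups = groups or sorted({pmap.pop_group[p] for p in pmap.populations})
    out = []
    for g in groups:
        inds = pmap.individuals_of_groups([g])
        if not inds:
            continue
        rows = pmap.row_indices(G, inds)
        vals = G.values[rows]
        obs = vals != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(n_obs > 0, (vals == 1).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
            f = np.where(n_obs > 0,
                         np.where(obs, vals, 0).sum(axis=0) / np.maximum(2 * n_obs, 1),
                         np.nan)
        he = 2.0 * f * (1.0 - f)
        out.append((g, float(np.nanmean(ho)), float(np.nanmean(he))))
    return pd.DataFrame(out, columns=["group", "H_o", "H_e"])


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def r2_matrix(vals: np.ndarray, min_pairs: int = 2) -> np.ndarray:
    """Pairwise squared Pearson correlation of 012 columns.

    Correlations use individuals non-missing at both loci of a pair;
    pairs with fewer than ``min_pairs`` complete individuals or zero
    variance get NaN. Diagonal is 1 where defined.
    """
    obs = (vals != MISSING)
    V = np.where(obs, vals, 0).astype(float)
    O = obs.astype(float)
    n = O.T @ O
    sx = V.T @ O
    sxy = V.T @ V
    sxx = (V**2).T @ O
    cov = n * sxy - sx * sx.T
    varx = n * sxx - sx**2
    den = varx * varx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((n >= min_pairs) & (den > 0), cov**2 / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(r2, 1.0)
    r2[np.diag_indices_from(r2)] = np.where(
        np.diag(n) >= min_pairs, 1.0, np.nan
    )
    return r2


def median_ld(
    G: GenotypeMatrix, loci: Sequence[str], rows: np.ndarray | None = None
) -> float:
    """Median r^2 over all unordered pairs of the given loci."""
    if len(loci) < 2:
        raise ValueError("median_ld needs at least 2 loci")
    cols = G.locus_index(loci)
    vals = G.values[:, cols] if rows is None else G.values[np.ix_(rows, cols)]
    r2 = r2_matrix(vals)
    iu = np.triu_indices(len(cols), k=1)
    vals_u = r2[iu]
    n_skipped = int(np.isnan(vals_u).sum())
    if n_skipped:
        logger.info("median_ld: %d locus pairs skipped (too few complete pairs)", n_skipped)
    return float(np.nanmedian(vals_u))


# ---------------------------------------------------------------------------
# Matched bootstrap nulls
# ---------------------------------------------------------------------------

MAF_BIN_WIDTH = 0.05
MISS_BIN_WIDTH = 0.05


def match_bins(maf: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """Two-dimensional (MAF, missingness) bin index per locus."""
    mb = np.clip((maf / MAF_BIN_WIDTH).astype(int), 0, int(0.5 / MAF_BIN_WIDTH) - 1)
    sb = np.clip((miss / MISS_BIN_WIDTH).astype(int), 0, int(1.0 / MISS_BIN_WIDTH) - 1)
    return np.stack([mb, sb], axis=1)


def matched_bootstrap_null(
    G: GenotypeMatrix,
    pmap: PopulationMap,
    outlier_loci: Sequence[str],
    exclude_loci: Iterable[str],
    statistic: str | Callable[[list[str]], float],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    groups: Sequence[str] | None = None,
    scope_rows: np.ndarray | None = None,
) -> MatchedNull:
    """Empirical null for a set statistic from bin-matched neutral SNPs.

    The neutral pool is every analysed locus minus ``exclude_loci``
    (conventionally the union of outliers over all gradients). Each
    bootstrap replicate draws, for every outlier SNP, one neutral SNP
    uniformly (with replacement) from the same (MAF x missingness) bin,
    widening the bin by one step at a time when empty, and recomputes the
    statistic. The upper-tail p-value uses the +1 correction.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if statistic == "fst":
        stat_fn = lambda loci: hierarchical_fstats(G, pmap, groups, loci).fst
    elif statistic == "fct":
        stat_fn = lambda loci: hierarchical_fstats(G, pmap, groups, loci).fct
    elif statistic == "median_r2":
        stat_fn = lambda loci: median_ld(G, loci, rows=scope_rows)
    elif callable(statistic):
        stat_fn = statistic
        statistic = getattr(statistic, "__name__", "custom")
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    from .core import minor_allele_freq, missingness

    maf = minor_allele_freq(G, scope_rows)
    miss = missingness(G, scope_rows)
    bins = match_bins(np.nan_to_num(maf), miss)
    pool_ids = [l for l in G.locus_ids if l not in set(exclude_loci)]
    if not pool_ids:
        raise ValueError("neutral pool is empty")
    pool_idx = G.locus_index(pool_ids)
    out_idx = G.locus_index(outlier_loci)

    # map each outlier SNP to its matched neutral candidates
    candidates: list[np.ndarray] = []
    n_widened = 0
    for j in out_idx:
        width = 0
        while True:
            ok = (np.abs(bins[pool_idx, 0] - bins[j, 0]) <= width) & (
                np.abs(bins[pool_idx, 1] - bins[j, 1]) <= width
            )
            if ok.any():
                break
            width += 1
            if width > max(int(0.5 / MAF_BIN_WIDTH), int(1.0 / MISS_BIN_WIDTH)):
                raise ValueError(
                    f"no neutral SNP matches locus {G.locus_ids[j]} in any bin"
                )
        if width > 0:
            n_widened += 1
            logger.info(
                "matched_bootstrap_null: bin widened %d step(s) for %s",
                width, G.locus_ids[j],
            )
        candidates.append(pool_idx[ok])

    observed = stat_fn(list(outlier_loci))
    null = np.empty(n_boot)
    for b in range(n_boot):
        draw = [c[rng.integers(c.size)] for c in candidates]
        null[b] = stat_fn([G.locus_ids[j] for j in draw])
    p = (1.0 + np.sum(null >= observed)) / (n_boot + 1.0)
    return MatchedNull(str(statistic), float(observed), null, float(p), n_boot, n_widened)
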