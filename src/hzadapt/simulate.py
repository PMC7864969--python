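"""Synthetic hybrid-zone generator with planted truth.

Emulates the sampling structure of a two-species conifer hybrid zone: a
latitudinal cline in genome-wide ancestry across hybrid populations
flanked by pure parental populations of each species, tens of thousands
(desk preset: thousands) of biallelic SNPs with missing data, and
environmental gradients of two kinds — "freeze-like" gradients that
covary with latitude (hence with ancestry) and "water-like" gradients
independent of latitude.

Two classes of adaptive loci are planted:

* ``adaptive_introgressed`` — loci whose local ancestry weight is pushed
  toward the donor species (P2) where a freeze-class gradient is high,
  the signature of recent adaptive introgression;
* ``adaptive_background`` — loci whose frequency tracks a water-class
  gradient irrespective of ancestry, the signature of selection on
  background (standing or de novo) variation.

Allele frequencies, not coalescent genealogies, are simulated: loci are
independent, which is fast, fully seed-reproducible, and sufficient for
every statistic the pipeline computes. Parental divergence follows a
Balding–Nichols model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import MISSING, EnvTable, GenotypeMatrix, PopulationMap


@dataclass
class SimParams:
    """Generator settings; defaults are the desk-scale study preset."""

    n_hyb_pops: int = 20
    trees_per_pop: tuple[int, int] = (8, 8)  # inclusive range
    n_parental_pops: int = 4  # per species
    parental_trees_per_pop: int = 8
    n_loci: int = 5000
    n_adaptive_introgressed: int = 20
    n_adaptive_background: int = 20
    parental_divergence: float = 0.2  # Balding-Nichols F between the species
    lat_range: tuple[float, float] = (33.0, 41.0)
    cline_center: float = 37.0
    cline_width: float = 1.5
    # (name, class, target correlation with latitude over hybrid pops)
    env_gradients: tuple[tuple[str, str, float], ...] = (
        ("DD_0_wt", "freeze", 0.85),
        ("FFP", "freeze", 0.80),
        ("PAS_wt", "freeze", 0.75),
        ("RH_sp", "water", 0.0),
        ("CMD_sm", "water", 0.0),
        ("CECSOL_s1", "water", 0.0),
    )
    s_intro: float = 10.0  # logit-scale ancestry shift per SD of target gradient
    s_bg: float = 0.10  # frequency shift per SD of target gradient
    tree_ancestry_sd: float = 0.5  # logit-scale spread of tree ancestry within a pop
    drift_sd: float = 0.02
    missing_rate: float = 0.10
    min_delta_introgressed: float = 0.95  # parental freq difference for planted loci
    max_delta_background: float = 0.3  # background variants are not ancestry-informative
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.parental_divergence < 1.0):
            raise ValueError("parental_divergence must be in (0, 1)")
        for r in (self.missing_rate, self.drift_sd):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.missing_rate >= 1:
            raise ValueError("missing_rate must be < 1")
        for name, cls, rho in self.env_gradients:
            if abs(rho) > 1:
                raise ValueError(f"gradient {name}: |rho_lat| > 1 is infeasible")
            if cls not in ("freeze", "water", "other"):
                raise ValueError(f"gradient {name}: unknown class {cls!r}")
        n_planted = self.n_adaptive_introgressed + self.n_adaptive_background
        if n_planted > self.n_loci:
            raise ValueError("more planted loci than loci")
        if self.n_adaptive_introgressed and not any(
            c == "freeze" for _, c, _ in self.env_gradients
        ):
            raise ValueError("adaptive_introgressed loci need a freeze-class gradient")
        if self.n_adaptive_background and not any(
            c == "water" for _, c, _ in self.env_gradients
        ):
            raise ValueError("adaptive_background loci need a water-class gradient")
        if min(self.trees_per_pop) < 1 or self.trees_per_pop[0] > self.trees_per_pop[1]:
            raise ValueError("invalid trees_per_pop range")


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside a simulated dataset."""

    locus_class: pd.Series  # locus -> {neutral, adaptive_introgressed, adaptive_background}
    target_gradient: pd.Series  # locus -> gradient name ("" for neutral)
    ancestry: pd.Series  # population -> true donor-species ancestry q in [0, 1]
    tree_ancestry: pd.Series | None = None  # individual -> realized ancestry

    def loci_of_class(self, cls: str) -> list[str]:
        return list(self.locus_class.index[self.locus_class == cls])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus_class.index,
                "class": self.locus_class.values,
                "target_gradient": self.target_gradient.reindex(
                    self.locus_class.index
                ).fillna("").values,
            }
        )


def simulate_parental_freqs(
    n_loci: int, F_div: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balding–Nichols parental allele frequencies.

    An ancestral frequency pi ~ Uniform(0.05, 0.95) is drawn per locus and
    each species' frequency from Beta(pi(1-F)/F, (1-pi)(1-F)/F)
    independently, so the expected Weir–Cockerham divergence between the
    species is F_div. Loci that come out fixed for the same allele in both
    species are redrawn.
    """
    if not (0.0 < F_div < 1.0):
        raise ValueError("F_div must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f1 = np.empty(n_loci)
    f2 = np.empty(n_loci)
    todo = np.arange(n_loci)
    scale = (1.0 - F_div) / F_div
    while todo.size:
        pi = rng.uniform(0.05, 0.95, size=todo.size)
        a, b = pi * scale, (1.0 - pi) * scale
        f1[todo] = rng.beta(a, b)
        f2[todo] = rng.beta(a, b)
        both_fixed_same = ((f1[todo] <= 0) & (f2[todo] <= 0)) | (
            (f1[todo] >= 1) & (f2[todo] >= 1)
        )
        todo = todo[both_fixed_same]
    return f1, f2


def _exact_corr_vector(
    x: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized vector whose sample correlation with ``x`` is exactly rho."""
    zx = (x - x.mean()) / x.std()
    w = rng.normal(size=x.size)
    w = w - w.mean() - zx * (w @ zx) / (zx @ zx)  # orthogonal to zx and centred
    if np.allclose(w, 0):  # degenerate draw; retry deterministically
        w = np.arange(x.size) - (x.size - 1) / 2.0
        w = w - zx * (w @ zx) / (zx @ zx)
    w = w / np.sqrt((w @ w) / x.size)
    return rho * zx + np.sqrt(max(0.0, 1.0 - rho**2)) * w


def simulate_hybrid_zone(
    params: SimParams, return_haplotypes: bool = False
) -> tuple[GenotypeMatrix, PopulationMap, EnvTable, TruthTable] | tuple:
    """Generate a complete synthetic hybrid-zone dataset.

    Returns ``(GenotypeMatrix, PopulationMap, EnvTable, TruthTable)``, or
    with ``return_haplotypes=True`` a 5-tuple whose last element is the
    (2*n_individuals, n_loci) gamete matrix underlying the genotypes
    (rows 2i and 2i+1 are individual i's gametes); loci are simulated
    independently, so any gametic LD in the hybrid zone arises from the
    admixture structure alone — this is the oracle for the Ohta
    components.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    P = params

    # --- populations and coordinates -------------------------------------
    hyb_pops = [f"H{i + 1:02d}" for i in range(P.n_hyb_pops)]
    p1_pops = [f"S{i + 1}" for i in range(P.n_parental_pops)]  # southern species
    p2_pops = [f"F{i + 1}" for i in range(P.n_parental_pops)]  # northern donor
    lat_lo, lat_hi = P.lat_range
    hyb_lat = np.linspace(lat_lo, lat_hi, P.n_hyb_pops)
    p1_lat = np.linspace(lat_lo - 4.0, lat_lo - 1.0, P.n_parental_pops)
    p2_lat = np.linspace(lat_hi + 1.0, lat_hi + 4.0, P.n_parental_pops)

    pop_group: dict[str, str] = {}
    pop_coords: dict[str, tuple[float, float, float]] = {}
    all_pops = hyb_pops + p1_pops + p2_pops
    all_lats = np.concatenate([hyb_lat, p1_lat, p2_lat])
    lons = -108.0 + rng.normal(0.0, 0.8, size=len(all_pops))
    elevs = rng.uniform(2000.0, 3200.0, size=len(all_pops))
    for p, la, lo, el in zip(all_pops, all_lats, lons, elevs):
        pop_group[p] = "HYB" if p in hyb_pops else ("P1" if p in p1_pops else "P2")
        pop_coords[p] = (float(la), float(lo), float(el))

    # --- ancestry cline ---------------------------------------------------
    q_hyb = expit((hyb_lat - P.cline_center) / P.cline_width)
    q = pd.Series(
        np.concatenate([q_hyb, np.zeros(P.n_parental_pops), np.ones(P.n_parental_pops)]),
        index=all_pops,
        name="q",
    )

    # --- environmental gradients -----------------------------------------
    env_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    z_by_gradient: dict[str, np.ndarray] = {}
    for k, (name, cls, rho) in enumerate(P.env_gradients):
        z = _exact_corr_vector(hyb_lat, rho, rng)
        z_by_gradient[name] = z
        # parental rows: continue the latitude trend plus matched noise
        slope = rho
        z_par = slope * (
            (np.concatenate([p1_lat, p2_lat]) - hyb_lat.mean()) / hyb_lat.std()
        ) + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=2 * P.n_parental_pops)
        col = np.concatenate([z, z_par])
        env_cols[name] = 10.0 * (k + 1) + 3.0 * col  # arbitrary affine units
        meta_rows.append((name, cls, k + 1 if cls == "freeze" else len(P.env_gradients) - k))
    env = EnvTable(
        pd.DataFrame(env_cols, index=pd.Index(all_pops, name="pop")),
        pd.DataFrame(meta_rows, columns=["name", "class", "divergence_rank"]),
    )

    # --- parental frequencies and planted classes -------------------------
    f1, f2 = simulate_parental_freqs(P.n_loci, P.parental_divergence, rng)
    loci = [f"ctg{j + 1}:{(j + 1) * 100}" for j in range(P.n_loci)]
    delta = np.abs(f2 - f1)
    informative = np.flatnonzero(delta >= P.min_delta_introgressed)
    if informative.size < P.n_adaptive_introgressed:
        # top-up: force divergence at the deficit loci
        need = P.n_adaptive_introgressed - informative.size
        extra = np.argsort(delta)[::-1][informative.size : informative.size + need]
        lo = rng.uniform(0.02, max(0.021, 0.98 - P.min_delta_introgressed), size=need)
        f1[extra], f2[extra] = lo, lo + P.min_delta_introgressed
        informative = np.concatenate([informative, extra])
    intro_idx = rng.choice(informative, size=P.n_adaptive_introgressed, replace=False)
    remaining = np.setdiff1d(np.arange(P.n_loci), intro_idx)
    # background variants emulate standing variation: low parental divergence
    low_div = remaining[np.abs(f2[remaining] - f1[remaining]) <= P.max_delta_background]
    pool_bg = low_div if low_div.size >= P.n_adaptive_background else remaining
    bg_idx = rng.choice(pool_bg, size=P.n_adaptive_background, replace=False)

    locus_class = pd.Series("neutral", index=loci, name="class")
    target = pd.Series("", index=loci, name="target_gradient")
    freeze_names = [n for n, c, _ in P.env_gradients if c == "freeze"]
    water_names = [n for n, c, _ in P.env_gradients if c == "water"]
    for r, j in enumerate(intro_idx):
        locus_class.iloc[j] = "adaptive_introgressed"
        target.iloc[j] = freeze_names[r % len(freeze_names)]
    for r, j in enumerate(bg_idx):
        locus_class.iloc[j] = "adaptive_background"
        target.iloc[j] = water_names[r % len(water_names)]

    # --- trees and their realized ancestries -------------------------------
    # Trees within a hybrid population vary in genome-wide ancestry around
    # the population's cline value (the within-population spread visible in
    # admixture plots of real hybrid zones); this is also what generates
    # within-population mixture LD at ancestry-informative locus pairs.
    q_arr = q.to_numpy()
    sizes = []
    for p in all_pops:
        if pop_group[p] == "HYB":
            sizes.append(int(rng.integers(P.trees_per_pop[0], P.trees_per_pop[1] + 1)))
        else:
            sizes.append(P.parental_trees_per_pop)
    ind_ids, ind_pop_idx = [], []
    for i, (p, s) in enumerate(zip(all_pops, sizes)):
        for t in range(s):
            ind_ids.append(f"{p}_t{t + 1}")
            ind_pop_idx.append(i)
    ind_pop_idx = np.asarray(ind_pop_idx)
    n_ind = len(ind_ids)

    is_hyb_tree = ind_pop_idx < P.n_hyb_pops
    q_pop_tree = q_arr[ind_pop_idx]
    logit_qt = logit(np.clip(q_pop_tree, 1e-6, 1 - 1e-6))
    if P.tree_ancestry_sd > 0:
        logit_qt = logit_qt + np.where(
            is_hyb_tree, rng.normal(0.0, P.tree_ancestry_sd, n_ind), 0.0
        )
    q_tree = np.where(is_hyb_tree, expit(logit_qt), q_pop_tree)

    # --- per-tree allele probabilities -------------------------------------
    pf = q_tree[:, None] * f2[None, :] + (1 - q_tree[:, None]) * f1[None, :]
    # adaptive introgressed: tree-level ancestry weight pushed toward P2
    # where the target freeze gradient is high (hybrid trees only)
    for j in intro_idx:
        z = z_by_gradient[target.iloc[j]]
        q_eff = expit(logit_qt + P.s_intro * z[np.clip(ind_pop_idx, 0, P.n_hyb_pops - 1)])
        pf[:, j] = np.where(
            is_hyb_tree, q_eff * f2[j] + (1 - q_eff) * f1[j], pf[:, j]
        )
    # adaptive background: direct frequency response to the water gradient
    for j in bg_idx:
        z = z_by_gradient[target.iloc[j]]
        pf[:, j] = pf[:, j] + np.where(
            is_hyb_tree, P.s_bg * z[np.clip(ind_pop_idx, 0, P.n_hyb_pops - 1)], 0.0
        )
    if P.drift_sd > 0:
        drift = rng.normal(0.0, P.drift_sd, size=(len(all_pops), P.n_loci))
        pf = pf + drift[ind_pop_idx]  # shared within a population
    pf = np.clip(pf, 0.0, 1.0)

    g1 = (rng.random((n_ind, P.n_loci)) < pf).astype(np.int16)
    g2 = (rng.random((n_ind, P.n_loci)) < pf).astype(np.int16)
    values = g1 + g2
    if P.missing_rate > 0:
        miss = rng.random((n_ind, P.n_loci)) < P.missing_rate
        values[miss] = MISSING

    G = GenotypeMatrix(values, ind_ids, loci)
    pmap = PopulationMap(dict(zip(ind_ids, [all_pops[i] for i in ind_pop_idx])),
                         pop_group, pop_coords)
    truth = TruthTable(locus_class, target, q,
                       pd.Series(q_tree, index=ind_ids, name="tree_ancestry"))
    if return_haplotypes:
        hap = np.empty((2 * n_ind, P.n_loci), dtype=np.int16)
        hap[0::2], hap[1::2] = g1, g2
        return G, pmap, env, truth, hap
    return G, pmap, env, truth
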