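"""Hybrid index and per-SNP genomic clines.

The hybrid index h of a tree is the maximum-likelihood proportion of its
genome derived from the donor parental species (P2), estimated from loci
whose parental allele-frequency difference exceeds ``delta_min`` under a
binomial mixture: P(counted allele) = h f_P2 + (1 - h) f_P1.

Per locus, genotype classes (0/1/2 copies of the P2-like allele) are
modelled as a multinomial logistic function of h with linear and
quadratic terms, anchored to the neutral expectation: the class log-odds
carry the neutral h-mixture probabilities as offsets, so the neutral
model is exactly the point where all regression coefficients vanish and
the likelihood-ratio statistic is chi-square with df = number of free
coefficients. Loci missing a genotype class entirely collapse to a
binomial (allele-count) logistic regression, flagged.

SNPs are called significantly introgressed in the P2 direction when the
LRT passes a Bonferroni family threshold and the fitted P2-homozygote
probability exceeds the upper envelope of neutral simulations in at
least a fraction ``tree_frac`` of the trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .core import MISSING, GenotypeMatrix, PopulationMap, logger

FREQ_CLIP = 1e-3  # parental frequency shrinkage away from fixation


@dataclass
class ClineFits:
    """Batched genomic-cline fits over loci."""

    table: pd.DataFrame  # locus, lrt, df, p, collapsed
    phi: np.ndarray      # loci x trees fitted P2-homozygote probability
    phi0: np.ndarray     # loci x trees neutral-mixture P2-homozygote probability
    h: np.ndarray        # hybrid index per tree (fit order)
    individuals: list[str]


@dataclass
class IntrogressionCalls:
    loci: list[str]
    tree_support: pd.Series  # per called locus: fraction of trees above envelope
    alpha_family: float
    envelope_level: float
    tree_frac: float
    n_tested: int

    @property
    def Spf(self) -> int:
        return len(self.loci)


def parental_freqs(
    G: GenotypeMatrix, pmap: PopulationMap, clip: float = FREQ_CLIP
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled counted-allele frequency per locus in each parental group.

    Frequencies are shrunk into [clip, 1 - clip] so that no genotype is
    assigned zero likelihood downstream.
    """
    out = []
    for g in ("P1", "P2"):
        rows = pmap.row_indices(G, pmap.individuals_of_groups([g]))
        vals = G.values[rows]
        obs = vals != MISSING
        n = 2 * obs.sum(axis=0)
        c = np.where(obs, vals, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, c / np.maximum(n, 1), np.nan)
        out.append(np.clip(f, clip, 1.0 - clip))
    return out[0], out[1]


def hybrid_index(
    G: GenotypeMatrix,
    pmap: PopulationMap,
    delta_min: float = 0.1,
    min_informative: int = 50,
    individuals: list[str] | None = None,
) -> pd.DataFrame:
    """Maximum-likelihood hybrid index per individual.

    Loci with parental frequency difference below ``delta_min`` are
    excluded; individuals with fewer than ``min_informative`` non-missing
    informative loci are flagged low-confidence. h is found by bounded
    scalar optimisation to 1e-6.
    """
    f1, f2 = parental_freqs(G, pmap)
    informative = np.flatnonzero(
        np.isfinite(f1) & np.isfinite(f2) & (np.abs(f2 - f1) >= delta_min)
    )
    if informative.size == 0:
        raise ValueError("no informative loci for the hybrid index")
    inds = individuals if individuals is not None else G.individual_ids
    rows = pmap.row_indices(G, inds)
    V = G.values[np.ix_(rows, informative)]
    f1i, f2i = f1[informative], f2[informative]

    recs = []
    for r, ind in enumerate(inds):
        g = V[r]
        obs = g != MISSING
        n_inf = int(obs.sum())
        if n_inf == 0:
            recs.append((ind, np.nan, 0, True))
            continue
        go, f1o, f2o = g[obs].astype(float), f1i[obs], f2i[obs]

        def negll(h):
            pi = np.clip(h * f2o + (1.0 - h) * f1o, 1e-9, 1 - 1e-9)
            return -np.sum(
                go * np.log(pi) + (2.0 - go) * np.log1p(-pi)
            )

        res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        recs.append((ind, float(res.x), n_inf, n_inf < min_informative))
    df = pd.DataFrame(recs, columns=["individual", "h", "n_informative", "low_confidence"])
    if df["low_confidence"].any():
        logger.info("hybrid_index: %d individuals flagged low-confidence",
                    int(df["low_confidence"].sum()))
    return df


# ---------------------------------------------------------------------------
# Batched cline fitting
# ---------------------------------------------------------------------------


def _neutral_class_probs(h: np.ndarray, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Neutral h-mixture genotype-class probabilities, shape (L, n, 3)."""
    pi = h[None, :] * f2[:, None] + (1.0 - h[None, :]) * f1[:, None]
    pi = np.clip(pi, 1e-9, 1.0 - 1e-9)
    return np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=-1)


def _fit_multinomial_batch(
    Y: np.ndarray, W: np.ndarray, offsets: np.ndarray, X: np.ndarray,
    max_iter: int = 60, tol: float = 1e-9, ridge: float = 1e-8,
):
    """Newton fit of the offset-anchored multinomial model for many loci.

    Y: (L, n) genotype class in {0,1,2}; W: (L, n) observation weights;
    offsets: (L, n, 3) log neutral class probabilities; X: (n, k) feature
    rows [1, h, h^2]. Six free parameters per locus (k per non-reference
    class). Returns (loglik at MLE, loglik at null, fitted class
    probabilities (L, n, 3)).
    """
    L, n = Y.shape
    k = X.shape[1]
    npar = 2 * k
    theta = np.zeros((L, npar))
    Yc = np.stack([(Y == c) & (W > 0) for c in range(3)], axis=-1).astype(float)

    def probs_ll(th, off, yc):
        eta = off.copy()
        eta[..., 1] += th[:, :k] @ X.T
        eta[..., 2] += th[:, k:] @ X.T
        eta -= eta.max(axis=-1, keepdims=True)
        ex = np.exp(eta)
        P = ex / ex.sum(axis=-1, keepdims=True)
        ll = (yc * np.log(np.clip(P, 1e-300, None))).sum(axis=(1, 2))
        return P, ll - 0.5 * ridge * (th**2).sum(axis=1)

    P, ll = probs_ll(theta, offsets, Yc)
    ll_null = ll.copy()
    active = np.arange(L)
    for _ in range(max_iter):
        if not active.size:
            break
        a = active
        Pa, tha, Wa, Ya = P[a], theta[a], W[a], Yc[a]
        resid = Ya[..., 1:] - Pa[..., 1:] * Wa[..., None]  # (A, n, 2)
        grad = np.einsum("lnc,nk->lck", resid, X).reshape(a.size, npar)
        grad -= ridge * tha
        Wp = Pa[..., 1:] * Wa[..., None]
        H = np.empty((a.size, npar, npar))
        for c in range(2):
            for d in range(2):
                wcd = (1.0 if c == d else 0.0) * Wp[..., c] \
                    - Wp[..., c] * Pa[..., 1 + d] * Wa
                H[:, c * k:(c + 1) * k, d * k:(d + 1) * k] = np.einsum(
                    "ln,nk,nm->lkm", wcd, X, X
                )
        H += ridge * np.eye(npar)
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-6 * np.eye(npar), grad[..., None])[..., 0]
        norms = np.linalg.norm(step, axis=1, keepdims=True)
        step = step * np.minimum(1.0, 5.0 / np.maximum(norms, 1e-12))
        offa, lla = offsets[a], ll[a]
        new = tha + step
        Pn, lln = probs_ll(new, offa, Ya)
        worse = lln < lla - 1e-12
        halvings = 0
        while worse.any() and halvings < 12:
            step[worse] *= 0.5
            new = tha + step
            Pn, lln = probs_ll(new, offa, Ya)
            worse = lln < lla - 1e-12
            halvings += 1
        improved = lln >= lla
        theta[a] = np.where(improved[:, None], new, tha)
        P[a] = np.where(improved[:, None, None], Pn, Pa)
        delta = np.where(improved, lln - lla, 0.0)
        ll[a] = np.where(improved, lln, lla)
        active = a[delta >= tol]
    return ll, ll_null, P


def _fit_binomial_batch(
    Y: np.ndarray, W: np.ndarray, pi0: np.ndarray, X: np.ndarray,
    max_iter: int = 60, tol: float = 1e-9, ridge: float = 1e-8,
):
    """Allele-count logistic fit with logit(pi0) offset; k free parameters."""
    L, n = Y.shape
    k = X.shape[1]
    off = np.log(pi0) - np.log1p(-pi0)
    theta = np.zeros((L, k))
    Yw = np.where(W > 0, Y, 0).astype(float)

    def ll_of(th):
        eta = off + th @ X.T
        pi = 1.0 / (1.0 + np.exp(-eta))
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        ll = (W * (Yw * np.log(pi) + (2 - Yw) * np.log1p(-pi))).sum(axis=1)
        return pi, ll - 0.5 * ridge * (th**2).sum(axis=1)

    pi, ll = ll_of(theta)
    ll_null = ll.copy()
    for _ in range(max_iter):
        grad = np.einsum("ln,nk->lk", W * (Yw - 2 * pi), X) - ridge * theta
        wvar = W * 2 * pi * (1 - pi)
        H = np.einsum("ln,nk,nm->lkm", wvar, X, X) + ridge * np.eye(k)
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        norms = np.linalg.norm(step, axis=1, keepdims=True)
        step = step * np.minimum(1.0, 5.0 / np.maximum(norms, 1e-12))
        new = theta + step
        pin, lln = ll_of(new)
        worse = lln < ll - 1e-12
        halvings = 0
        while worse.any() and halvings < 12:
            step[worse] *= 0.5
            new = theta + step
            pin, lln = ll_of(new)
            worse = lln < ll - 1e-12
            halvings += 1
        improved = lln >= ll
        theta = np.where(improved[:, None], new, theta)
        pi = np.where(improved[:, None], pin, pi)
        delta = np.where(improved, lln - ll, 0.0)
        ll = np.where(improved, lln, ll)
        if delta.max(initial=0.0) < tol:
            break
    return ll, ll_null, pi


def fit_genomic_clines(
    G: GenotypeMatrix,
    h: pd.DataFrame | np.ndarray,
    f1: np.ndarray,
    f2: np.ndarray,
    individuals: list[str] | None = None,
    loci: list[str] | None = None,
) -> ClineFits:
    """Fit the offset-anchored genomic-cline model at every locus.

    ``h`` is either the frame from :func:`hybrid_index` or an array
    aligned to ``individuals``. Genotypes are oriented to count the
    P2-like allele (the allele more frequent in the donor species) so the
    fitted phi is the P2-homozygote probability. Loci with an entirely
    absent genotype class use the binomial collapse (flagged).
    """
    if isinstance(h, pd.DataFrame):
        if individuals is None:
            individuals = list(h["individual"])
        hvec = h.set_index("individual")["h"].loc[individuals].to_numpy()
    else:
        hvec = np.asarray(h, dtype=float)
        if individuals is None:
            individuals = list(G.individual_ids)
    if np.ptp(hvec[np.isfinite(hvec)]) == 0:
        raise ValueError("hybrid index is constant across trees: cline undefined")
    loci = loci if loci is not None else list(G.locus_ids)
    cols = G.locus_index(loci)
    pos = {s: i for i, s in enumerate(G.individual_ids)}
    rows = np.array([pos[s] for s in individuals])
    V = G.values[np.ix_(rows, cols)].T  # (L, n)
    f1v, f2v = f1[cols], f2[cols]

    # orient to the P2-like allele
    flip = f2v < f1v
    Vo = np.where(V == MISSING, MISSING, np.where(flip[:, None], 2 - V, V))
    a1 = np.where(flip, 1.0 - f1v, f1v)
    a2 = np.where(flip, 1.0 - f2v, f2v)

    W = (Vo != MISSING).astype(float)
    ok_h = np.isfinite(hvec)
    W = W * ok_h[None, :]
    Y = np.where(Vo == MISSING, 0, Vo)

    X = np.column_stack([np.ones_like(hvec), np.nan_to_num(hvec),
                         np.nan_to_num(hvec) ** 2])
    classes_present = np.stack(
        [((Y == c) & (W > 0)).any(axis=1) for c in range(3)], axis=1
    )
    collapsed = ~classes_present.all(axis=1)
    L, n = Y.shape
    lrt = np.full(L, np.nan)
    dfv = np.full(L, 0)
    phi = np.full((L, n), np.nan)
    phi0 = np.full((L, n), np.nan)

    multi = np.flatnonzero(~collapsed)
    if multi.size:
        P0 = _neutral_class_probs(hvec, a1[multi], a2[multi])
        ll, ll0, P = _fit_multinomial_batch(
            Y[multi], W[multi], np.log(P0), X
        )
        lrt[multi] = 2.0 * (ll - ll0)
        dfv[multi] = 2 * X.shape[1]
        phi[multi] = P[..., 2]
        phi0[multi] = P0[..., 2]
    binom = np.flatnonzero(collapsed)
    if binom.size:
        logger.info("fit_genomic_clines: %d loci collapsed to binomial fits",
                    binom.size)
        pi0 = np.clip(
            hvec[None, :] * a2[binom, None] + (1 - hvec[None, :]) * a1[binom, None],
            1e-9, 1 - 1e-9,
        )
        ll, ll0, pi = _fit_binomial_batch(Y[binom], W[binom], pi0, X)
        lrt[binom] = 2.0 * (ll - ll0)
        dfv[binom] = X.shape[1]
        phi[binom] = pi**2  # implied P2-homozygote probability under HWE
        phi0[binom] = pi0**2
    lrt = np.maximum(lrt, 0.0)
    p = chi2.sf(lrt, dfv)
    table = pd.DataFrame(
        {"locus": loci, "lrt": lrt, "df": dfv, "p": p, "collapsed": collapsed}
    )
    phi[:, ~ok_h] = np.nan
    phi0[:, ~ok_h] = np.nan
    return ClineFits(table, phi, phi0, hvec, list(individuals))


def neutral_cline_envelope(
    h: np.ndarray,
    parental_pairs: np.ndarray,
    n_sim: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    scale: str = "excess",
) -> np.ndarray:
    """Per-tree upper envelope of the neutral fitted P2-homozygote signal.

    ``parental_pairs`` is an (m, 2) array of observed (f_P1, f_P2)
    P2-like-allele frequency pairs; each simulated locus resamples one
    pair, draws genotypes from the h-mixture binomial, and is fitted with
    the same cline model. The envelope is the per-tree ``(1 + level)/2``
    quantile over simulations (``level=1`` gives the maximum).

    With ``scale="excess"`` (default) the envelope is on the scale of the
    fitted probability minus the simulated locus's own neutral-mixture
    curve, which makes exceedance comparable across loci with different
    parental frequencies; ``scale="phi"`` gives the raw fitted
    probability envelope.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if scale not in ("excess", "phi"):
        raise ValueError("scale must be 'excess' or 'phi'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = np.asarray(h, dtype=float)
    pick = rng.integers(parental_pairs.shape[0], size=n_sim)
    a1 = np.clip(parental_pairs[pick, 0], FREQ_CLIP, 1 - FREQ_CLIP)
    a2 = np.clip(parental_pairs[pick, 1], FREQ_CLIP, 1 - FREQ_CLIP)
    pi = h[None, :] * a2[:, None] + (1 - h[None, :]) * a1[:, None]
    Y = rng.binomial(2, np.clip(pi, 0, 1))
    W = np.ones_like(Y, dtype=float)
    X = np.column_stack([np.ones_like(h), h, h**2])
    P0 = _neutral_class_probs(h, a1, a2)
    _, _, P = _fit_multinomial_batch(Y, W, np.log(P0), X)
    sims = P[..., 2] - P0[..., 2] if scale == "excess" else P[..., 2]
    q = 0.5 * (1.0 + level)
    return np.quantile(sims, q, axis=0)


def call_introgressed_snps(
    fits: ClineFits,
    envelope: np.ndarray,
    alpha_family: float = 0.05,
    tree_frac: float = 0.20,
    envelope_level: float = 0.95,
    scale: str = "excess",
) -> IntrogressionCalls:
    """Bonferroni + envelope-support calls of P2-direction introgression.

    A locus is called when (i) its LRT p-value is below
    ``alpha_family / n_tested`` and (ii) the fitted P2-homozygote signal
    (on the same scale as the envelope: excess over the locus's own
    neutral curve by default) lies above the neutral envelope for at
    least ``tree_frac`` of the trees with data. Calls are monotone
    non-increasing in both thresholds.
    """
    S = len(fits.table)
    thr = alpha_family / S
    have = np.isfinite(fits.phi)
    signal = fits.phi - fits.phi0 if scale == "excess" else fits.phi
    above = (signal > envelope[None, :]) & have
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(
            have.sum(axis=1) > 0, above.sum(axis=1) / np.maximum(have.sum(axis=1), 1), 0.0
        )
    called = (fits.table["p"].to_numpy() < thr) & (support >= tree_frac)
    loci = [l for l, c in zip(fits.table["locus"], called) if c]
    sup = pd.Series(support[called], index=loci, name="tree_support")
    return IntrogressionCalls(
        loci, sup, alpha_family, envelope_level, tree_frac, S
    )
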