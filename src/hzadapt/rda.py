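"""Redundancy analysis (RDA) on Hellinger-transformed frequencies.

The response is the population x locus allele-frequency table, row-wise
Hellinger-transformed (square root of relative abundance) so that
Euclidean ordination is appropriate. Predictor blocks are: leading
principal components of the scaled environmental gradients, a polynomial
trend surface of (lat, lon, elev), mean per-population ancestry, and the
first eigenvector of the population covariance matrix (population
structure). Collinear predictors are pruned by variance inflation
factor. Model R^2 is the constrained fraction of total variance,
adjusted as 1 - (1 - R2)(n - 1)/(n - m - 1); significance uses row
permutations (residuals of the reduced model when conditioning).
Variance partitioning over the four predictor blocks solves the
inclusion–exclusion system for all 15 regions of the Venn diagram on
adjusted R^2, the standard varpart construction (negative components are
reported as-is).

Permutation statistics are computed through the response Gram matrix:
for a projection P and row-permuted response, the constrained sum of
squares is trace(P C_perm) with C the response Gram matrix, so each
permutation costs O(n_pops^2) regardless of the number of loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EnvTable, FreqTable, PopulationMap, logger


@dataclass
class RDAResult:
    r2: float
    r2_adj: float
    pseudo_f: float
    p: float
    n: int
    m: int  # constrained predictors (rank)
    n_condition: int
    n_perm: int


@dataclass
class PredictorSet:
    env: pd.DataFrame
    geo: pd.DataFrame
    ancestry: pd.DataFrame
    structure: pd.DataFrame

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {
            "env": self.env, "geo": self.geo,
            "ancestry": self.ancestry, "structure": self.structure,
        }


# ---------------------------------------------------------------------------


def hellinger_transform(F: FreqTable, populations: list[str] | None = None) -> pd.DataFrame:
    """Row-wise Hellinger transform of the frequency table.

    Undefined cells (no data) are mean-imputed per locus beforehand
    (count logged); a population whose frequencies sum to zero is
    rejected by name. Every output row has unit sum of squares.
    """
    pops = populations if populations is not None else F.populations
    idx = [F.populations.index(p) for p in pops]
    f = F.freq[idx].copy()
    n_missing = int(np.isnan(f).sum())
    if n_missing:
        col_mean = np.nanmean(f, axis=0)
        fill = np.broadcast_to(col_mean, f.shape)
        f = np.where(np.isnan(f), fill, f)
        logger.info("hellinger_transform: %d undefined cells mean-imputed", n_missing)
    rowsum = f.sum(axis=1)
    zero = rowsum <= 0
    if zero.any():
        raise ValueError(
            f"population(s) with all-zero frequencies: {[pops[i] for i in np.flatnonzero(zero)]}"
        )
    Y = np.sqrt(f / rowsum[:, None])
    return pd.DataFrame(Y, index=pops, columns=F.locus_ids)


def _scale(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    s = X.std(axis=0)
    s[s == 0] = 1.0
    return X / s


def build_predictors(
    env: EnvTable,
    pmap: PopulationMap,
    ancestry: pd.Series,
    omega: np.ndarray,
    populations: list[str],
    var_target: float = 0.90,
    geo_degree: int = 2,
) -> PredictorSet:
    """Assemble the four predictor blocks over the given populations.

    Environmental PCs are the minimal set of leading axes of the scaled
    gradient matrix reaching ``var_target`` cumulative variance
    (duplicate gradients dropped first). Geography is a centred/scaled
    polynomial expansion of (lat, lon, elev) up to ``geo_degree``
    (default quadratic trend surface). Ancestry and structure are single
    columns; ``omega`` must be ordered like ``populations``.
    """
    E = env.values.loc[populations]
    dup = E.T.duplicated()
    if dup.any():
        logger.info("build_predictors: dropping duplicate gradients %s",
                    list(E.columns[dup]))
        E = E.loc[:, ~dup]
    Es = _scale(E.to_numpy(dtype=float))
    U, s, Vt = np.linalg.svd(Es, full_matrices=False)
    var = s**2
    var = var / var.sum()
    k = int(np.searchsorted(np.cumsum(var), var_target) + 1)
    k = min(k, len(s))
    pcs = U[:, :k] * s[:k]
    env_df = pd.DataFrame(pcs, index=populations,
                          columns=[f"envPC{i + 1}" for i in range(k)])

    coords = np.array([pmap.pop_coords[p] for p in populations], dtype=float)
    base = _scale(coords)
    cols, names = [], []
    axes = ["lat", "lon", "elev"]
    for d in range(1, geo_degree + 1):
        for combo in itertools.combinations_with_replacement(range(3), d):
            term = np.prod(base[:, combo], axis=1)
            cols.append(term)
            names.append("*".join(axes[c] for c in combo))
    geo_df = pd.DataFrame(_scale(np.column_stack(cols)), index=populations, columns=names)

    anc = ancestry.loc[populations].to_numpy(dtype=float)
    anc_df = pd.DataFrame(
        {"ancestry": anc - anc.mean()}, index=populations
    )
    w, V = np.linalg.eigh(omega)
    ev1 = V[:, -1]
    ev1 = ev1 if ev1[np.argmax(np.abs(ev1))] >= 0 else -ev1  # sign convention
    str_df = pd.DataFrame({"structPC1": ev1 - ev1.mean()}, index=populations)
    for name, df in (("env", env_df), ("geo", geo_df), ("ancestry", anc_df),
                     ("structure", str_df)):
        if (df.std(axis=0) == 0).any():
            raise ValueError(f"constant column in predictor block {name!r}")
    return PredictorSet(env_df, geo_df, anc_df, str_df)


def vif_prune(X: pd.DataFrame, threshold: float = 10.0) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the highest-VIF column until all VIF <= threshold."""
    if X.shape[1] < 2:
        return X, []
    X = X.copy()
    dropped: list[str] = []
    while X.shape[1] >= 2:
        vifs = {}
        M = _scale(X.to_numpy(dtype=float))
        for j, c in enumerate(X.columns):
            y = M[:, j]
            others = np.delete(M, j, axis=1)
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(y)), others]), y, rcond=None
            )
            resid = y - np.column_stack([np.ones(len(y)), others]) @ beta
            r2 = 1.0 - resid @ resid / (y @ y)
            vifs[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=vifs.get)
        if vifs[worst] <= threshold:
            break
        X = X.drop(columns=[worst])
        dropped.append(worst)
        logger.info("vif_prune: dropped %s (VIF %.3g)", worst, vifs[worst])
    return X, dropped


# ---------------------------------------------------------------------------


def _proj(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of X (rank-safe)."""
    if X.size == 0:
        return np.zeros((X.shape[0], X.shape[0]))
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    keep = diag > 1e-10 * max(1.0, diag.max())
    Q = Q[:, keep]
    return Q @ Q.T


def _rank(X: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(X)) if X.size else 0


def rda_fit(
    Y,
    X,
    Z=None,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> RDAResult:
    """Constrained ordination R^2 of Y on X (optionally partialling out Z).

    Y is populations x loci (DataFrame or array); X and Z predictor
    matrices aligned to the same rows. With Z, both Y and X are
    residualised on Z first and permutations shuffle the reduced-model
    residual rows; without Z, permutations shuffle the (centred) response
    rows freely. ``n_perm=0`` skips the test (p = NaN).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Ym = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    n = Ym.shape[0]
    Zm = None
    if Z is not None:
        Zm = Z.to_numpy(dtype=float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, float)
        if Zm.ndim == 1:
            Zm = Zm[:, None]
    q = _rank(Zm - Zm.mean(axis=0)) if Zm is not None else 0

    Yc = Ym - Ym.mean(axis=0)
    Xc = Xm - Xm.mean(axis=0)
    if Zm is not None:
        Pz = _proj(Zm - Zm.mean(axis=0))
        Yr = Yc - Pz @ Yc
        Xr = Xc - Pz @ Xc
    else:
        Yr, Xr = Yc, Xc
    m = _rank(Xr)
    if m == 0:
        if Zm is not None:
            # X entirely inside the conditioned space: nothing left to explain
            return RDAResult(0.0, 0.0, 0.0, float("nan"), n, 0, q, 0)
        raise ValueError("predictor matrix has rank 0")
    if n <= m + q + 1:
        raise ValueError("too few rows for the requested model")
    Px = _proj(Xr)
    C = Yr @ Yr.T
    ss_tot = float(np.trace(C))
    if ss_tot <= 0:
        raise ValueError("response has zero variance")
    ss_fit = float(np.sum(Px * C))
    r2 = ss_fit / ss_tot
    df_resid = n - m - q - 1
    pseudo_f = (
        float("inf") if r2 >= 1.0 - 1e-14 else (r2 / m) / ((1.0 - r2) / df_resid)
    )
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid

    p = float("nan")
    if n_perm > 0:
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r2_perm = float(np.sum(Px * C[np.ix_(perm, perm)])) / ss_tot
            if r2_perm >= r2:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
    return RDAResult(float(r2), float(r2_adj), float(pseudo_f), p, n, m, q, n_perm)


def variance_partition4(Y, predictors: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Adjusted-R^2 partitioning over all 15 regions of four predictor sets.

    For every non-empty subset S the union value u(S) = R2_adj of the
    concatenated predictors is computed; the exclusive region values c_T
    solve u(S) = sum over T intersecting S of c_T. Components may come
    out negative (flagged); their sum equals the full-model adjusted R^2
    exactly.
    """
    names = list(predictors)
    if len(names) != 4:
        raise ValueError("exactly four predictor matrices are required")
    subsets = [
        frozenset(c)
        for r in range(1, 5)
        for c in itertools.combinations(names, r)
    ]
    u = {}
    for S in subsets:
        X = pd.concat([predictors[k] for k in names if k in S], axis=1)
        u[S] = rda_fit(Y, X, n_perm=0).r2_adj
    A = np.array(
        [[1.0 if T & S else 0.0 for T in subsets] for S in subsets]
    )
    b = np.array([u[S] for S in subsets])
    c = np.linalg.solve(A, b)
    rows = []
    for T, val in zip(subsets, c):
        rows.append(("&".join(sorted(T)), len(T), val, val < 0))
    df = pd.DataFrame(rows, columns=["region", "order", "adj_r2", "negative"])
    if df["negative"].any():
        logger.info("variance_partition4: %d negative components retained",
                    int(df["negative"].sum()))
    total = float(df["adj_r2"].sum())
    full = u[frozenset(names)]
    assert abs(total - full) < 1e-8, "inclusion-exclusion identity violated"
    df.attrs["total_explained"] = full
    return df


def interaction_model_test(
    Y,
    env: pd.DataFrame,
    ancestry: pd.DataFrame,
    condition: list[pd.DataFrame] | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Compare env+ancestry against env+ancestry+interaction by permutation.

    Model 2 has the joint effects, Model 1 adds the columnwise products
    env_j x ancestry. The added terms are tested with a Freedman–Lane
    permutation F-test under the reduced model (both models conditioned
    on ``condition``). Returns both adjusted R^2 values, the F statistic
    and the permutation p-value.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Ym = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    n = Ym.shape[0]
    anc = ancestry.to_numpy(dtype=float).reshape(n, -1)
    inter = env.to_numpy(dtype=float) * anc  # broadcast over env columns
    inter_df = pd.DataFrame(
        inter, index=env.index, columns=[f"{c}:anc" for c in env.columns]
    )
    X2 = pd.concat([env, ancestry], axis=1)
    X1 = pd.concat([X2, inter_df], axis=1)
    Z = pd.concat(condition, axis=1) if condition else None

    fit1 = rda_fit(Y, X1, Z, n_perm=0)
    fit2 = rda_fit(Y, X2, Z, n_perm=0)

    Yc = Ym - Ym.mean(axis=0)
    def design(X):
        M = X.to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        if Z is not None:
            Zc = Z.to_numpy(dtype=float)
            Zc = Zc - Zc.mean(axis=0)
            return np.column_stack([Zc, M])
        return M
    P1 = _proj(design(X1))
    P2 = _proj(design(X2))
    m1 = _rank(design(X1))
    m2 = _rank(design(X2))
    df_added = m1 - m2
    if df_added == 0:
        raise ValueError("interaction terms are collinear with the joint model")
    df_resid = n - m1 - 1
    R2resid = Yc - P2 @ Yc  # reduced-model residuals
    Cr = R2resid @ R2resid.T

    def f_stat(C):
        rss1 = float(np.sum((np.eye(n) - P1) * C))
        rss2 = float(np.sum((np.eye(n) - P2) * C))
        return ((rss2 - rss1) / df_added) / (rss1 / df_resid)

    f_obs = f_stat(Cr)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if f_stat(Cr[np.ix_(perm, perm)]) >= f_obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return {
        "r2_adj_model1": fit1.r2_adj,
        "r2_adj_model2": fit2.r2_adj,
        "r2_model1": fit1.r2,
        "r2_model2": fit2.r2,
        "f_added": float(f_obs),
        "df_added": int(df_added),
        "p_added": float(p),
        "n_perm": n_perm,
    }
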