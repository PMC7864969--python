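"""Multiple matrix regression with randomization (MMRR) and its partition.

Pairwise distance/response matrices are vectorised over the strict lower
triangle and regressed by OLS. Three models — full (environment +
geography), environment-only and geography-only — yield the variance
decomposition used for the LD components:

    R2_pureEnv    = R2_full - R2_geoOnly
    R2_pureGeo    = R2_full - R2_envOnly
    R2_confounded = R2_full - R2_pureEnv - R2_pureGeo

Significance is assessed by Mantel-style simultaneous row/column
permutation of the response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MMRRResult:
    r2_full: float
    r2_env_only: float
    r2_geo_only: float
    r2_pure_env: float
    r2_pure_geo: float
    r2_confounded: float
    coefficients: dict
    p_full: float
    p_env_only: float
    p_geo_only: float
    n_perm: int


def _as_matrix(M) -> np.ndarray:
    return M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, float)


def _vec(M: np.ndarray, tri: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    return M[tri]


def _r2(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    Xc = np.column_stack([np.ones(y.size), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - float(np.sum(resid**2) / ss_tot), beta


def mmrr_partition(
    D_resp, D_env, D_geo, n_perm: int = 999, seed: int | np.random.Generator = 0
) -> MMRRResult:
    """Partition a response distance matrix on environment and geography.

    Matrices must be square and conformable (same population order). NaN
    response entries are dropped pairwise. The permutation p-value for
    each model is (1 + #{R2_perm >= R2_obs}) / (n_perm + 1) under joint
    row/column permutation of the response matrix.
    """
    R, E, Gg = map(_as_matrix, (D_resp, D_env, D_geo))
    n = R.shape[0]
    if not (R.shape == E.shape == Gg.shape == (n, n)):
        raise ValueError("matrices are not conformable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tri = np.tril_indices(n, k=-1)

    def standardize(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else v - v.mean()

    def fit(Rm):
        keep = np.isfinite(Rm[tri])
        y = Rm[tri][keep]
        if y.size < 3 or np.ptp(y) == 0:
            raise ValueError("constant or empty response matrix: R^2 undefined")
        y = standardize(y)
        e = standardize(E[tri][keep])
        g = standardize(Gg[tri][keep])
        r2_full, beta = _r2(y, np.column_stack([e, g]))
        r2_env, _ = _r2(y, e[:, None])
        r2_geo, _ = _r2(y, g[:, None])
        return r2_full, r2_env, r2_geo, beta

    r2_full, r2_env, r2_geo, beta = fit(R)
    counts = np.zeros(3)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Rp = R[np.ix_(perm, perm)]
        pf, pe, pg, _ = fit(Rp)
        counts += [pf >= r2_full, pe >= r2_env, pg >= r2_geo]
    p_full, p_env, p_geo = (1.0 + counts) / (n_perm + 1.0)

    pure_env = r2_full - r2_geo
    pure_geo = r2_full - r2_env
    return MMRRResult(
        r2_full, r2_env, r2_geo,
        pure_env, pure_geo, r2_full - pure_env - pure_geo,
        {"intercept": beta[0], "env": beta[1], "geo": beta[2]},
        float(p_full), float(p_env), float(p_geo), n_perm,
    )


def env_distance_matrix(env, gradient: str, populations: list[str]) -> pd.DataFrame:
    """Pairwise absolute differences along one environmental gradient."""
    v = env.vector(gradient, populations)
    D = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(D, index=populations, columns=populations)
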