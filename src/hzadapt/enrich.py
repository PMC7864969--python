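"""Fold enrichment of outlier SNP sets in the introgressed SNP set.

For an environmental gradient with B association outliers, of which Bpf
are also significantly introgressed from the donor species, against Spf
introgressed SNPs among S tested:

    FE = (Bpf / B) / (Spf / S)

FE > 1 means the gradient's outliers carry donor ancestry more often
than a random SNP — the signature of adaptive introgression along that
gradient. Significance comes from a permutation null that redraws B loci
uniformly without replacement from the tested universe (the null count
Bpf is then hypergeometric), with empirical 95th/99th percentile
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .clines import IntrogressionCalls
from .core import EnvTable, logger
from .gea import OutlierSet


@dataclass
class EnrichmentResult:
    gradient: str
    B: int
    Bpf: int
    Spf: int
    S: int
    fe: float
    p: float = float("nan")
    pct95: float = float("nan")
    pct99: float = float("nan")
    exceed_95: bool = False
    exceed_99: bool = False
    n_perm: int = 0


def fold_enrichment(
    outlier: OutlierSet, calls: IntrogressionCalls, universe: list[str]
) -> EnrichmentResult:
    """FE for one outlier set, computed with exact rational arithmetic."""
    uni = set(universe)
    if not set(outlier.loci) <= uni:
        raise ValueError("outlier loci outside the tested universe")
    B = outlier.B
    intro = set(calls.loci)
    Spf = len(intro & uni)
    S = len(uni)
    if B == 0 or Spf == 0:
        raise ValueError("FE undefined: empty outlier set or no introgressed SNPs")
    Bpf = len(set(outlier.loci) & intro)
    fe = Fraction(Bpf, B) / Fraction(Spf, S)
    return EnrichmentResult(outlier.gradient, B, Bpf, Spf, S, float(fe))


def permutation_null_fe(
    B: int,
    calls: IntrogressionCalls,
    universe: list[str],
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null FE distribution: B loci drawn without replacement per permutation.

    The null depends only on (B, Spf, S): the permuted Bpf is
    hypergeometric(S, Spf, B).
    """
    if B > len(universe):
        raise ValueError("B exceeds the universe size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intro_set = set(calls.loci)
    intro = np.array([l in intro_set for l in universe])
    S = len(universe)
    Spf = int(intro.sum())
    bpf = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        draw = rng.choice(S, size=B, replace=False)
        bpf[i] = int(intro[draw].sum())
    return (bpf / B) / (Spf / S)


def enrichment_scan(
    out_sets: dict[str, OutlierSet],
    calls: IntrogressionCalls,
    universe: list[str],
    env: EnvTable | None = None,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FE with permutation thresholds for every gradient's outlier set.

    Gradients with empty outlier sets are skipped (logged). Returns the
    per-gradient table and a per-class summary (median FE, counts above
    the 95th/99th null percentiles).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for g, oset in out_sets.items():
        if oset.B == 0:
            logger.info("enrichment_scan: gradient %s has no outliers, skipped", g)
            continue
        res = fold_enrichment(oset, calls, universe)
        null = permutation_null_fe(res.B, calls, universe, n_perm, rng)
        res.pct95 = float(np.quantile(null, 0.95))
        res.pct99 = float(np.quantile(null, 0.99))
        res.p = float((1.0 + np.sum(null >= res.fe)) / (n_perm + 1.0))
        res.exceed_95 = res.fe > res.pct95
        res.exceed_99 = res.fe > res.pct99
        res.n_perm = n_perm
        cls = env.gradient_class(g) if env is not None else "other"
        rows.append(
            (g, cls, res.B, res.Bpf, res.Spf, res.S, res.fe, res.p,
             res.pct95, res.pct99, res.exceed_95, res.exceed_99)
        )
    table = pd.DataFrame(
        rows,
        columns=["gradient", "class", "B", "Bpf", "Spf", "S", "fe", "p",
                 "pct95", "pct99", "exceed_95", "exceed_99"],
    )
    summary = (
        table.groupby("class")
        .agg(
            n_gradients=("gradient", "size"),
            median_fe=("fe", "median"),
            n_exceed_95=("exceed_95", "sum"),
            n_exceed_99=("exceed_99", "sum"),
        )
        .reset_index()
    )
    return table, summary
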