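"""LD-network detection of outlier SNP clusters (OCs).

Single-linkage hierarchical clustering on the distance 1 - r^2 yields a
merge tree; for every cluster the merger-change score
``lambda = (median within-cluster LD - median LD after merging into its
parent) * cluster size`` measures how sharply LD drops when the cluster
dissolves into the background. Clusters whose lambda exceeds
``median(lambda) + phi * MAD(lambda)`` and that contain at least
``E_min`` SNPs, taken at the highest r^2 threshold at which they exist
(i.e. innermost among nested candidates), are reported as outlier
clusters — candidate co-adapted SNP sets.

The replicate design pairs the environmental-association outliers with an
equal number of MAF-matched putatively neutral SNPs, repeats clustering
over many random neutral draws, and summarises how often small sets of
outlier SNPs co-occur in an OC — co-occurrence that survives the matched
neutral background is the signature of co-selected clusters rather than
introgression-wide LD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core import GenotypeMatrix, logger, minor_allele_freq
from .diffstats import MAF_BIN_WIDTH, r2_matrix
from .gea import OutlierSet, unique_outlier_loci


@dataclass
class LDMatrix:
    loci: list[str]
    r2: np.ndarray
    n_pairs: np.ndarray  # complete-individual count per pair

    def __post_init__(self) -> None:
        if self.r2.shape != (len(self.loci), len(self.loci)):
            raise ValueError("r2 shape does not match loci")


@dataclass
class OCluster:
    members: list[str]
    lambda_: float
    median_r2: float
    prop_outlier: float = float("nan")
    dominant_gradient: str = ""
    same_contig_outliers: bool = False


def pairwise_r2(
    G: GenotypeMatrix, loci: list[str], rows: np.ndarray | None = None
) -> LDMatrix:
    """Full pairwise r^2 matrix over the given loci."""
    cols = G.locus_index(loci)
    vals = G.values[:, cols] if rows is None else G.values[np.ix_(rows, cols)]
    obs = (vals != -1).astype(float)
    n = obs.T @ obs
    return LDMatrix(list(loci), r2_matrix(vals), n)


def _node_members(Z: np.ndarray, n_leaves: int) -> list[np.ndarray]:
    members: list[np.ndarray] = [np.array([i]) for i in range(n_leaves)]
    for c1, c2 in Z[:, :2].astype(int):
        members.append(np.concatenate([members[c1], members[c2]]))
    return members


def ldna_clusters(
    LD: LDMatrix, E_min: int = 5, phi: float = 2.0
) -> list[OCluster]:
    """Detect outlier clusters in an LD matrix (see module docstring).

    Pairs with undefined r^2 are treated as unlinked (r^2 = 0). Returns
    disjoint clusters; an all-equal LD matrix yields an empty list.
    """
    if E_min < 2:
        raise ValueError("E_min must be >= 2")
    if phi <= 0:
        raise ValueError("phi must be positive")
    n = len(LD.loci)
    if n < 2:
        return []
    r2 = np.nan_to_num(LD.r2, nan=0.0).clip(0.0, 1.0)
    r2 = 0.5 * (r2 + r2.T)
    np.fill_diagonal(r2, 1.0)
    dist = squareform(1.0 - r2, checks=False)
    Z = linkage(dist, method="single")
    members = _node_members(Z, n)

    med = np.full(len(members), np.nan)
    for k in range(n, len(members)):
        idx = members[k]
        sub = r2[np.ix_(idx, idx)]
        med[k] = np.median(sub[np.triu_indices(idx.size, k=1)])
    parent = np.full(len(members), -1)
    for i, (c1, c2) in enumerate(Z[:, :2].astype(int)):
        parent[c1] = parent[c2] = n + i

    lam = {}
    for k in range(n, len(members)):
        p = parent[k]
        if p < 0:
            continue  # root: never merges further
        lam[k] = (med[k] - med[p]) * members[k].size
    if not lam:
        return []
    lam_vals = np.array(list(lam.values()))
    lam_med = np.median(lam_vals)
    mad = np.median(np.abs(lam_vals - lam_med))
    # a point-mass lambda distribution with a few extreme clusters drives
    # the MAD to ~0; floor the scale by the dynamic range so the limit
    # stays between the noise spike and genuine outliers
    scale = max(mad, 0.05 * max(float(lam_vals.max() - lam_med), 0.0))
    limit = lam_med + phi * scale
    cand = [k for k, v in lam.items() if v > limit and members[k].size >= E_min]
    # innermost among nested candidates = highest r2 threshold of existence
    cand_sets = {k: set(members[k]) for k in cand}
    keep = [
        k for k in cand
        if not any(k2 != k and cand_sets[k2] < cand_sets[k] for k2 in cand)
    ]
    # tree structure makes survivors disjoint; resolve any residual overlap
    keep.sort(key=lambda k: lam[k], reverse=True)
    assigned: set[int] = set()
    out: list[OCluster] = []
    for k in keep:
        mem = [i for i in members[k] if i not in assigned]
        mem = _trim_chained_members(r2, mem)
        if len(mem) < E_min:
            continue
        assigned.update(mem)
        sub = r2[np.ix_(mem, mem)]
        med_k = float(np.median(sub[np.triu_indices(len(mem), k=1)]))
        out.append(
            OCluster([LD.loci[i] for i in sorted(mem)], float(lam[k]), med_k)
        )
    return out


def _trim_chained_members(r2: np.ndarray, mem: list[int]) -> list[int]:
    """Drop members chained onto a cluster by single-linkage.

    Single linkage admits stragglers connected through one strong edge (or
    a chain of mergers at similar heights) even when their LD with the
    bulk of the cluster is at background level. Members whose median LD
    to the rest falls below half the cluster's median pairwise LD are
    removed iteratively.
    """
    mem = list(mem)
    while len(mem) >= 2:
        sub = r2[np.ix_(mem, mem)]
        med = np.median(sub[np.triu_indices(len(mem), k=1)])
        per_member = np.nanmedian(
            np.where(np.eye(len(mem), dtype=bool), np.nan, sub), axis=1
        )
        bad = per_member < 0.5 * med
        if not bad.any():
            break
        mem = [m for m, b in zip(mem, bad) if not b]
    return mem


def _maf_matched_draw(
    maf_bins: np.ndarray,
    out_idx: np.ndarray,
    pool_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One MAF-bin-matched neutral SNP per outlier, without replacement."""
    available = {int(j): True for j in pool_idx}
    pool_by_bin: dict[int, list[int]] = {}
    for j in pool_idx:
        pool_by_bin.setdefault(int(maf_bins[j]), []).append(int(j))
    draw = []
    for j in out_idx:
        width = 0
        while True:
            cands = [
                c
                for b in range(int(maf_bins[j]) - width, int(maf_bins[j]) + width + 1)
                for c in pool_by_bin.get(b, [])
                if available[c]
            ]
            if cands:
                break
            width += 1
            if width > int(0.5 / MAF_BIN_WIDTH):
                raise ValueError("neutral pool exhausted for MAF matching")
        pick = cands[rng.integers(len(cands))]
        available[pick] = False
        draw.append(pick)
    return np.asarray(draw)


def replicate_oc_analysis(
    G: GenotypeMatrix,
    out_sets: dict[str, OutlierSet],
    n_rep: int = 100,
    seed: int | np.random.Generator = 0,
    E_min: int = 5,
    phi: float = 2.0,
    rows: np.ndarray | None = None,
    set_sizes: tuple[int, ...] = (3, 4, 5, 6),
    max_enumeration: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outlier + matched-neutral LD clustering over ``n_rep`` replicates.

    Returns ``(oc_table, shared_sets)``: one row per detected OC per
    replicate (size, lambda, median r^2, proportion of members that are
    outliers, dominant gradient, same-contig flag), and the co-occurrence
    fraction across replicates of every outlier-SNP subset of the sizes in
    ``set_sizes`` ever observed together in an OC. OCs with more than
    ``max_enumeration`` outlier members skip subset enumeration (logged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    outl = unique_outlier_loci(out_sets)
    if len(outl) < 2:
        raise ValueError("need at least 2 outlier loci")
    out_idx = G.locus_index(outl)
    pool_idx = np.array(
        [j for j, l in enumerate(G.locus_ids) if l not in set(outl)], dtype=int
    )
    maf = np.nan_to_num(minor_allele_freq(G, rows))
    maf_bins = np.clip((maf / MAF_BIN_WIDTH).astype(int), 0, int(0.5 / MAF_BIN_WIDTH) - 1)

    gradients_of: dict[str, list[str]] = {}
    bf_of: dict[str, float] = {}
    for gname, s in out_sets.items():
        for l in s.loci:
            gradients_of.setdefault(l, []).append(gname)
            bf_of[l] = max(bf_of.get(l, 0.0), float(s.bf_med.get(l, 0.0)))
    sum_bf_by_gradient = {
        gname: float(s.bf_med.sum()) for gname, s in out_sets.items()
    }

    oc_rows = []
    set_hits: dict[tuple, int] = {}
    set_meta: dict[tuple, str] = {}
    outl_set = set(outl)
    for rep in range(n_rep):
        neutral = _maf_matched_draw(maf_bins, out_idx, pool_idx, rng)
        loci = outl + [G.locus_ids[j] for j in neutral]
        LD = pairwise_r2(G, loci, rows=rows)
        seen_this_rep: set[tuple] = set()
        for oc in ldna_clusters(LD, E_min=E_min, phi=phi):
            mem_out = [l for l in oc.members if l in outl_set]
            oc.prop_outlier = len(mem_out) / len(oc.members)
            # dominant gradient: plurality over member outliers, ties by
            # higher summed median BF of the gradient's outlier set
            votes: dict[str, int] = {}
            for l in mem_out:
                for gname in gradients_of.get(l, []):
                    votes[gname] = votes.get(gname, 0) + 1
            if votes:
                oc.dominant_gradient = max(
                    votes, key=lambda gname: (votes[gname], sum_bf_by_gradient.get(gname, 0.0))
                )
            contigs = [l.split(":", 1)[0] for l in mem_out]
            oc.same_contig_outliers = len(set(contigs)) < len(contigs)
            if oc.same_contig_outliers:
                logger.warning(
                    "replicate %d: outlier SNPs from the same contig co-occur "
                    "in an OC: %s", rep, sorted(mem_out),
                )
            oc_rows.append(
                (rep, len(oc.members), len(mem_out), oc.lambda_, oc.median_r2,
                 oc.prop_outlier, oc.dominant_gradient, oc.same_contig_outliers,
                 ";".join(oc.members))
            )
            for k in set_sizes:
                if len(mem_out) < k:
                    continue
                if len(mem_out) > max_enumeration:
                    logger.info(
                        "replicate %d: OC with %d outlier members exceeds "
                        "enumeration cap for k=%d", rep, len(mem_out), k,
                    )
                    continue
                for comb in itertools.combinations(sorted(mem_out), k):
                    seen_this_rep.add(comb)
                    set_meta.setdefault(comb, oc.dominant_gradient)
        for comb in seen_this_rep:
            set_hits[comb] = set_hits.get(comb, 0) + 1

    oc_table = pd.DataFrame(
        oc_rows,
        columns=["replicate", "size", "n_outlier", "lambda", "median_r2",
                 "prop_outlier", "dominant_gradient", "same_contig", "members"],
    )
    shared = pd.DataFrame(
        [
            (";".join(c), len(c), hits / n_rep, set_meta[c])
            for c, hits in sorted(set_hits.items())
        ],
        columns=["set_members", "k", "co_occurrence_fraction", "dominant_gradient"],
    )
    return oc_table, shared
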