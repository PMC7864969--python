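"""Core data containers for hybrid-zone genotype analysis.

The pipeline operates on unphased biallelic SNP genotypes in 012 coding
(counts of a designated "counted" allele per individual and locus), a
population map assigning each individual to a population and each
population to one of three groups (two pure parental species and the
hybrid zone), a per-population environmental table, and per-population
allele-frequency tables derived from the genotypes.

Missing genotypes are an explicit sentinel (``MISSING == -1``) carried as
masks throughout; they are never imputed, because the proportion of
missing data is itself used downstream as a matching covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hzadapt")

#: Sentinel for a missing genotype call in 012 coding.
MISSING: int = -1

#: The three population groups: the two pure parental species and the
#: hybrid zone. P2 plays the role of the donor species whose direction of
#: introgression is tested (P. flexilis in the motivating system).
GROUPS = ("P1", "P2", "HYB")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of counted-allele dosages in {0,1,2,MISSING}.

    Parameters
    ----------
    values
        Integer array of shape (n_individuals, n_loci); entries 0, 1, 2
        or :data:`MISSING`.
    individual_ids, locus_ids
        Unique labels for rows and columns. Locus ids are conventionally
        ``contig:pos`` but any unique strings are accepted.
    counted_allele
        Optional per-locus label of the allele being counted. When absent
        the counted allele is the abstract "minor" allele of the source
        file; all downstream statistics are direction-invariant or use
        absolute correlations, so polarity never changes results.
    """

    values: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    counted_allele: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2:
            raise FormatError("genotype values must be a 2-D array")
        n_ind, n_loc = self.values.shape
        if len(self.individual_ids) != n_ind:
            raise FormatError(
                f"{len(self.individual_ids)} individual ids for {n_ind} rows"
            )
        if len(self.locus_ids) != n_loc:
            raise FormatError(f"{len(self.locus_ids)} locus ids for {n_loc} columns")
        if len(set(self.individual_ids)) != n_ind:
            raise FormatError("individual ids are not unique")
        if len(set(self.locus_ids)) != n_loc:
            raise FormatError("locus ids are not unique")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"genotype {self.values[i, j]} at ({self.individual_ids[i]}, "
                f"{self.locus_ids[j]}) outside {{0,1,2,{MISSING}}}"
            )
        if self.counted_allele is not None and len(self.counted_allele) != n_loc:
            raise FormatError("counted_allele length does not match loci")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the call is missing."""
        return self.values == MISSING

    def locus_index(self, loci: Iterable[str]) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.locus_ids)}
        try:
            return np.array([pos[l] for l in loci], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown locus {e.args[0]!r}") from None

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given individuals and/or loci."""
        rows = np.arange(self.n_individuals)
        cols = np.arange(self.n_loci)
        ind_ids, loc_ids = self.individual_ids, self.locus_ids
        if individuals is not None:
            ipos = {s: i for i, s in enumerate(self.individual_ids)}
            rows = np.array([ipos[s] for s in individuals], dtype=int)
            ind_ids = list(individuals)
        if loci is not None:
            cols = self.locus_index(loci)
            loc_ids = list(loci)
        counted = (
            [self.counted_allele[c] for c in cols] if self.counted_allele else None
        )
        return GenotypeMatrix(
            self.values[np.ix_(rows, cols)].copy(), list(ind_ids), list(loc_ids), counted
        )


@dataclass
class PopulationMap:
    """Assignment of individuals to populations and populations to groups.

    Each population carries WGS84 decimal-degree coordinates and an
    elevation in metres.
    """

    individual_to_pop: dict[str, str]
    pop_group: dict[str, str]
    pop_coords: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        pops_used = set(self.individual_to_pop.values())
        for p in pops_used:
            if p not in self.pop_group:
                raise FormatError(f"population {p!r} has no group assignment")
            if p not in self.pop_coords:
                raise FormatError(f"population {p!r} has no coordinates")
        for p, g in self.pop_group.items():
            if g not in GROUPS:
                raise FormatError(f"group {g!r} for population {p!r} not in {GROUPS}")
        counts: dict[str, int] = {}
        for p in self.individual_to_pop.values():
            counts[p] = counts.get(p, 0) + 1
        self._pop_sizes = counts

    @property
    def populations(self) -> list[str]:
        """Populations with at least one individual, in stable order."""
        seen: dict[str, None] = {}
        for p in self.individual_to_pop.values():
            seen.setdefault(p, None)
        return list(seen)

    def populations_of_group(self, group: str) -> list[str]:
        return [p for p in self.populations if self.pop_group[p] == group]

    def individuals_of_pops(self, pops: Iterable[str]) -> list[str]:
        pops = set(pops)
        return [i for i, p in self.individual_to_pop.items() if p in pops]

    def individuals_of_groups(self, groups: Iterable[str]) -> list[str]:
        groups = set(groups)
        return [
            i
            for i, p in self.individual_to_pop.items()
            if self.pop_group[p] in groups
        ]

    def row_indices(self, G: GenotypeMatrix, individuals: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(G.individual_ids)}
        return np.array([pos[s] for s in individuals], dtype=int)


@dataclass
class EnvTable:
    """Population x gradient matrix of environmental values plus metadata.

    ``metadata`` has one row per gradient with columns ``name``, ``class``
    (one of ``freeze``, ``water``, ``other``) and ``divergence_rank`` (rank
    of the absolute difference of parental medians; 1 = most divergent).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate gradient names in environmental table")
        meta_names = set(self.metadata["name"])
        missing = [g for g in self.values.columns if g not in meta_names]
        if missing:
            # Unannotated gradients get class "other" and no rank.
            extra = pd.DataFrame(
                {"name": missing, "class": "other", "divergence_rank": np.nan}
            )
            self.metadata = pd.concat([self.metadata, extra], ignore_index=True)
        self.metadata = self.metadata.set_index("name", drop=False)

    @property
    def gradients(self) -> list[str]:
        return list(self.values.columns)

    def gradient_class(self, name: str) -> str:
        return str(self.metadata.loc[name, "class"])

    def gradients_of_class(self, cls: str) -> list[str]:
        return [g for g in self.gradients if self.gradient_class(g) == cls]

    def vector(self, name: str, populations: Sequence[str]) -> np.ndarray:
        if name not in self.values.columns:
            raise KeyError(f"unknown gradient {name!r}")
        sub = self.values.loc[list(populations), name]
        if sub.isna().any():
            raise FormatError(f"gradient {name!r} has missing population values")
        return sub.to_numpy(dtype=float)


@dataclass
class FreqTable:
    """Per-population counted-allele frequencies with sample sizes.

    ``freq[p, l]`` is the frequency of the counted allele at locus ``l``
    in population ``p`` (NaN where no non-missing calls exist) and
    ``n[p, l]`` the number of allele copies (2 x non-missing individuals)
    used.
    """

    freq: np.ndarray
    n: np.ndarray
    populations: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.freq.shape != self.n.shape:
            raise FormatError("freq and n shapes differ")
        if self.freq.shape != (len(self.populations), len(self.locus_ids)):
            raise FormatError("freq shape does not match labels")
        with np.errstate(invalid="ignore"):
            defined = self.n > 0
            bad = defined & ((self.freq < 0) | (self.freq > 1))
        if bad.any():
            raise FormatError("allele frequency outside [0, 1]")
        if np.isfinite(self.freq[~defined]).any():
            raise FormatError("frequency defined where n == 0")

    def subset_loci(self, loci: Sequence[str]) -> "FreqTable":
        pos = {l: i for i, l in enumerate(self.locus_ids)}
        cols = np.array([pos[l] for l in loci], dtype=int)
        return FreqTable(
            self.freq[:, cols].copy(), self.n[:, cols].copy(), list(self.populations), list(loci)
        )


# ---------------------------------------------------------------------------
# Site filters and frequency estimation
# ---------------------------------------------------------------------------


def filter_biallelic(
    G: GenotypeMatrix, pmap: PopulationMap, scope: Iterable[str]
) -> GenotypeMatrix:
    """Retain loci segregating (both alleles observed) within ``scope`` groups.

    A locus is kept when, among non-missing calls of individuals belonging
    to populations of the scope groups, the counted-allele frequency is
    strictly between 0 and 1. Loci with every call missing in scope are
    dropped (and logged). The operation is idempotent.
    """
    scope = set(scope)
    if not scope:
        raise ValueError("scope must name at least one group")
    unknown = scope - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups in scope: {sorted(unknown)}")
    inds = pmap.individuals_of_groups(scope)
    rows = pmap.row_indices(G, inds)
    vals = G.values[rows]
    obs = vals != MISSING
    n_copies = 2 * obs.sum(axis=0)
    counts = np.where(obs, vals, 0).sum(axis=0)
    all_missing = n_copies == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counts / n_copies
    keep = (~all_missing) & (counts > 0) & (counts < n_copies)
    if all_missing.any():
        dropped = [G.locus_ids[j] for j in np.flatnonzero(all_missing)[:5]]
        logger.info(
            "filter_biallelic: %d loci with all calls missing in scope "
            "(e.g. %s) dropped", int(all_missing.sum()), dropped,
        )
    kept_ids = [G.locus_ids[j] for j in np.flatnonzero(keep)]
    logger.info(
        "filter_biallelic: retained %d / %d loci in scope %s",
        len(kept_ids), G.n_loci, sorted(scope),
    )
    return G.subset(loci=kept_ids)


def allele_freqs(G: GenotypeMatrix, pmap: PopulationMap) -> FreqTable:
    """Per-population counted-allele frequencies f = counts / (2 * n_obs)."""
    pops = pmap.populations
    freq = np.full((len(pops), G.n_loci), np.nan)
    n = np.zeros((len(pops), G.n_loci), dtype=int)
    for i, p in enumerate(pops):
        rows = pmap.row_indices(G, pmap.individuals_of_pops([p]))
        vals = G.values[rows]
        obs = vals != MISSING
        n[i] = 2 * obs.sum(axis=0)
        counts = np.where(obs, vals, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[i] = np.where(n[i] > 0, counts / np.maximum(n[i], 1), np.nan)
    return FreqTable(freq, n, pops, list(G.locus_ids))


def minor_allele_freq(G: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Folded (minor) allele frequency per locus over the given rows."""
    vals = G.values if rows is None else G.values[rows]
    obs = vals != MISSING
    n = 2 * obs.sum(axis=0)
    counts = np.where(obs, vals, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, counts / np.maximum(n, 1), np.nan)
    return np.minimum(f, 1.0 - f)


def missingness(G: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Proportion of missing calls per locus over the given rows."""
    m = G.mask if rows is None else G.mask[rows]
    return m.mean(axis=0)
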