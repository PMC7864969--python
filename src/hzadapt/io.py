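"""Readers and writers for the pipeline's plain-text formats.

Genotypes use the VCFtools ``--012`` triplet dialect: a ``.012`` matrix
(rows = individuals, tab-separated entries 0/1/2 with -1 for missing,
optionally preceded by a 0-based row index as VCFtools writes it), a
``.012.indv`` file with one individual id per line, and a ``.012.pos``
file with ``contig<TAB>position`` per line.

Tabular inputs (population map, environmental table, gradient metadata,
truth table) are TSV with a header row.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    EnvTable,
    FormatError,
    GenotypeMatrix,
    PopulationMap,
)


def _triplet_paths(prefix: str | os.PathLike) -> tuple[Path, Path, Path]:
    prefix = str(prefix)
    if prefix.endswith(".012"):
        prefix = prefix[: -len(".012")]
    return Path(prefix + ".012"), Path(prefix + ".012.indv"), Path(prefix + ".012.pos")


def read_geno012(
    path_matrix: str | os.PathLike,
    path_indv: str | os.PathLike | None = None,
    path_pos: str | os.PathLike | None = None,
) -> GenotypeMatrix:
    """Read a VCFtools-style 012 triplet into a :class:`GenotypeMatrix`.

    ``path_matrix`` may be the ``.012`` file or the triplet prefix; when
    ``path_indv``/``path_pos`` are omitted they are derived from it. A
    leading per-row index column (the VCFtools convention) is detected
    from the column count and stripped.
    """
    if path_indv is None or path_pos is None:
        path_matrix, d_indv, d_pos = _triplet_paths(path_matrix)
        path_indv = path_indv or d_indv
        path_pos = path_pos or d_pos
    for p in (path_matrix, path_indv, path_pos):
        if not Path(p).exists():
            raise FileNotFoundError(p)

    indv = [ln.strip() for ln in Path(path_indv).read_text().splitlines() if ln.strip()]
    pos_lines = [
        ln.strip() for ln in Path(path_pos).read_text().splitlines() if ln.strip()
    ]
    if not pos_lines:
        raise FormatError(f"{path_pos}: no loci listed")
    loci = []
    for ln in pos_lines:
        parts = ln.split()
        loci.append(":".join(parts[:2]) if len(parts) >= 2 else parts[0])

    rows = []
    with open(path_matrix) as fh:
        for k, ln in enumerate(fh):
            ln = ln.strip()
            if not ln:
                continue
            fields = ln.split()
            if len(fields) == len(loci) + 1:
                fields = fields[1:]  # leading VCFtools row index
            elif len(fields) != len(loci):
                raise FormatError(
                    f"{path_matrix}: row {k} has {len(fields)} entries, "
                    f"expected {len(loci)}"
                )
            try:
                rows.append([int(x) for x in fields])
            except ValueError as e:
                raise FormatError(f"{path_matrix}: row {k}: {e}") from None
    if len(rows) != len(indv):
        raise FormatError(
            f"{path_matrix}: {len(rows)} genotype rows but {len(indv)} "
            f"individuals in {path_indv}"
        )
    values = np.asarray(rows, dtype=np.int16)
    values[values == -1] = MISSING
    return GenotypeMatrix(values, indv, loci)


def write_geno012(G: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write the 012 triplet (with VCFtools leading row index)."""
    p_mat, p_indv, p_pos = _triplet_paths(prefix)
    with open(p_mat, "w") as fh:
        for i in range(G.n_individuals):
            fh.write("\t".join([str(i)] + [str(int(v)) for v in G.values[i]]) + "\n")
    Path(p_indv).write_text("".join(s + "\n" for s in G.individual_ids))
    with open(p_pos, "w") as fh:
        for l in G.locus_ids:
            parts = l.split(":", 1)
            fh.write((parts[0] + "\t" + parts[1] if len(parts) == 2 else l + "\t0") + "\n")


def read_population_map(path: str | os.PathLike) -> PopulationMap:
    """TSV with columns indiv, pop, group, lat, lon, elev."""
    df = pd.read_csv(path, sep="\t", dtype={"indiv": str, "pop": str, "group": str})
    required = {"indiv", "pop", "group", "lat", "lon", "elev"}
    if not required.issubset(df.columns):
        raise FormatError(f"population map missing columns {required - set(df.columns)}")
    ind_to_pop = dict(zip(df["indiv"], df["pop"]))
    if len(ind_to_pop) != len(df):
        raise FormatError("duplicate individual ids in population map")
    pop_group: dict[str, str] = {}
    pop_coords: dict[str, tuple[float, float, float]] = {}
    for _, r in df.iterrows():
        pop_group[r["pop"]] = r["group"]
        pop_coords[r["pop"]] = (float(r["lat"]), float(r["lon"]), float(r["elev"]))
    return PopulationMap(ind_to_pop, pop_group, pop_coords)


def write_population_map(pmap: PopulationMap, path: str | os.PathLike) -> None:
    rows = []
    for ind, pop in pmap.individual_to_pop.items():
        lat, lon, elev = pmap.pop_coords[pop]
        rows.append((ind, pop, pmap.pop_group[pop], lat, lon, elev))
    pd.DataFrame(rows, columns=["indiv", "pop", "group", "lat", "lon", "elev"]).to_csv(
        path, sep="\t", index=False
    )


def read_env_table(
    path_values: str | os.PathLike, path_metadata: str | os.PathLike | None = None
) -> EnvTable:
    """Environmental TSV (first column ``pop``) plus optional metadata TSV."""
    vals = pd.read_csv(path_values, sep="\t")
    if "pop" not in vals.columns:
        raise FormatError("environmental table must have a 'pop' column")
    vals = vals.set_index("pop")
    if path_metadata is not None:
        meta = pd.read_csv(path_metadata, sep="\t")
        if "name" not in meta.columns or "class" not in meta.columns:
            raise FormatError("gradient metadata needs 'name' and 'class' columns")
        if "divergence_rank" not in meta.columns:
            meta["divergence_rank"] = np.nan
    else:
        meta = pd.DataFrame(
            {"name": list(vals.columns), "class": "other", "divergence_rank": np.nan}
        )
    return EnvTable(vals, meta)


def write_env_table(env: EnvTable, path_values, path_metadata=None) -> None:
    env.values.rename_axis("pop").to_csv(path_values, sep="\t")
    if path_metadata is not None:
        env.metadata.reset_index(drop=True).to_csv(path_metadata, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Deterministic TSV writer used by every pipeline stage."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
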