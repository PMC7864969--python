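"""Configuration-driven orchestration of the full analysis.

Stages (in dependency order): ``simulate`` (or external input), ``filter``,
``gea``, ``clines``, ``fstats``, ``ldna``, ``ohta``, ``rda``, ``enrich``.
Each stage writes one or more TSV tables to the output directory; a JSON
manifest records the configuration, derived stage seeds, package and
library versions and headline counts, so that an identical configuration
and seed reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import EnvTable, FormatError, GenotypeMatrix, PopulationMap, logger
from . import clines as _clines
from . import diffstats as _diff
from . import enrich as _enrich
from . import gea as _gea
from . import geo as _geo
from . import ldnet as _ldnet
from . import mmrr as _mmrr
from . import ohta as _ohta
from . import rda as _rda
from .core import allele_freqs, filter_biallelic
from .io import (
    read_env_table,
    read_geno012,
    read_population_map,
    write_env_table,
    write_geno012,
    write_population_map,
    write_tsv,
)
from .simulate import SimParams, simulate_hybrid_zone

STAGE_ORDER = ["simulate", "filter", "gea", "clines", "fstats", "ldna", "ohta",
               "rda", "enrich"]
STAGE_DEPS = {
    "filter": [],
    "gea": ["filter"],
    "clines": ["filter"],
    "fstats": ["gea"],
    "ldna": ["gea"],
    "ohta": ["gea"],
    "rda": ["gea", "clines"],
    "enrich": ["gea", "clines"],
}

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "hzadapt_out",
    "stages": ["all"],
    "simulate": {},
    "input": {},
    "gea": {"n_runs": 3, "subset_size": 1000, "quantile": 0.99, "tau": 1.0,
            "gradients": None},
    "fstats": {"n_boot": 1000, "statistics": ["fst", "fct", "median_r2"]},
    "ldna": {"n_rep": 100, "e_min": 5, "phi": 2.0},
    "ohta": {"n_perm": 999},
    "rda": {"n_perm": 9999, "var_target": 0.90, "vif_threshold": 10.0,
            "geo_degree": 2},
    "clines": {"delta_min": 0.1, "n_sim_envelope": 1000, "envelope_level": 0.95,
               "alpha_family": 0.05, "tree_frac": 0.20, "min_informative": 50},
    "enrich": {"n_perm": 10000},
}


class DependencyError(RuntimeError):
    pass


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    for k, v in user.items():
        if k not in cfg:
            raise FormatError(f"unknown configuration key {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, dict):
            for kk, vv in v.items():
                if kk not in cfg[k] and k != "simulate" and k != "input":
                    raise FormatError(f"unknown configuration key {k}.{kk}")
                cfg[k][kk] = vv
        else:
            cfg[k] = v
    return cfg


def _resolve_stages(requested: list[str]) -> list[str]:
    if requested == ["all"] or requested == "all":
        return [s for s in STAGE_ORDER]
    stages = list(dict.fromkeys(requested))
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise FormatError(f"unknown stages {unknown}")
    for s in stages:
        for d in STAGE_DEPS.get(s, []):
            if d not in stages:
                raise DependencyError(
                    f"stage {s!r} requires stage {d!r}, which is not requested "
                    "and has no stored artifact"
                )
    return [s for s in STAGE_ORDER if s in stages or (s == "simulate" and s in stages)]


def _stage_seed(base: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(base), STAGE_ORDER.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config) -> dict:
    """Execute the configured stages; returns in-memory artifacts.

    Raises :class:`DependencyError` when a requested stage's upstream
    stage is absent, and validation errors (unknown gradients, unknown
    config keys) before any computation starts.
    """
    cfg = load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    stages = _resolve_stages(cfg["stages"])
    manifest: dict = {
        "package_version": __version__,
        "numpy": np.__version__,
        "config": cfg,
        "stages": stages,
        "stage_seeds": {s: _stage_seed(cfg["seed"], s) for s in stages},
        "counts": {},
    }
    ctx: dict = {"manifest": manifest}
    try:
        # ---- input ------------------------------------------------------
        if "simulate" in stages:
            params = SimParams(**{**cfg["simulate"],
                                  "seed": cfg["simulate"].get("seed", cfg["seed"])})
            G, pmap, env, truth = simulate_hybrid_zone(params)
            ctx.update(G=G, pmap=pmap, env=env, truth=truth)
            write_geno012(G, out / "simulated")
            write_population_map(pmap, out / "popmap.tsv")
            write_env_table(env, out / "env.tsv", out / "env_meta.tsv")
            write_tsv(truth.to_frame(), out / "truth.tsv")
        else:
            inp = cfg["input"]
            for key in ("geno012", "popmap", "env"):
                if key not in inp:
                    raise DependencyError(
                        f"no 'simulate' stage and no input.{key} configured"
                    )
            ctx["G"] = read_geno012(inp["geno012"])
            ctx["pmap"] = read_population_map(inp["popmap"])
            ctx["env"] = read_env_table(inp["env"], inp.get("env_meta"))

        # validate gradient names before any compute
        g_cfg = cfg["gea"]["gradients"]
        if g_cfg:
            unknown = [g for g in g_cfg if g not in ctx["env"].gradients]
            if unknown:
                raise FormatError(f"unknown gradient name(s) in config: {unknown}")

        for stage in stages:
            if stage == "simulate":
                continue
            _STAGE_FNS[stage](ctx, cfg, out, manifest["stage_seeds"][stage])
    finally:
        logger.removeHandler(fh)
        fh.close()
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    return ctx


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_filter(ctx, cfg, out, seed):
    G, pmap = ctx["G"], ctx["pmap"]
    G_hyb = filter_biallelic(G, pmap, {"HYB"})
    # cline universe additionally requires segregation across the parentals
    G_par = filter_biallelic(G_hyb, pmap, {"P1", "P2"})
    ctx["G_hyb"] = G_hyb
    ctx["cline_universe"] = list(G_par.locus_ids)
    hyb_pops = pmap.populations_of_group("HYB")
    F_all = allele_freqs(G_hyb, pmap)
    idx = [F_all.populations.index(p) for p in hyb_pops]
    from .core import FreqTable
    ctx["F_hyb"] = FreqTable(F_all.freq[idx], F_all.n[idx], hyb_pops,
                             list(G_hyb.locus_ids))
    ctx["manifest"]["counts"]["n_biallelic_hyb"] = G_hyb.n_loci
    ctx["manifest"]["counts"]["n_cline_universe"] = len(ctx["cline_universe"])
    write_geno012(G_hyb, out / "filtered")


def _stage_gea(ctx, cfg, out, seed):
    c = cfg["gea"]
    env = ctx["env"]
    gradients = c["gradients"] or env.gradients
    out_sets, records = _gea.gea_scan(
        ctx["F_hyb"], env, gradients, n_runs=c["n_runs"],
        subset_size=c["subset_size"], q=c["quantile"], tau=c["tau"], seed=seed,
    )
    ctx["out_sets"] = out_sets
    ctx["gea_records"] = records
    # population covariance kept for the RDA structure axis
    ctx["cov"] = _gea.estimate_pop_covariance(
        ctx["F_hyb"], c["subset_size"], seed=seed, run_id=0
    )
    write_tsv(records, out / "gea_records.tsv")
    rows = [(g, l, float(s.bf_med.get(l, np.nan)))
            for g, s in out_sets.items() for l in s.loci]
    write_tsv(pd.DataFrame(rows, columns=["gradient", "locus", "bf_med"]),
              out / "gea_outliers.tsv")
    ctx["manifest"]["counts"]["n_unique_outliers"] = len(
        _gea.unique_outlier_loci(out_sets))


def _stage_fstats(ctx, cfg, out, seed):
    c = cfg["fstats"]
    G, pmap = ctx["G_hyb"], ctx["pmap"]
    rng = np.random.default_rng(seed)
    exclude = _gea.unique_outlier_loci(ctx["out_sets"])
    hyb_rows = pmap.row_indices(G, pmap.individuals_of_groups(["HYB"]))
    groups = ("P1", "P2", "HYB")
    glob = _diff.hierarchical_fstats(G, pmap, groups)
    het = _diff.heterozygosities(G, pmap)
    rows = []
    for g, oset in ctx["out_sets"].items():
        if oset.B < 2:
            continue
        for stat in c["statistics"]:
            mn = _diff.matched_bootstrap_null(
                G, pmap, oset.loci, exclude, stat, n_boot=c["n_boot"], seed=rng,
                groups=None if stat == "median_r2" else groups,
                scope_rows=hyb_rows if stat == "median_r2" else None,
            )
            rows.append((g, stat, mn.observed, float(np.mean(mn.null_values)),
                         mn.p, mn.n_widened))
    tbl = pd.DataFrame(rows, columns=["gradient", "statistic", "observed",
                                      "null_mean", "p", "n_widened"])
    ctx["fstats_table"] = tbl
    ctx["global_fstats"] = glob
    ctx["manifest"]["counts"]["global_fst"] = glob.fst
    ctx["manifest"]["counts"]["global_fct"] = glob.fct
    write_tsv(tbl, out / "fstats_outlier_sets.tsv")
    write_tsv(het, out / "heterozygosities.tsv")


def _stage_ldna(ctx, cfg, out, seed):
    c = cfg["ldna"]
    pmap = ctx["pmap"]
    hyb_rows = pmap.row_indices(ctx["G_hyb"], pmap.individuals_of_groups(["HYB"]))
    oc_table, shared = _ldnet.replicate_oc_analysis(
        ctx["G_hyb"], ctx["out_sets"], n_rep=c["n_rep"], seed=seed,
        E_min=c["e_min"], phi=c["phi"], rows=hyb_rows,
    )
    ctx["oc_table"], ctx["shared_sets"] = oc_table, shared
    ctx["manifest"]["counts"]["n_ocs"] = len(oc_table)
    write_tsv(oc_table, out / "ldna_ocs.tsv")
    write_tsv(shared, out / "ldna_shared_sets.tsv")


def _stage_ohta(ctx, cfg, out, seed):
    c = cfg["ohta"]
    G, pmap, env = ctx["G_hyb"], ctx["pmap"], ctx["env"]
    pops = pmap.populations_of_group("HYB")
    D_geo = _geo.geographic_distance_matrix(pmap).loc[pops, pops]
    rng = np.random.default_rng(seed)
    rows = []
    for g, oset in ctx["out_sets"].items():
        if oset.B < 2:
            continue
        D_is, D_st = _ohta.pairwise_d_matrices(G, pmap, oset.loci, pops)
        D_env = _mmrr.env_distance_matrix(env, g, pops)
        for resp_name, D_resp in (("D_IS", D_is), ("D_ST", D_st)):
            r = _mmrr.mmrr_partition(D_resp, D_env, D_geo, n_perm=c["n_perm"],
                                     seed=rng)
            rows.append((g, resp_name, r.r2_full, r.r2_pure_env, r.r2_pure_geo,
                         r.r2_confounded, r.p_full, r.p_env_only, r.p_geo_only))
    tbl = pd.DataFrame(rows, columns=["gradient", "response", "r2_full",
                                      "r2_pure_env", "r2_pure_geo",
                                      "r2_confounded", "p_full", "p_env", "p_geo"])
    ctx["ohta_table"] = tbl
    write_tsv(tbl, out / "ohta_mmrr.tsv")


def _stage_clines(ctx, cfg, out, seed):
    c = cfg["clines"]
    G, pmap = ctx["G_hyb"], ctx["pmap"]
    universe = ctx["cline_universe"]
    hyb_inds = pmap.individuals_of_groups(["HYB"])
    hi = _clines.hybrid_index(G, pmap, delta_min=c["delta_min"],
                              min_informative=c["min_informative"],
                              individuals=hyb_inds)
    f1, f2 = _clines.parental_freqs(G, pmap)
    fits = _clines.fit_genomic_clines(G, hi, f1, f2, individuals=hyb_inds,
                                      loci=universe)
    cols = G.locus_index(universe)
    delta_ok = np.abs(f2[cols] - f1[cols]) >= c["delta_min"]
    pairs = np.column_stack([f1[cols][delta_ok], f2[cols][delta_ok]])
    flip = pairs[:, 1] < pairs[:, 0]
    pairs[flip] = 1.0 - pairs[flip]  # orient to the P2-like allele
    env_curve = _clines.neutral_cline_envelope(
        fits.h, pairs, n_sim=c["n_sim_envelope"], level=c["envelope_level"],
        seed=seed,
    )
    calls = _clines.call_introgressed_snps(
        fits, env_curve, alpha_family=c["alpha_family"], tree_frac=c["tree_frac"],
        envelope_level=c["envelope_level"],
    )
    ctx.update(hybrid_index=hi, cline_fits=fits, calls=calls)
    ctx["manifest"]["counts"]["n_introgressed"] = calls.Spf
    write_tsv(hi, out / "hybrid_index.tsv")
    tab = fits.table.copy()
    tab["called"] = tab["locus"].isin(set(calls.loci))
    sup = calls.tree_support.reindex(tab["locus"]).to_numpy()
    tab["tree_support"] = sup
    write_tsv(tab, out / "cline_fits.tsv")


def _stage_rda(ctx, cfg, out, seed):
    c = cfg["rda"]
    pmap, env = ctx["pmap"], ctx["env"]
    pops = pmap.populations_of_group("HYB")
    F = ctx["F_hyb"]
    Y = _rda.hellinger_transform(F, pops)
    hi = ctx["hybrid_index"].set_index("individual")["h"]
    anc = pd.Series(
        {p: hi.reindex(pmap.individuals_of_pops([p])).mean() for p in pops},
        name="ancestry",
    )
    pred = _rda.build_predictors(env, pmap, anc, ctx["cov"].omega, pops,
                                 var_target=c["var_target"],
                                 geo_degree=c["geo_degree"])
    blocks = pred.as_dict()
    X_all = pd.concat(blocks.values(), axis=1)
    X_pruned, dropped = _rda.vif_prune(X_all, threshold=c["vif_threshold"])
    blocks = {k: v.loc[:, [col for col in v.columns if col in X_pruned.columns]]
              for k, v in blocks.items()}
    blocks = {k: v for k, v in blocks.items() if v.shape[1] > 0}
    rng = np.random.default_rng(seed)
    rows = []
    names = list(blocks)
    full = _rda.rda_fit(Y, pd.concat(blocks.values(), axis=1),
                        n_perm=c["n_perm"], seed=rng)
    rows.append(("All", full.r2, full.r2_adj, full.p))
    for k in names:
        r = _rda.rda_fit(Y, blocks[k], n_perm=c["n_perm"], seed=rng)
        rows.append((k, r.r2, r.r2_adj, r.p))
        others = pd.concat([blocks[j] for j in names if j != k], axis=1)
        rp = _rda.rda_fit(Y, blocks[k], Z=others, n_perm=c["n_perm"], seed=rng)
        rows.append((f"{k} |X", rp.r2, rp.r2_adj, rp.p))
    tbl = pd.DataFrame(rows, columns=["model", "r2", "r2_adj", "p"])
    write_tsv(tbl, out / "rda_models.tsv")
    ctx["rda_models"] = tbl
    if len(blocks) == 4:
        vp = _rda.variance_partition4(Y, blocks)
        write_tsv(vp, out / "rda_varpart.tsv")
        ctx["rda_varpart"] = vp
        inter = _rda.interaction_model_test(
            Y, blocks["env"], blocks["ancestry"],
            condition=[blocks["geo"], blocks["structure"]],
            n_perm=min(c["n_perm"], 999), seed=rng,
        )
        write_tsv(pd.DataFrame([inter]), out / "rda_interaction.tsv")
        ctx["rda_interaction"] = inter
    ctx["manifest"]["counts"]["rda_dropped_vif"] = dropped


def _stage_enrich(ctx, cfg, out, seed):
    c = cfg["enrich"]
    universe = ctx["cline_universe"]
    sets_in_universe = {
        g: _gea.OutlierSet(g, [l for l in s.loci if l in set(universe)],
                           s.bf_med)
        for g, s in ctx["out_sets"].items()
    }
    table, summary = _enrich.enrichment_scan(
        sets_in_universe, ctx["calls"], universe, ctx["env"],
        n_perm=c["n_perm"], seed=seed,
    )
    ctx["enrichment"], ctx["enrichment_summary"] = table, summary
    write_tsv(table, out / "enrichment.tsv")
    write_tsv(summary, out / "enrichment_summary.tsv")


_STAGE_FNS = {
    "filter": _stage_filter,
    "gea": _stage_gea,
    "fstats": _stage_fstats,
    "ldna": _stage_ldna,
    "ohta": _stage_ohta,
    "clines": _stage_clines,
    "rda": _stage_rda,
    "enrich": _stage_enrich,
}
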