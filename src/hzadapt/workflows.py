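"""High-level study workflows on the synthetic preset.

These functions bundle the stage calls of a complete desk-scale analysis
into a single deterministic protocol: simulate, filter, scan, estimate
the hybrid index, fit clines, call introgression, and test enrichment.
They are what the worked examples, the validation suite and the
reproduction script all run, so the numbers those report come from one
code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clines as _clines
from . import enrich as _enrich
from . import gea as _gea
from .core import FreqTable, GenotypeMatrix, PopulationMap, allele_freqs, filter_biallelic
from .simulate import SimParams, TruthTable, simulate_hybrid_zone


@dataclass
class PresetRun:
    """Artifacts of one synthetic-preset analysis run."""

    params: SimParams
    G: GenotypeMatrix
    pmap: PopulationMap
    env: object
    truth: TruthTable
    G_hyb: GenotypeMatrix
    universe: list[str]  # loci biallelic in the hybrid zone and across parentals
    F_hyb: FreqTable
    out_sets: dict[str, _gea.OutlierSet]
    hybrid_index: pd.DataFrame
    cline_fits: _clines.ClineFits
    calls: _clines.IntrogressionCalls
    enrichment: pd.DataFrame
    enrichment_summary: pd.DataFrame

    def gea_recall_freeze(self) -> float:
        """Fraction of planted introgressed loci in the union of freeze-class outlier sets."""
        freeze = [g for g in self.env.gradients
                  if self.env.gradient_class(g) == "freeze"]
        union = set().union(*[set(self.out_sets[g].loci) for g in freeze]) if freeze else set()
        planted = set(self.truth.loci_of_class("adaptive_introgressed"))
        return len(planted & union) / len(planted) if planted else float("nan")

    def cline_recall(self) -> float:
        """Fraction of planted introgressed loci (in the tested universe) called."""
        planted = set(self.truth.loci_of_class("adaptive_introgressed")) & set(self.universe)
        if not planted:
            return float("nan")
        return len(planted & set(self.calls.loci)) / len(planted)

    def enrichment_sign_ok(self) -> bool:
        """True when every freeze gradient exceeds pct95 and no water gradient does."""
        t = self.enrichment
        fr = t[t["class"] == "freeze"]
        wa = t[t["class"] == "water"]
        return bool(len(fr) and fr["exceed_95"].all() and not wa["exceed_95"].any())


def hybrid_freq_table(G_hyb: GenotypeMatrix, pmap: PopulationMap) -> FreqTable:
    """Allele-frequency table restricted to hybrid-zone populations."""
    F_all = allele_freqs(G_hyb, pmap)
    hyb_pops = pmap.populations_of_group("HYB")
    idx = [F_all.populations.index(p) for p in hyb_pops]
    return FreqTable(F_all.freq[idx], F_all.n[idx], hyb_pops, list(G_hyb.locus_ids))


def run_preset(
    seed: int,
    params: SimParams | None = None,
    subset_size: int = 1000,
    n_sim_envelope: int = 500,
    n_perm_fe: int = 2000,
) -> PresetRun:
    """One deterministic end-to-end analysis of a simulated hybrid zone.

    The generator seed is ``seed``; stage seeds are fixed offsets of it so
    the whole run is reproducible from the single argument.
    """
    params = params if params is not None else SimParams(seed=seed)
    G, pmap, env, truth = simulate_hybrid_zone(params)
    G_hyb = filter_biallelic(G, pmap, {"HYB"})
    G_par = filter_biallelic(G_hyb, pmap, {"P1", "P2"})
    universe = list(G_par.locus_ids)
    F_hyb = hybrid_freq_table(G_hyb, pmap)

    out_sets, _ = _gea.gea_scan(F_hyb, env, seed=seed, subset_size=subset_size)

    hyb_inds = pmap.individuals_of_groups(["HYB"])
    hi = _clines.hybrid_index(G_hyb, pmap, individuals=hyb_inds)
    f1, f2 = _clines.parental_freqs(G_hyb, pmap)
    fits = _clines.fit_genomic_clines(G_hyb, hi, f1, f2, individuals=hyb_inds,
                                      loci=universe)
    cols = G_hyb.locus_index(universe)
    ok = np.abs(f2[cols] - f1[cols]) >= 0.1
    pairs = np.column_stack([f1[cols][ok], f2[cols][ok]])
    flip = pairs[:, 1] < pairs[:, 0]
    pairs[flip] = 1.0 - pairs[flip]
    envelope = _clines.neutral_cline_envelope(
        fits.h, pairs, n_sim=n_sim_envelope, seed=seed + 200
    )
    calls = _clines.call_introgressed_snps(fits, envelope)

    uset = set(universe)
    sets_u = {
        g: _gea.OutlierSet(g, [l for l in s.loci if l in uset], s.bf_med)
        for g, s in out_sets.items()
    }
    table, summary = _enrich.enrichment_scan(
        sets_u, calls, universe, env, n_perm=n_perm_fe, seed=seed + 300
    )
    return PresetRun(params, G, pmap, env, truth, G_hyb, universe, F_hyb,
                     out_sets, hi, fits, calls, table, summary)
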