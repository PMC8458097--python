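"""Reproducible simulation studies: calibration, power and recovery of every
analysis stage against the synthetic generator's ground truth.

Each function generates its own data from a seed, runs the corresponding
analysis exactly as a user would, and returns the measured operating
characteristics.  These studies back both the test suite and the
reproduction script; their default sizes are chosen to finish on a single
CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from . import metabolome, scoring, zonation
from .composition import batch_credible_flags, hpd_interval
from .core import SignatureSet, normalize_log1p_cpm
from .crossomics import integrate_reactions
from .markers import moderated_de, state_markers
from .simulate import (
    SimConfig,
    default_sim_config,
    simulate_composition_table,
    simulate_crypt_experiment,
    simulate_reaction_network,
    simulate_spectra,
)

__all__ = [
    "composition_null_calibration",
    "composition_power",
    "hpd_normal_endpoints",
    "marker_recovery",
    "de_null_fdr",
    "cycle_region_recovery",
    "zonation_recovery",
    "peak_pipeline_recovery",
    "integration_recovery",
]

_BASE8 = np.array([0.25, 0.2, 0.15, 0.1, 0.1, 0.08, 0.07, 0.05])
_CLUSTERS8 = tuple(f"T{i}" for i in range(8))


def _composition_batches(n_datasets, shift_map, seed):
    x1, x2 = [], []
    for d in range(n_datasets):
        cfg = SimConfig(
            cells_per_sample=3000,
            clusters=_CLUSTERS8,
            baseline_composition=tuple(_BASE8 / _BASE8.sum()),
            shift_map=shift_map,
            seed=seed + d,
        )
        tab, cond = simulate_composition_table(cfg)
        x1.append(tab.values[(cond == "CD").values])
        x2.append(tab.values[(cond == "HFHSD").values])
    return np.asarray(x1), np.asarray(x2)


def composition_null_calibration(
    n_datasets: int = 200, seed: int = 0, n_iter: int = 1000,
    n_warmup: int = 400, n_chains: int = 2,
) -> float:
    """Fraction of (dataset, cell type) pairs flagged credible on null data.

    3v3 samples, 8 cell types, 3,000 cells per sample, no planted shift;
    reduced-iteration sampling (2,000 pooled post-warm-up draws/dataset).
    Nominal rate for a 95% HPD exclusion rule is 5%.
    """
    x1, x2 = _composition_batches(n_datasets, {}, seed * 7919 + 1)
    flags, _ = batch_credible_flags(
        x1, x2, n_iter=n_iter, n_warmup=n_warmup, n_chains=n_chains, seed=seed
    )
    return float(flags.mean())


def composition_power(
    n_datasets: int = 100, seed: int = 0, n_iter: int = 5000,
    n_warmup: int = 2000, n_chains: int = 4,
) -> float:
    """Detection rate of a planted x2 frequency shift on a 10%-baseline
    cell type (3v3 x 3,000 cells) at full default draws."""
    shifted = "T3"  # baseline frequency 0.10
    x1, x2 = _composition_batches(n_datasets, {shifted: 2.0}, seed * 7919 + 2)
    flags, _ = batch_credible_flags(
        x1, x2, n_iter=n_iter, n_warmup=n_warmup, n_chains=n_chains, seed=seed
    )
    return float(flags[:, list(_CLUSTERS8).index(shifted)].mean())


def hpd_normal_endpoints(seed: int = 0, n: int = 1_000_000) -> tuple[float, float]:
    """95% HPD endpoints of standard-normal draws (target: +/-1.96)."""
    rng = np.random.default_rng(seed)
    return hpd_interval(rng.standard_normal(n), 0.95)


def marker_recovery(seed: int = 0) -> dict:
    """Precision/recall of the pairwise Wilcoxon marker rule.

    3 states x ~300 cells, 2,000 genes, 20 planted markers per state at
    fold change 4; selection rule z > 5 and rank <= 1,200 in every test.
    """
    genes = [f"g{i:04d}" for i in range(2000)]
    marker_plan = {
        s: (genes[20 * k : 20 * (k + 1)], 4.0)
        for k, s in enumerate(["A", "B", "C"])
    }
    cfg = SimConfig(
        n_samples_per_condition=1,
        cells_per_sample=450,
        n_genes=2000,
        clusters=("A", "B", "C"),
        baseline_composition=(1 / 3, 1 / 3, 1 / 3),
        marker_plan=marker_plan,
        seed=seed,
    )
    ds = simulate_crypt_experiment(cfg)
    expr = normalize_log1p_cpm(ds.counts)
    table = state_markers(expr, ds.annotation.table["cluster"], z_min=5.0, top_n=1200)
    found = set(zip(table["state"], table["gene"]))
    planted = {
        (s, g) for s, (gs, _) in marker_plan.items() for g in gs
    }
    tp = len(found & planted)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(planted)
    return {"precision": precision, "recall": recall, "n_found": len(found)}


def de_null_fdr(
    n_runs: int = 100, seed: int = 0, n_genes: int = 1000, n_per_group: int = 100,
    fdr_max: float = 0.01, lfc_min: float = 0.1,
) -> float:
    """Mean false-discovery proportion on all-null, equal-variance data at
    the flag thresholds (FDR < 0.01 and |logFC| > 0.1)."""
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(2 * n_per_group)]
    gene_ids = [f"g{j}" for j in range(n_genes)]
    cond = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=cells)
    fdps = []
    from .core import ExpressionMatrix

    for _ in range(n_runs):
        values = rng.normal(1.0, 0.5, (2 * n_per_group, n_genes))
        expr = ExpressionMatrix(values, cells, gene_ids)
        res = moderated_de(expr, cond, fdr_max=fdr_max, lfc_min=lfc_min)
        n_disc = int(res["flagged"].sum())
        fdps.append(1.0 if n_disc > 0 else 0.0)  # every discovery is false
    return float(np.mean(fdps))


def cycle_region_recovery(seed: int = 0, cells_per_sample: int = 600,
                          n_genes: int = 1000) -> dict:
    """Recovery error (percentage points) of planted cycling fractions and
    proximal/distal mixtures on the default fully-featured simulation."""
    cfg = default_sim_config(seed=seed, cells_per_sample=cells_per_sample,
                            n_genes=n_genes)
    ds = simulate_crypt_experiment(cfg)
    expr = normalize_log1p_cpm(ds.counts)
    ann = ds.annotation.table
    cp = ds.truth["cycle_plan"]
    sv_s = scoring.signature_score(expr, SignatureSet("S", cp["s_genes"]), seed=seed)
    sv_g = scoring.signature_score(expr, SignatureSet("G2M", cp["g2m_genes"]), seed=seed)
    calls = scoring.classify_cell_cycle(sv_s, sv_g)
    cyc_clusters = list(cp["cycling_fraction"])
    mask = ann["cluster"].isin(cyc_clusters)
    recovered = float(calls.loc[mask.values, "cycling"].mean())
    truth_frac = float((ann.loc[mask, "phase_truth"] != "G1").mean())
    rp = ds.truth["regional_plan"]
    sv_p = scoring.signature_score(
        expr, SignatureSet("prox", rp["proximal_genes"]), seed=seed
    )
    sv_d = scoring.signature_score(
        expr, SignatureSet("dist", rp["distal_genes"]), seed=seed
    )
    region = scoring.classify_region(sv_p, sv_d)
    mix_clusters = list(rp["mixture"])
    mmask = ann["cluster"].isin(mix_clusters)
    rec_prox = float((region[mmask.values] == "proximal").mean())
    truth_prox = float((ann.loc[mmask, "region_truth"] == "proximal").mean())
    return {
        "cycling_recovered": recovered,
        "cycling_truth": truth_frac,
        "cycling_error_points": abs(recovered - truth_frac) * 100,
        "proximal_recovered": rec_prox,
        "proximal_truth": truth_prox,
        "proximal_error_points": abs(rec_prox - truth_prox) * 100,
    }


def zonation_recovery(seed: int = 0, cells_per_sample: int = 600,
                      n_genes: int = 1000) -> dict:
    """Spearman correlation of the pseudospace coordinate with the latent
    villus position, zone-size balance, and the landmark-swap symmetry."""
    cfg = default_sim_config(seed=seed, cells_per_sample=cells_per_sample,
                            n_genes=n_genes)
    ds = simulate_crypt_experiment(cfg)
    expr = normalize_log1p_cpm(ds.counts)
    ann = ds.annotation.table
    zp = ds.truth["zonation_plan"]
    keep = ann.index[ann["cluster"].isin(zp["clusters"])]
    frame = expr.to_frame().loc[keep]
    from .core import ExpressionMatrix

    sub = ExpressionMatrix(frame.values, frame.index.tolist(), frame.columns.tolist())
    bottom = SignatureSet("bottom", zp["bottom_genes"])
    tip = SignatureSet("tip", zp["tip_genes"])
    zeta = zonation.pseudospace_order(sub, bottom, tip, seed=seed)
    u = ann.loc[keep, "u_truth"].values
    rho = float(st.spearmanr(zeta.values, u).statistic)
    zones = zonation.partition_zones(zeta, k=5)
    sizes = zones.value_counts()
    flipped = zonation.pseudospace_order(sub, tip, bottom, seed=seed)
    sym_exact = bool(np.allclose(zeta.values + flipped.values, 1.0))
    return {
        "spearman": rho,
        "zone_size_spread": int(sizes.max() - sizes.min()),
        "swap_symmetry_exact": sym_exact,
        "n_cells": len(zeta),
    }


def peak_pipeline_recovery(n_seeds: int = 10, seed: int = 0) -> dict:
    """Recovery of 20 planted peaks (height >= 8 sigma) and cascade isotope
    exclusion over replicate noise seeds, plus the discriminative-mass
    counts against the designed ground truth (5 enriched + 3 depleted)."""
    mz = np.linspace(300.0, 330.0, 150001)  # 0.2 mDa spacing
    step = mz[1] - mz[0]
    rng = np.random.default_rng(seed)

    def well_separated(p):
        allp = np.sort(np.concatenate([p, p + 1.00335]))
        return np.min(np.diff(allp)) > 0.1

    pos = np.sort(rng.uniform(301.0, 327.0, 20))
    while not well_separated(pos):
        pos = np.sort(rng.uniform(301.0, 327.0, 20))
    heights = rng.uniform(10.0, 30.0, 20)  # mean-spectrum noise ~0.3 -> SNR >> 8
    plan = []
    n_enriched, n_depleted = 5, 3
    for i, (m, h) in enumerate(zip(pos, heights)):
        if i < n_enriched:
            hh = (h, 2.5 * h)
        elif i < n_enriched + n_depleted:
            hh = (2.5 * h, h)
        else:
            hh = (h, h)
        # narrow FT-ICR-like lines: FWHM ~0.9 mDa, just above the width floor
        plan.append({"mz": float(m), "heights": hh, "width": 0.0004})
    total_found = 0
    satellites_surviving = 0
    extra_peaks = 0
    pass_counts = []
    for s in range(n_seeds):
        ss = simulate_spectra(5, mz, plan, noise_sd=1.0, seed=seed * 1000 + s)
        peaks = metabolome.pick_peaks(ss)
        kept = metabolome.exclude_isotopes(peaks)
        dist = np.abs(kept["mz"].values[:, None] - pos[None, :])
        matched = dist.min(axis=1) <= 1.01 * step  # apex within one grid step
        total_found += int((dist.min(axis=0) <= 1.01 * step).sum())
        extra_peaks += int((~matched).sum())
        sat_dist = np.abs(kept["mz"].values[:, None] - (pos + 1.00335)[None, :])
        satellites_surviving += int((sat_dist.min(axis=1) <= 1.01 * step).sum())
        disc = metabolome.discriminative_masses(kept, groups=ss.groups)
        pass_counts.append((disc.attrs["n_enriched"], disc.attrs["n_depleted"]))
    return {
        "planted_per_seed": 20,
        "recovered_per_seed": total_found / n_seeds,
        "extra_peaks_total": extra_peaks,
        "satellites_surviving": satellites_surviving,
        "pass_counts": pass_counts,
        "designed_enriched": n_enriched,
        "designed_depleted": n_depleted,
    }


def integration_recovery(seed: int = 0) -> dict:
    """Exact flagging of planted doubly-significant reactions among 100."""
    rmap, _, _ = simulate_reaction_network(
        n_genes=300, n_reactions=100, n_metabolites=250, n_pathways=8,
        seed=seed, max_genes_per_reaction=2, max_mets_per_reaction=2,
    )
    rids = sorted(rmap)
    rng = np.random.default_rng(seed)
    planted = sorted(rng.choice(rids, size=5, replace=False))
    sig_genes = {rmap[r]["genes"][0] for r in planted}
    sig_mets = {rmap[r]["metabolites"][0] for r in planted}
    rep = integrate_reactions(sig_genes, sig_mets, rmap)
    expected = {
        r for r, spec in rmap.items()
        if set(spec["genes"]) & sig_genes and set(spec["metabolites"]) & sig_mets
    }
    return {
        "n_planted": len(planted),
        "n_expected": len(expected),
        "n_flagged": len(rep.affected_reactions),
        "exact_match": set(rep.affected_reactions) == expected,
        "planted_all_flagged": set(planted) <= set(rep.affected_reactions),
    }
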