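"""Config-driven pipeline runner.

A single structured YAML config lists the stages to run, their input
paths and thresholds, and one seed; every stage threshold defaults to the
study's printed value.  Outputs are CSV/JSON plus a machine-readable
manifest and a one-line-per-stage log; runs are deterministic given the
seed (no timestamps enter any output).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, crossomics, markers, metabolome, scoring, simulate, zonation
from .core import SignatureSet, ValidationError, normalize_log1p_cpm
from .io import (
    read_annotation,
    read_count_matrix,
    read_reaction_map,
    read_signatures,
    write_annotation,
    write_count_matrix,
)

__all__ = ["run_pipeline", "KNOWN_STAGES"]

KNOWN_STAGES = (
    "simulate",
    "composition",
    "score",
    "zonation",
    "markers",
    "de",
    "maldi",
    "integrate",
    "homa",
)


class _Run:
    """Mutable pipeline state shared between stages."""

    def __init__(self, config: dict, out_dir: Path) -> None:
        self.config = config
        self.out = out_dir
        self.seed = int(config.get("seed", 0))
        self.state: dict = {}
        self.manifest: list[dict] = []
        self.log: list[str] = []

    def params(self, stage: str) -> dict:
        return dict(self.config.get(stage, {}) or {})

    def record(self, stage: str, outputs: list[Path], note: str) -> None:
        self.manifest.append(
            {"stage": stage, "outputs": [str(p.relative_to(self.out)) for p in outputs]}
        )
        self.log.append(f"[{stage}] seed={self.seed} {note}")

    # ------------------------------------------------------------------
    def need_dataset(self, stage: str):
        """Counts + annotation, from the simulate stage or from file inputs."""
        if "dataset" in self.state:
            return self.state["dataset"]
        p = self.params(stage)
        if {"mtx", "cells", "genes", "annotation"} <= set(p):
            cm = read_count_matrix(p["mtx"], p["cells"], p["genes"],
                                   transposed=p.get("transposed"))
            ann = read_annotation(p["annotation"])
            ann.validate_against(cm)
            ds = simulate.SyntheticDataset(cm, ann, {})
            self.state["dataset"] = ds
            return ds
        raise ValidationError(
            f"stage {stage!r} needs counts: run 'simulate' first or supply "
            "mtx/cells/genes/annotation paths in its config section"
        )

    def need_expression(self, stage: str):
        if "expr" not in self.state:
            ds = self.need_dataset(stage)
            scale = float(self.config.get("normalize", {}).get("scale", 1e4))
            self.state["expr"] = normalize_log1p_cpm(ds.counts, scale=scale)
        return self.state["expr"]

    def truth_signature(self, plan_key: str, gene_key: str, name: str) -> SignatureSet:
        ds = self.state.get("dataset")
        if ds is None or not ds.truth or not ds.truth.get(plan_key):
            raise ValidationError(
                f"no {plan_key} available; supply a signature file instead"
            )
        return SignatureSet(name, list(ds.truth[plan_key][gene_key]))


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_simulate(run: _Run) -> None:
    p = run.params("simulate")
    cfg = simulate.default_sim_config(seed=run.seed, **p)
    ds = simulate.simulate_crypt_experiment(cfg)
    run.state["dataset"] = ds
    out = run.out / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(ds.counts, out / "counts.mtx", out / "cells.tsv", out / "genes.tsv")
    write_annotation(ds.annotation, out / "annotation.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    run.record(
        "simulate",
        [out / "counts.mtx", out / "annotation.tsv", out / "truth.json"],
        f"cells={ds.counts.n_cells} genes={ds.counts.n_genes}",
    )


def _stage_composition(run: _Run) -> None:
    p = run.params("composition")
    if "table" in p:
        tab = pd.read_csv(p["table"], index_col=0)
        cond = tab.pop("condition")
        model = composition.DirichletMultinomialModel(tab, cond)
    else:
        ds = run.need_dataset("composition")
        model = composition.DirichletMultinomialModel.from_annotation(ds.annotation)
    res = model.fit(
        n_iter=int(p.get("n_iter", 5000)),
        n_warmup=int(p.get("n_warmup", 2000)),
        n_chains=int(p.get("n_chains", 4)),
        seed=run.seed,
    )
    rep = res.shift_report(mass=float(p.get("mass", 0.95)))
    run.out.mkdir(parents=True, exist_ok=True)
    csv = run.out / "composition_shifts.csv"
    rep.to_csv(csv, index_label="cell_type")
    js = run.out / "composition_posterior.json"
    with open(js, "w") as fh:
        json.dump(
            {
                "posterior_mean": res.posterior_mean().round(10).to_dict(),
                "rhat_max": max(res.draws.rhat.values()),
                "credible": rep.loc[rep["credible"]].index.tolist(),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    run.record(
        "composition", [csv, js],
        f"samples={model.table.shape[0]} types={model.table.shape[1]} "
        f"iters={p.get('n_iter', 5000)} mass={p.get('mass', 0.95)}",
    )


def _signatures_for(run: _Run, stage: str, keys: dict[str, tuple[str, str]]) -> dict:
    p = run.params(stage)
    if "signatures" in p:
        sigs = read_signatures(p["signatures"])
        missing = [name for name in keys if name not in sigs]
        if missing:
            raise ValidationError(f"signature file lacks sets {missing}")
        return {name: sigs[name] for name in keys}
    return {
        name: run.truth_signature(plan, key, name)
        for name, (plan, key) in keys.items()
    }


def _stage_score(run: _Run) -> None:
    p = run.params("score")
    expr = run.need_expression("score")
    ds = run.state["dataset"]
    sigs = _signatures_for(
        run, "score",
        {
            "S": ("cycle_plan", "s_genes"),
            "G2M": ("cycle_plan", "g2m_genes"),
            "proximal": ("regional_plan", "proximal_genes"),
            "distal": ("regional_plan", "distal_genes"),
        },
    )
    kw = dict(
        n_bins=int(p.get("n_bins", 25)),
        n_controls=int(p.get("n_controls", 50)),
        seed=run.seed,
    )
    s = scoring.signature_score(expr, sigs["S"], **kw)
    g2m = scoring.signature_score(expr, sigs["G2M"], **kw)
    prox = scoring.signature_score(expr, sigs["proximal"], **kw)
    dist = scoring.signature_score(expr, sigs["distal"], **kw)
    cycle = scoring.classify_cell_cycle(s, g2m)
    region = scoring.classify_region(prox, dist)
    per_cell = cycle.copy()
    per_cell["score_proximal"] = prox.scores
    per_cell["score_distal"] = dist.scores
    per_cell["region"] = region
    run.out.mkdir(parents=True, exist_ok=True)
    cell_csv = run.out / "scores_per_cell.csv"
    per_cell.to_csv(cell_csv, index_label="cell_id")
    props = scoring.region_proportions(region, ds.annotation)
    prop_csv = run.out / "region_proportions.csv"
    props.to_csv(prop_csv, index=False)
    run.state["cycle"] = cycle
    run.state["scores"] = {"S": s, "G2M": g2m}
    run.record(
        "score", [cell_csv, prop_csv],
        f"cells={len(per_cell)} bins={kw['n_bins']} controls={kw['n_controls']}",
    )


def _stage_zonation(run: _Run) -> None:
    p = run.params("zonation")
    expr = run.need_expression("zonation")
    ds = run.state["dataset"]
    sigs = _signatures_for(
        run, "zonation",
        {
            "bottom": ("zonation_plan", "bottom_genes"),
            "tip": ("zonation_plan", "tip_genes"),
        },
    )
    cells = p.get("clusters")
    if cells is None and ds.truth.get("zonation_plan"):
        cells = ds.truth["zonation_plan"]["clusters"]
    ann = ds.annotation.table
    keep = ann.index[ann["cluster"].isin(cells)] if cells else ann.index
    sub = expr.to_frame().loc[keep]
    sub_expr = type(expr)(sub.values, sub.index.tolist(), sub.columns.tolist(),
                          scale=expr.scale)
    zeta = zonation.pseudospace_order(sub_expr, sigs["bottom"], sigs["tip"], seed=run.seed)
    res = zonation.zonation_profiles(
        sub_expr, zeta, ann.loc[keep, "condition"], k=int(p.get("zones", 5)),
    )
    run.out.mkdir(parents=True, exist_ok=True)
    cell_csv = run.out / "zonation_per_cell.csv"
    res.cells.to_csv(cell_csv, index_label="cell_id")
    prof_csv = run.out / "zonation_profiles.csv"
    res.profiles.to_csv(prof_csv, index=False)
    run.record("zonation", [cell_csv, prof_csv], f"cells={len(res.cells)} zones={p.get('zones', 5)}")


def _stage_markers(run: _Run) -> None:
    p = run.params("markers")
    expr = run.need_expression("markers")
    ds = run.state["dataset"]
    table = markers.state_markers(
        expr,
        ds.annotation.table["cluster"],
        z_min=float(p.get("z_min", 5.0)),
        top_n=int(p.get("top_n", 1200)),
    )
    run.out.mkdir(parents=True, exist_ok=True)
    csv = run.out / "state_markers.csv"
    table.to_csv(csv, index=False)
    run.record(
        "markers", [csv],
        f"states={ds.annotation.table['cluster'].nunique()} "
        f"z_min={p.get('z_min', 5.0)} top_n={p.get('top_n', 1200)}",
    )


def _stage_de(run: _Run) -> None:
    p = run.params("de")
    expr = run.need_expression("de")
    ds = run.state["dataset"]
    res = markers.moderated_de(
        expr,
        condition=ds.annotation.table["condition"],
        strata=ds.annotation.table["cluster"],
        fdr_max=float(p.get("fdr_max", 0.01)),
        lfc_min=float(p.get("lfc_min", 0.1)),
    )
    run.out.mkdir(parents=True, exist_ok=True)
    csv = run.out / "moderated_de.csv"
    res.to_csv(csv, index=False)
    run.state["de"] = res
    run.record(
        "de", [csv],
        f"genes={expr.n_genes} fdr<{p.get('fdr_max', 0.01)} "
        f"|logFC|>{p.get('lfc_min', 0.1)} flagged={int(res['flagged'].sum())}",
    )


def _stage_maldi(run: _Run) -> None:
    p = run.params("maldi")
    if "spectra" in p:
        raw = pd.read_csv(p["spectra"])
        groups = list(p["groups"])
        spectra = simulate.SpectrumSet(
            mz=raw.iloc[:, 0].values,
            intensities=raw.iloc[:, 1:].values.T,
            groups=groups,
        )
    else:
        mz = np.linspace(
            float(p.get("mz_min", 300.0)), float(p.get("mz_max", 340.0)),
            int(p.get("grid", 200001)),
        )
        rng = np.random.default_rng(run.seed + 7)
        n_peaks = int(p.get("n_peaks", 20))
        pos = np.sort(rng.uniform(mz[0] + 2, mz[-1] - 2, n_peaks))
        plan = []
        for i, m in enumerate(pos):
            h1 = float(rng.uniform(10, 30))
            h2 = h1 * (2.5 if i % 4 == 0 else 1.0)
            plan.append({"mz": float(m), "heights": (h1, h2), "width": 0.0004})
        spectra = simulate.simulate_spectra(
            int(p.get("n_per_group", 5)), mz, plan,
            noise_sd=float(p.get("noise_sd", 1.0)), seed=run.seed + 8,
        )
    peaks = metabolome.pick_peaks(
        spectra,
        min_width=float(p.get("min_width", 0.0005)),
        snr_min=float(p.get("snr_min", 4.0)),
        intensity_frac=float(p.get("intensity_frac", 0.0001)),
    )
    peaks = metabolome.exclude_isotopes(peaks)
    disc = metabolome.discriminative_masses(
        peaks, groups=spectra.groups,
        fc_min=float(p.get("fc_min", 2.0)), p_max=float(p.get("p_max", 0.05)),
    )
    run.out.mkdir(parents=True, exist_ok=True)
    peaks_csv = run.out / "peaks.csv"
    peaks.to_csv(peaks_csv, index=False)
    disc_csv = run.out / "discriminative_masses.csv"
    disc.to_csv(disc_csv, index=False)
    run.state["maldi"] = disc
    run.record(
        "maldi", [peaks_csv, disc_csv],
        f"peaks={len(peaks)} pass={disc.attrs['n_pass']} "
        f"(enriched={disc.attrs['n_enriched']} depleted={disc.attrs['n_depleted']})",
    )


def _stage_integrate(run: _Run) -> None:
    p = run.params("integrate")
    if "reaction_map" in p:
        rmap = read_reaction_map(p["reaction_map"])
    else:
        rmap, _, _ = simulate.simulate_reaction_network(seed=run.seed + 11)
    sig_genes = set(p.get("sig_genes", []))
    sig_mets = set(p.get("sig_metabolites", []))
    if not sig_genes and "de" in run.state:
        sig_genes = set(run.state["de"].loc[run.state["de"]["flagged"], "gene"])
    report = crossomics.integrate_reactions(sig_genes, sig_mets, rmap)
    run.out.mkdir(parents=True, exist_ok=True)
    r_csv = run.out / "integration_reactions.csv"
    report.reactions.to_csv(r_csv, index=False)
    p_csv = run.out / "integration_pathways.csv"
    report.pathways.to_csv(p_csv, index=False)
    run.record(
        "integrate", [r_csv, p_csv],
        f"reactions={len(report.reactions)} affected={len(report.affected_reactions)}",
    )


def _stage_homa(run: _Run) -> None:
    p = run.params("homa")
    if "glucose" not in p or "insulin" not in p:
        raise ValidationError("homa stage needs glucose and insulin values")
    ir, beta = crossomics.homa_indices(float(p["glucose"]), float(p["insulin"]))
    run.out.mkdir(parents=True, exist_ok=True)
    js = run.out / "homa.json"
    with open(js, "w") as fh:
        json.dump({"HOMA_IR": ir, "HOMA_beta": beta}, fh, indent=1, sort_keys=True)
    run.record("homa", [js], f"glucose={p['glucose']} insulin={p['insulin']}")


_STAGES = {
    "simulate": _stage_simulate,
    "composition": _stage_composition,
    "score": _stage_score,
    "zonation": _stage_zonation,
    "markers": _stage_markers,
    "de": _stage_de,
    "maldi": _stage_maldi,
    "integrate": _stage_integrate,
    "homa": _stage_homa,
}


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run the stages listed in a YAML config; returns the output directory.

    Validates the stage list (and stage-local input requirements where
    possible) before any computation starts; writes ``manifest.json`` and
    ``pipeline.log`` alongside the stage outputs.
    """
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    stages = config.get("stages", [])
    if not stages:
        raise ValidationError("config lists no stages")
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValidationError(f"unknown stages {unknown}; known: {list(_STAGES)}")
    # upstream checks before any computation
    needs_counts = {"composition", "score", "zonation", "markers", "de"}
    have_sim = False
    for s in stages:
        if s == "simulate":
            have_sim = True
        if s in needs_counts and not have_sim:
            p = dict(config.get(s, {}) or {})
            file_ok = {"mtx", "cells", "genes", "annotation"} <= set(p) or "table" in p
            if not file_ok:
                raise ValidationError(
                    f"stage {s!r} has no upstream counts: add 'simulate' before "
                    "it or supply input paths in its config section"
                )
    out = Path(out_dir or config.get("output_dir", "cryptomics_results"))
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(config, out)
    for s in stages:
        _STAGES[s](run)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": run.seed, "stages": run.manifest}, fh, indent=1, sort_keys=True)
    (out / "pipeline.log").write_text("\n".join(run.log) + "\n")
    return out
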