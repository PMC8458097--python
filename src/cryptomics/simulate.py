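"""Seeded generators of synthetic crypt-cell experiments, mass spectra and
reaction networks.

The single-cell generator emulates the structure of a two-diet crypt
scRNA-seq design: 2 conditions x 3 replicate mice, ~10 cell clusters whose
per-sample abundances are Dirichlet-multinomial around a condition
composition (optionally with planted multiplicative frequency shifts),
gamma-Poisson (negative binomial) gene counts with log-normal library
sizes, cluster marker programs, proximal/distal regional programs,
S/G2M cell-cycle programs, and a latent villus-axis position u in [0,1]
for enterocyte-type cells with log-linear landmark gradients.

Every generator is deterministic given its seed, and each returns a truth
manifest sufficient to compute the expected value of downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CellAnnotation, CountMatrix, ValidationError

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "SpectrumSet",
    "default_sim_config",
    "simulate_crypt_experiment",
    "simulate_composition_table",
    "simulate_spectra",
    "simulate_reaction_network",
]

ISOTOPE_SPACING = 1.00335  # Da, 13C - 12C

DEFAULT_CLUSTERS = (
    "ISC",
    "EnterocyteProgenitor",
    "Enterocyte",
    "GobletProgenitor",
    "Goblet",
    "EEP_Sox4",
    "EEP_Ngn3",
    "EEC",
    "Tuft",
    "Unassigned",
)
DEFAULT_COMPOSITION = (0.22, 0.18, 0.15, 0.08, 0.10, 0.05, 0.05, 0.08, 0.04, 0.05)


@dataclass
class SimConfig:
    """Design of a synthetic crypt experiment.

    Attributes
    ----------
    clusters, baseline_composition
        Cluster names and their baseline frequency simplex (condition 1).
    shift_map
        cluster -> multiplicative frequency change applied in condition 2
        (renormalized afterwards).  Empty map = null experiment.
    composition_concentration
        Dirichlet-multinomial concentration governing replicate-to-replicate
        compositional overdispersion (larger = tighter replicates).
    marker_plan
        cluster -> (marker gene names, fold change) planted markers.
    regional_plan
        dict with 'proximal_genes', 'distal_genes', 'fold',
        'mixture' (cluster -> proximal fraction; clusters absent are
        assigned proximal deterministically).
    cycle_plan
        dict with 's_genes', 'g2m_genes', 'fold',
        'cycling_fraction' (cluster -> fraction of cycling cells).
    zonation_plan
        dict with 'clusters' (which clusters carry a latent villus axis),
        'tip_genes', 'bottom_genes', 'slope' (log-fold change across the
        full axis; tip genes increase with u, bottom genes decrease).
    """

    n_samples_per_condition: int = 3
    cells_per_sample: int = 1000
    n_genes: int = 2000
    clusters: Sequence[str] = DEFAULT_CLUSTERS
    baseline_composition: Sequence[float] = DEFAULT_COMPOSITION
    shift_map: dict[str, float] = field(default_factory=dict)
    composition_concentration: float = 200.0
    conditions: tuple[str, str] = ("CD", "HFHSD")
    marker_plan: dict[str, tuple[list[str], float]] = field(default_factory=dict)
    regional_plan: dict | None = None
    cycle_plan: dict | None = None
    zonation_plan: dict | None = None
    dispersion: float = 0.3
    base_mean_log_mu: float = -0.7
    base_mean_log_sd: float = 1.0
    libsize_log_mu: float = 0.0
    libsize_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.baseline_composition, dtype=float)
        if len(comp) != len(self.clusters):
            raise ValidationError("composition length != number of clusters")
        if not np.isclose(comp.sum(), 1.0, atol=1e-8):
            raise ValidationError("baseline composition must sum to 1")
        if (comp < 0).any():
            raise ValidationError("negative baseline frequencies")
        for k, f in self.shift_map.items():
            if k not in self.clusters:
                raise ValidationError(f"shift on unknown cluster {k!r}")
            if f < 0:
                raise ValidationError(f"negative frequency multiplier for {k!r}")

    def condition_composition(self, condition_index: int) -> np.ndarray:
        comp = np.asarray(self.baseline_composition, dtype=float).copy()
        if condition_index == 1:
            for k, f in self.shift_map.items():
                comp[list(self.clusters).index(k)] *= f
            if comp.sum() <= 0:
                raise ValidationError("shift map annihilates the composition")
            comp = comp / comp.sum()
        return comp


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    annotation: CellAnnotation
    truth: dict


def default_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A fully-featured default design: planted markers for every cluster,
    regional and cycle programs, and a villus-axis gradient in enterocytes."""
    n_genes = int(overrides.pop("n_genes", 2000))
    if n_genes < 300:
        raise ValidationError(
            "default_sim_config needs n_genes >= 300 to host its gene programs"
        )
    genes = [f"g{i:04d}" for i in range(n_genes)]
    clusters = list(DEFAULT_CLUSTERS)
    marker_plan = {}
    cursor = 0
    for cl in clusters:
        marker_plan[cl] = (genes[cursor : cursor + 10], 4.0)
        cursor += 10
    regional_plan = {
        "proximal_genes": genes[cursor : cursor + 20],
        "distal_genes": genes[cursor + 20 : cursor + 40],
        "fold": 4.0,
        "baseline": 0.3,
        # every cluster carries both identities; the focus lineages lean 70/30
        "mixture": {
            cl: (0.7 if cl in ("ISC", "Enterocyte", "Goblet") else 0.5)
            for cl in clusters
        },
    }
    cursor += 40
    # cell-cycle programs mimic real S/G2M genes: many genes, near-silent
    # outside cycling cells, strongly induced in them
    cycle_plan = {
        "s_genes": genes[cursor : cursor + 50],
        "g2m_genes": genes[cursor + 50 : cursor + 100],
        "fold": 80.0,
        "baseline": 0.05,
        "cycling_fraction": {
            "ISC": 0.3,
            "EnterocyteProgenitor": 0.3,
            "GobletProgenitor": 0.2,
            "EEP_Sox4": 0.2,
            "EEP_Ngn3": 0.2,
        },
    }
    cursor += 100
    zonation_plan = {
        "clusters": ["Enterocyte"],
        "tip_genes": genes[cursor : cursor + 10],
        "bottom_genes": genes[cursor + 10 : cursor + 20],
        "slope": 3.0,  # ~20-fold bottom-to-tip, as for strong zonation markers
        "baseline": 2.0,  # landmark genes are among the most abundant transcripts
    }
    cfg = SimConfig(
        n_genes=n_genes,
        marker_plan=marker_plan,
        regional_plan=regional_plan,
        cycle_plan=cycle_plan,
        zonation_plan=zonation_plan,
        seed=seed,
        **overrides,
    )
    return cfg


def _sample_cluster_counts(
    rng: np.random.Generator, n_cells: int, comp: np.ndarray, concentration: float
) -> np.ndarray:
    """Dirichlet-multinomial draw of per-cluster cell counts for one sample."""
    p = rng.dirichlet(concentration * comp)
    return rng.multinomial(n_cells, p)


def simulate_composition_table(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Cluster-count table only (no gene expression): samples x clusters plus
    a per-sample condition factor.  The fast path for compositional studies."""
    rng = rng or np.random.default_rng(config.seed)
    rows, conds, names = [], [], []
    for ci, cond in enumerate(config.conditions):
        comp = config.condition_composition(ci)
        for s in range(config.n_samples_per_condition):
            rows.append(
                _sample_cluster_counts(
                    rng, config.cells_per_sample, comp, config.composition_concentration
                )
            )
            conds.append(cond)
            names.append(f"{cond}_{s + 1}")
    table = pd.DataFrame(rows, index=names, columns=list(config.clusters))
    return table, pd.Series(conds, index=names, name="condition")


def simulate_crypt_experiment(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic crypt-cell experiment.

    Per sample, cluster abundances are Dirichlet-multinomial around the
    condition composition; per cell, gene counts are gamma-Poisson with a
    log-normal library-size factor and multiplicative per-cell programs
    (cluster markers, regional identity, cell-cycle phase, villus axis).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    clusters = list(config.clusters)

    # gene baseline means (linear scale) and dispersions
    base_mean = np.exp(
        rng.normal(config.base_mean_log_mu, config.base_mean_log_sd, config.n_genes)
    )
    alpha = np.full(config.n_genes, config.dispersion)

    # program plans may re-centre the baseline of their genes (e.g. cycle
    # genes are near-silent outside cycling cells); baselines keep a
    # log-normal spread so program genes land in many expression bins
    for plan, keys in (
        (config.regional_plan, ("proximal_genes", "distal_genes")),
        (config.cycle_plan, ("s_genes", "g2m_genes")),
        (config.zonation_plan, ("tip_genes", "bottom_genes")),
    ):
        if plan and plan.get("baseline") is not None:
            for key in keys:
                idx = [gene_pos[g] for g in plan[key] if g in gene_pos]
                base_mean[idx] = plan["baseline"] * np.exp(
                    rng.normal(0.0, 0.5, len(idx))
                )

    def plan_idx(names: Sequence[str]) -> np.ndarray:
        idx = [gene_pos[g] for g in names if g in gene_pos]
        if len(idx) != len(names):
            missing = [g for g in names if g not in gene_pos]
            raise ValidationError(f"plan references unknown genes {missing[:5]}")
        return np.asarray(idx, dtype=int)

    records: list[dict] = []
    blocks: list[sp.csr_matrix] = []
    cell_counter = 0
    for ci, cond in enumerate(config.conditions):
        comp = config.condition_composition(ci)
        for s in range(config.n_samples_per_condition):
            sample = f"{cond}_{s + 1}"
            ncl = _sample_cluster_counts(
                rng, config.cells_per_sample, comp, config.composition_concentration
            )
            for k, cl in enumerate(clusters):
                n = int(ncl[k])
                if n == 0:
                    continue
                # per-cell multiplicative fold matrix, cells x genes
                fold = np.ones((n, config.n_genes))
                if cl in config.marker_plan:
                    mg, fc = config.marker_plan[cl]
                    fold[:, plan_idx(mg)] *= fc
                region = np.full(n, "proximal", dtype=object)
                if config.regional_plan:
                    rp = config.regional_plan
                    frac = rp.get("mixture", {}).get(cl, 1.0)
                    is_prox = rng.random(n) < frac
                    region = np.where(is_prox, "proximal", "distal")
                    fold[np.ix_(is_prox, plan_idx(rp["proximal_genes"]))] *= rp["fold"]
                    fold[np.ix_(~is_prox, plan_idx(rp["distal_genes"]))] *= rp["fold"]
                phase = np.full(n, "G1", dtype=object)
                if config.cycle_plan:
                    cp = config.cycle_plan
                    cfrac = cp.get("cycling_fraction", {}).get(cl, 0.0)
                    cycling = rng.random(n) < cfrac
                    in_s = cycling & (rng.random(n) < 0.5)
                    in_g2m = cycling & ~in_s
                    phase[in_s] = "S"
                    phase[in_g2m] = "G2M"
                    fold[np.ix_(in_s, plan_idx(cp["s_genes"]))] *= cp["fold"]
                    fold[np.ix_(in_g2m, plan_idx(cp["g2m_genes"]))] *= cp["fold"]
                u = np.full(n, np.nan)
                if config.zonation_plan and cl in config.zonation_plan["clusters"]:
                    zp = config.zonation_plan
                    u = rng.uniform(0.0, 1.0, n)
                    # log-linear landmark gradients, centred at u = 0.5
                    grad = np.exp(zp["slope"] * (u - 0.5))
                    fold[:, plan_idx(zp["tip_genes"])] *= grad[:, None]
                    fold[:, plan_idx(zp["bottom_genes"])] /= grad[:, None]

                lib = np.exp(
                    rng.normal(config.libsize_log_mu, config.libsize_log_sd, n)
                )
                mu = lib[:, None] * base_mean[None, :] * fold
                # gamma-Poisson: var = mu + alpha mu^2
                shape = 1.0 / alpha[None, :]
                lam = rng.gamma(shape, mu / shape)
                block = rng.poisson(lam)
                blocks.append(sp.csr_matrix(block))
                for j in range(n):
                    records.append(
                        {
                            "cell_id": f"c{cell_counter + j:06d}",
                            "sample": sample,
                            "condition": cond,
                            "cluster": cl,
                            "region_truth": region[j],
                            "phase_truth": phase[j],
                            "u_truth": u[j],
                        }
                    )
                cell_counter += n

    counts = sp.csr_matrix(sp.vstack(blocks)) if blocks else sp.csr_matrix((0, config.n_genes))
    ann = pd.DataFrame.from_records(records).set_index("cell_id")
    matrix = CountMatrix(
        counts=counts, cell_ids=ann.index.tolist(), gene_ids=genes
    )
    truth = {
        "clusters": clusters,
        "baseline_composition": list(map(float, config.baseline_composition)),
        "shift_map": dict(config.shift_map),
        "marker_plan": {
            k: {"genes": list(v[0]), "fold": float(v[1])}
            for k, v in config.marker_plan.items()
        },
        "regional_plan": config.regional_plan,
        "cycle_plan": config.cycle_plan,
        "zonation_plan": config.zonation_plan,
        "seed": config.seed,
    }
    return SyntheticDataset(
        counts=matrix, annotation=CellAnnotation(ann), truth=truth
    )


# ---------------------------------------------------------------------------
# Mass spectra


@dataclass
class SpectrumSet:
    """Per-sample intensity vectors on a shared, strictly increasing m/z grid."""

    mz: np.ndarray
    intensities: np.ndarray  # samples x grid points
    groups: list[str]

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if np.any(np.diff(self.mz) <= 0):
            raise ValidationError("m/z grid must be strictly increasing")
        if self.intensities.shape[1] != self.mz.size:
            raise ValidationError("intensity columns != grid length")
        if len(self.groups) != self.intensities.shape[0]:
            raise ValidationError("group labels != number of spectra")

    def mean_spectrum(self) -> np.ndarray:
        return self.intensities.mean(axis=0)


def simulate_spectra(
    n_per_group: int,
    mz_grid: np.ndarray,
    peak_plan: list[dict],
    noise_sd: float = 1.0,
    seed: int = 0,
    isotope_ratio: float = 0.3,
    groups: tuple[str, str] = ("CD", "HFHSD"),
) -> SpectrumSet:
    """Sum-of-Gaussians spectra with white noise and isotope satellites.

    ``peak_plan`` entries: {'mz': float, 'heights': (h_group1, h_group2),
    'width': float (Gaussian sigma in Da), 'isotope': bool (default True)}.
    Each planted monoisotopic peak gains a satellite at +1.00335 Da scaled
    by ``isotope_ratio``.
    """
    mz = np.asarray(mz_grid, dtype=float)
    if np.any(np.diff(mz) <= 0):
        raise ValidationError("m/z grid must be strictly increasing")
    for pk in peak_plan:
        if not (mz[0] <= pk["mz"] <= mz[-1]):
            raise ValidationError(f"peak at m/z {pk['mz']} outside grid")
    rng = np.random.default_rng(seed)
    labels = [groups[0]] * n_per_group + [groups[1]] * n_per_group
    spectra = np.zeros((2 * n_per_group, mz.size))
    for i, grp_idx in enumerate([0] * n_per_group + [1] * n_per_group):
        for pk in peak_plan:
            h = float(pk["heights"][grp_idx])
            w = float(pk.get("width", 0.01))
            spectra[i] += h * np.exp(-0.5 * ((mz - pk["mz"]) / w) ** 2)
            if pk.get("isotope", True):
                sat_mz = pk["mz"] + ISOTOPE_SPACING
                if sat_mz <= mz[-1]:
                    spectra[i] += (
                        isotope_ratio
                        * h
                        * np.exp(-0.5 * ((mz - sat_mz) / w) ** 2)
                    )
        if noise_sd > 0:
            spectra[i] += rng.normal(0.0, noise_sd, mz.size)
    np.clip(spectra, 0.0, None, out=spectra)
    return SpectrumSet(mz=mz, intensities=spectra, groups=labels)


# ---------------------------------------------------------------------------
# Reaction network


def simulate_reaction_network(
    n_genes: int = 50,
    n_reactions: int = 100,
    n_metabolites: int = 60,
    n_pathways: int = 8,
    seed: int = 0,
    max_genes_per_reaction: int = 3,
    max_mets_per_reaction: int = 3,
) -> tuple[dict, dict, pd.DataFrame]:
    """Random gene<->reaction<->metabolite incidence with a pathway partition.

    Returns
    -------
    reaction_map
        {reaction_id: {'genes': [...], 'metabolites': [...], 'pathway': id}}
    pathway_graph
        {pathway_id: {'nodes': [metabolites], 'edges': [[m1, m2], ...]}} —
        metabolites of a reaction are pairwise adjacent.
    metabolite_db
        DataFrame (id, name, exact_mass) usable for ppm annotation.
    """
    if min(n_genes, n_reactions, n_metabolites, n_pathways) < 1:
        raise ValidationError("all network sizes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:03d}" for i in range(n_genes)]
    mets = [f"met{i:03d}" for i in range(n_metabolites)]
    pathways = [f"pw{i:02d}" for i in range(n_pathways)]
    reaction_map: dict[str, dict] = {}
    pathway_nodes: dict[str, set] = {p: set() for p in pathways}
    pathway_edges: dict[str, set] = {p: set() for p in pathways}
    for r in range(n_reactions):
        rid = f"rxn{r:03d}"
        ng = int(rng.integers(1, max_genes_per_reaction + 1))
        nm = int(rng.integers(1, max_mets_per_reaction + 1))
        rgenes = sorted(rng.choice(genes, size=min(ng, n_genes), replace=False))
        rmets = sorted(rng.choice(mets, size=min(nm, n_metabolites), replace=False))
        pw = pathways[r % n_pathways]
        reaction_map[rid] = {
            "genes": [str(g) for g in rgenes],
            "metabolites": [str(m) for m in rmets],
            "pathway": pw,
        }
        pathway_nodes[pw].update(rmets)
        for a in rmets:
            for b in rmets:
                if a < b:
                    pathway_edges[pw].add((str(a), str(b)))
    pathway_graph = {
        p: {
            "nodes": sorted(map(str, pathway_nodes[p])),
            "edges": [list(e) for e in sorted(pathway_edges[p])],
        }
        for p in pathways
    }
    masses = np.sort(rng.uniform(60.0, 990.0, n_metabolites))
    metabolite_db = pd.DataFrame(
        {
            "id": mets,
            "name": [f"metabolite {i}" for i in range(n_metabolites)],
            "exact_mass": masses,
        }
    )
    return reaction_map, pathway_graph, metabolite_db
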