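"""Gene-signature scoring and rule-based cell classification.

The score of a signature in a cell is the mean expression of its genes
minus the mean expression of a control pool drawn from expression-matched
bins: genes are binned by their dataset-average expression into ``n_bins``
equal-size bins and ``n_controls`` control genes are drawn from the bin of
each signature gene.  Scores therefore centre on zero for signatures that
behave like background.

Classification rules:
* cell cycle — G1 if neither the S nor the G2M score is positive, else the
  phase with the larger score (ties to G2M);
* regional identity — proximal if the proximal score exceeds the distal
  score, else distal (ties to distal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellAnnotation, ExpressionMatrix, SignatureSet, ValidationError

__all__ = [
    "ScoreVector",
    "signature_score",
    "classify_cell_cycle",
    "classify_region",
    "region_proportions",
    "cycle_correlated_genes",
]


@dataclass
class ScoreVector:
    """Per-cell signature score with the control-draw metadata."""

    scores: pd.Series  # indexed by cell_id
    signature: str
    n_bins: int
    n_controls: int
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.values)):
            raise ValidationError("non-finite scores")


def signature_score(
    expr: ExpressionMatrix,
    signature: SignatureSet,
    n_bins: int = 25,
    n_controls: int = 50,
    seed: int = 0,
) -> ScoreVector:
    """Expression-bin-controlled signature score per cell.

    Missing signature genes are dropped with a warning; an empty overlap is
    an error.  Deterministic given ``seed``.
    """
    matched = signature.matched(expr.gene_ids)
    if len(matched.genes) < len(signature.genes):
        dropped = sorted(set(signature.genes) - set(matched.genes))
        warnings.warn(
            f"signature {signature.name!r}: {len(dropped)} genes not in matrix "
            f"(e.g. {dropped[:3]})",
            UserWarning,
            stacklevel=2,
        )
    sig_idx = expr.gene_index(matched.genes)

    avg = expr.values.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    # equal-size bins over the average-expression ranking
    bin_of = np.empty(expr.n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(expr.n_genes) * n_bins) // expr.n_genes, n_bins - 1
    )
    genes_in_bin = [np.flatnonzero(bin_of == b) for b in range(n_bins)]

    rng = np.random.default_rng(seed)
    sig_set = set(sig_idx.tolist())
    control_idx: list[np.ndarray] = []
    for gi in sig_idx:
        pool = genes_in_bin[bin_of[gi]]
        # the signature's own genes never serve as their controls
        pool = pool[~np.isin(pool, sig_idx)]
        if pool.size == 0:  # bin exhausted by the signature: widen to universe
            pool = np.setdiff1d(np.arange(expr.n_genes), sig_idx)
        if pool.size == 0:
            raise ValidationError("no control genes outside the signature")
        take = rng.choice(pool, size=min(n_controls, pool.size), replace=False)
        control_idx.append(take)
    ctrl = np.unique(np.concatenate(control_idx))

    sig_mean = expr.values[:, sig_idx].mean(axis=1)
    ctrl_mean = expr.values[:, ctrl].mean(axis=1)
    scores = pd.Series(sig_mean - ctrl_mean, index=expr.cell_ids, name=signature.name)
    return ScoreVector(scores, signature.name, n_bins, n_controls, seed)


def _aligned(a: pd.Series, b: pd.Series) -> tuple[pd.Series, pd.Series]:
    if set(a.index) != set(b.index):
        raise ValidationError("score vectors cover different cell sets")
    return a, b.reindex(a.index)


def classify_cell_cycle(score_s: ScoreVector, score_g2m: ScoreVector) -> pd.DataFrame:
    """Assign G1/S/G2M per cell from the two cycle scores.

    G1 when max(S, G2M) <= 0; otherwise the larger score wins, ties going
    to G2M.  Returns a frame with columns score_S, score_G2M, phase, cycling.
    """
    s, g = _aligned(score_s.scores, score_g2m.scores)
    phase = np.where(
        np.maximum(s.values, g.values) <= 0.0,
        "G1",
        np.where(s.values > g.values, "S", "G2M"),
    )
    return pd.DataFrame(
        {
            "score_S": s.values,
            "score_G2M": g.values,
            "phase": phase,
            "cycling": phase != "G1",
        },
        index=s.index,
    )


def classify_region(score_prox: ScoreVector, score_dist: ScoreVector) -> pd.Series:
    """Proximal/distal call per cell: proximal iff prox - dist > 0 (tie -> distal)."""
    p, d = _aligned(score_prox.scores, score_dist.scores)
    region = np.where(p.values - d.values > 0.0, "proximal", "distal")
    return pd.Series(region, index=p.index, name="region")


def region_proportions(
    region: pd.Series, annotation: CellAnnotation
) -> pd.DataFrame:
    """Per (cluster, condition) proximal/distal proportions, mean +/- s.e.m.
    across samples."""
    tab = annotation.table.loc[region.index].copy()
    tab["region"] = region.values
    per_sample = (
        tab.groupby(["cluster", "condition", "sample"])["region"]
        .value_counts(normalize=True)
        .rename("proportion")
        .reset_index()
    )
    agg = (
        per_sample.groupby(["cluster", "condition", "region"])["proportion"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n_samples="count")
        .reset_index()
    )
    return agg


def cycle_correlated_genes(
    expr: ExpressionMatrix,
    score: ScoreVector,
    cells: pd.Index | list[str] | None = None,
    r_min: float = 0.7,
) -> pd.DataFrame:
    """Genes whose expression correlates with a cycle score over cycling cells.

    Pearson r per gene on the supplied cell subset (default: all scored
    cells); genes with r > ``r_min`` are returned sorted by decreasing r.
    Zero-variance genes are excluded and listed in the ``excluded`` attr.
    """
    idx = pd.Index(cells) if cells is not None else score.scores.index
    if len(idx) < 3:
        raise ValidationError("need >= 3 cells for correlation")
    pos = [expr.cell_ids.index(c) for c in idx]
    X = expr.values[pos, :]
    y = score.scores.reindex(idx).values
    if np.std(y) == 0:
        raise ValidationError("score has zero variance over the selected cells")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    zero_var = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[zero_var] = np.nan
    out = pd.DataFrame({"gene": expr.gene_ids, "r": r})
    excluded = out.loc[zero_var, "gene"].tolist()
    out = out.dropna().query("r > @r_min").sort_values("r", ascending=False)
    out = out.reset_index(drop=True)
    out.attrs["excluded_zero_variance"] = excluded
    return out
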