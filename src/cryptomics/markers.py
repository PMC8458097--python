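"""Marker-gene selection, moderated differential expression, enrichment.

Three families of procedures live here:

* pairwise Wilcoxon rank-sum marker rules — a gene is a state marker when
  its tie-corrected z exceeds ``z_min`` AND its z-rank is within ``top_n``
  in *every* pairwise test of that state against the others; the lineage
  variant excludes later stages of the same lineage from the test set;
* empirical-Bayes moderated t with a mean-variance trend (the limma-trend
  scheme): gene-wise residual variances are shrunk toward a locally
  weighted trend s0^2(A) fitted on average log expression, with the prior
  degrees of freedom d0 estimated by moment-matching the scaled-F
  distribution of s^2 / s0^2;
* gene-set over-representation by a two-sided Fisher exact test, with the
  mean |logFC| of in-set query genes reported as a weighting summary.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "wilcoxon_z",
    "state_markers",
    "lineage_markers",
    "moderated_de",
    "bulk_regulated_sets",
    "gene_set_enrichment",
]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum z


def _wilcoxon_z_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Tie-corrected rank-sum z per column; positive when x is larger.

    x: (n, G); y: (m, G).  Mid-ranks, no continuity correction; all-tied
    columns give z = 0.
    """
    n, m = x.shape[0], y.shape[0]
    if n == 0 or m == 0:
        raise ValidationError("both groups must be non-empty")
    z_data = np.vstack([x, y])
    N = n + m
    rmin = st.rankdata(z_data, axis=0, method="min")
    rmax = st.rankdata(z_data, axis=0, method="max")
    ranks = (rmin + rmax) / 2.0  # mid-ranks
    W = ranks[:n].sum(axis=0)
    mu = n * (N + 1) / 2.0
    # sum over tie groups of (t^3 - t) == sum over elements of (t_e^2 - 1)
    t_e = rmax - rmin + 1.0
    ties = (t_e**2 - 1.0).sum(axis=0)
    sigma2 = n * m / 12.0 * ((N + 1) - ties / (N * (N - 1)))
    z = np.zeros(z_data.shape[1])
    ok = sigma2 > 0
    z[ok] = (W[ok] - mu) / np.sqrt(sigma2[ok])
    return z


def wilcoxon_z(x_values: Sequence[float], y_values: Sequence[float]) -> float:
    """Tie-corrected normal approximation of the Wilcoxon rank-sum statistic.

    Returns z = (W - mu_W) / sigma_W with mid-ranks and the tie-corrected
    variance; sign is positive when ``x_values`` is stochastically larger.
    """
    x = np.asarray(x_values, dtype=float).reshape(-1, 1)
    y = np.asarray(y_values, dtype=float).reshape(-1, 1)
    return float(_wilcoxon_z_matrix(x, y)[0])


# ---------------------------------------------------------------------------
# Marker rules


def _pairwise_marker_scan(
    expr: ExpressionMatrix,
    labels: pd.Series,
    test_sets: Mapping[str, list[str]],
    z_min: float,
    top_n: int,
) -> pd.DataFrame:
    """Apply the z/rank rule for each focal state against its test set."""
    values = expr.values
    cell_pos = {c: i for i, c in enumerate(expr.cell_ids)}
    idx_of = {
        lab: np.array([cell_pos[c] for c in labels.index[labels == lab]])
        for lab in labels.unique()
    }
    rows = []
    for state, opponents in test_sets.items():
        min_z = np.full(expr.n_genes, np.inf)
        max_rank = np.zeros(expr.n_genes, dtype=int)
        passing = np.ones(expr.n_genes, dtype=bool)
        for opp in opponents:
            z = _wilcoxon_z_matrix(values[idx_of[state]], values[idx_of[opp]])
            # competition ranking on descending z: ties share the best rank
            rank = st.rankdata(-z, method="min").astype(int)
            passing &= (z > z_min) & (rank <= top_n)
            min_z = np.minimum(min_z, z)
            max_rank = np.maximum(max_rank, rank)
        for g in np.flatnonzero(passing):
            rows.append(
                {
                    "state": state,
                    "gene": expr.gene_ids[g],
                    "min_z": min_z[g],
                    "max_rank": int(max_rank[g]),
                }
            )
    table = pd.DataFrame(rows, columns=["state", "gene", "min_z", "max_rank"])
    if len(table):
        table = table.sort_values(
            ["state", "min_z"], ascending=[True, False]
        ).reset_index(drop=True)
    return table


def _usable_states(labels: pd.Series, min_cells: int = 3) -> list[str]:
    states = []
    for lab, cnt in labels.value_counts().items():
        if cnt >= min_cells:
            states.append(lab)
        else:
            warnings.warn(
                f"state {lab!r} has {cnt} < {min_cells} cells; excluded",
                UserWarning,
                stacklevel=3,
            )
    return sorted(states)


def state_markers(
    expr: ExpressionMatrix,
    labels: pd.Series,
    z_min: float = 5.0,
    top_n: int = 1200,
) -> pd.DataFrame:
    """State-specific markers by the pairwise Wilcoxon rule.

    A gene is a marker of state *i* iff in the test of *i* against every
    other state its z exceeds ``z_min`` and its descending-z rank is within
    ``top_n``.  Genes tied at the ``top_n`` boundary are kept.
    """
    labels = labels.dropna().astype(str)
    states = _usable_states(labels)
    if len(states) < 2:
        raise ValidationError("need >= 2 states with enough cells")
    test_sets = {s: [t for t in states if t != s] for s in states}
    return _pairwise_marker_scan(expr, labels, test_sets, z_min, top_n)


def lineage_markers(
    expr: ExpressionMatrix,
    labels: pd.Series,
    stage_order: Sequence[tuple[str, str]],
    z_min: float = 5.0,
    top_n: int = 1200,
) -> pd.DataFrame:
    """Lineage markers: as :func:`state_markers`, but each progenitor is not
    tested against later stages of its own lineage.

    ``stage_order`` lists (earlier, later) pairs; the exclusion set of a
    state is the transitive closure of its descendants.  A cyclic order is
    an error; an empty order reduces exactly to :func:`state_markers`.
    """
    labels = labels.dropna().astype(str)
    states = _usable_states(labels)
    if len(states) < 2:
        raise ValidationError("need >= 2 states with enough cells")
    children: dict[str, set[str]] = {s: set() for s in states}
    for early, late in stage_order:
        if early in children:
            children[early].add(late)
    # transitive closure with cycle detection (DFS)
    def descendants(s: str) -> set[str]:
        out: set[str] = set()
        stack, onpath = [s], {s}
        order: list[tuple[str, bool]] = [(s, False)]
        seen: set[str] = set()
        while order:
            node, done = order.pop()
            if done:
                onpath.discard(node)
                continue
            order.append((node, True))
            for ch in children.get(node, ()):  # noqa: B905
                if ch == s or ch in onpath:
                    raise ValidationError("cyclic stage order")
                out.add(ch)
                if ch not in seen:
                    seen.add(ch)
                    onpath.add(ch)
                    order.append((ch, False))
        return out

    test_sets = {}
    for s in states:
        excl = descendants(s)
        test_sets[s] = [t for t in states if t != s and t not in excl]
    test_sets = {s: opp for s, opp in test_sets.items() if opp}
    return _pairwise_marker_scan(expr, labels, test_sets, z_min, top_n)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t (limma-trend scheme)


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-10):
            break
    return x


def _squeeze_var(
    s2: np.ndarray, df: float, covariate: np.ndarray | None = None,
    lowess_frac: float = 0.5,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Empirical-Bayes moment estimation of (d0, s0^2), optionally with a
    mean-expression trend.

    Returns (posterior variances, d0, s0^2 per gene).  d0 = inf means all
    variances collapse to the prior; d0 estimated <= 0 is treated as inf.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is not None and np.ptp(covariate) > 0:
        fit = lowess(e, covariate, frac=lowess_frac, it=2, return_sorted=False)
        efit = np.asarray(fit, dtype=float)
    else:
        efit = np.full_like(e, e.mean())
    resid = e - efit
    evar = resid.var(ddof=1) if resid.size > 1 else 0.0
    evar -= float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s0_2 = np.exp(efit + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(efit)
    if np.isfinite(d0):
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        post = s0_2.copy()
    return post, d0, s0_2


def _two_group_moderated(
    logx: np.ndarray,
    grp: np.ndarray,
    trend: bool,
    d0_override: float | None,
) -> pd.DataFrame:
    """Core moderated two-sample test on a (observations x genes) log matrix.

    ``grp`` is boolean: True marks the second condition (logFC = mean2 - mean1).
    """
    x1, x2 = logx[~grp], logx[grp]
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 observations per condition")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    lfc = m2 - m1
    df = n1 + n2 - 2
    ss = ((x1 - m1) ** 2).sum(axis=0) + ((x2 - m2) ** 2).sum(axis=0)
    s2 = ss / df
    ave = logx.mean(axis=0)
    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0.0:
            post = np.maximum(s2, 1e-300)
            s0_2 = np.full_like(s2, np.nan)
        else:
            _, _, s0_2 = _squeeze_var(s2, df, ave if trend else None)
            post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    else:
        post, d0, s0_2 = _squeeze_var(s2, df, ave if trend else None)
        df_total = df + d0
    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    t = lfc / (np.sqrt(post) * c)
    if np.isfinite(df_total):
        p = 2.0 * st.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * st.norm.sf(np.abs(t))
    return pd.DataFrame(
        {
            "logFC": lfc,
            "AveExpr": ave,
            "t": t,
            "P": p,
            "s2": s2,
            "s2_post": post,
            "d0": d0,
            "df_total": df_total,
        }
    )


def moderated_de(
    expr: ExpressionMatrix,
    condition: pd.Series,
    strata: pd.Series | None = None,
    fdr_max: float = 0.01,
    lfc_min: float = 0.1,
    trend: bool = True,
    d0_override: float | None = None,
    conditions: tuple[str, str] | None = None,
    pseudobulk: pd.Series | None = None,
) -> pd.DataFrame:
    """Condition-wise moderated differential expression per stratum.

    Per gene and stratum: logFC (condition2 - condition1 mean log
    expression), moderated t with variance shrunk toward the lowess
    mean-variance trend, raw P, Benjamini-Hochberg FDR within stratum, and
    a flag for FDR < ``fdr_max`` and |logFC| > ``lfc_min``.  With
    ``pseudobulk`` (a per-cell sample factor), cells are averaged per
    sample first for replicate-level inference.
    """
    condition = condition.reindex(expr.cell_ids)
    if condition.isna().any():
        raise ValidationError("condition missing for some cells")
    levels = sorted(condition.unique().tolist())
    if conditions is not None:
        if sorted(conditions) != levels:
            raise ValidationError(f"conditions {conditions} != levels {levels}")
        levels = list(conditions)
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 conditions, found {levels}")
    if strata is None:
        strata = pd.Series("all", index=condition.index)
    else:
        strata = strata.reindex(condition.index).fillna("NA")

    results = []
    for stratum in sorted(strata.unique()):
        mask = (strata == stratum).values
        cond_s = condition[mask]
        if cond_s.nunique() < 2:
            warnings.warn(
                f"stratum {stratum!r} has a single condition; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        logx = expr.values[mask]
        grp = (cond_s == levels[1]).values
        if pseudobulk is not None:
            pb = pseudobulk.reindex(cond_s.index)
            samples = sorted(pb.unique())
            logx = np.vstack([logx[(pb == s).values].mean(axis=0) for s in samples])
            grp = np.array(
                [cond_s[(pb == s).values].iloc[0] == levels[1] for s in samples]
            )
        try:
            res = _two_group_moderated(logx, grp, trend, d0_override)
        except ValidationError as exc:
            warnings.warn(f"stratum {stratum!r}: {exc}; skipped", UserWarning, stacklevel=2)
            continue
        res.insert(0, "gene", expr.gene_ids)
        res.insert(1, "stratum", stratum)
        res["FDR"] = multipletests(res["P"].values, method="fdr_bh")[1]
        res["logFC_log2"] = res["logFC"] / np.log(2.0)
        res["flagged"] = (res["FDR"] < fdr_max) & (res["logFC"].abs() > lfc_min)
        results.append(res)
    if not results:
        raise ValidationError("no stratum with both conditions present")
    return pd.concat(results, ignore_index=True)


def bulk_regulated_sets(
    bulk: pd.DataFrame,
    groups: pd.Series,
    p_max: float = 0.01,
    fc_min: float = 1.3,
    min_avg: float = 32.0,
    trend: bool = False,
) -> pd.DataFrame:
    """Regulated-gene calls on linear-scale bulk expression.

    ``bulk``: genes x samples, linear scale; ``groups``: two-level factor
    per sample.  Per gene: moderated two-sample test on log2 values; a gene
    is *regulated* iff raw P < ``p_max`` AND linear fold change (larger
    group mean over smaller) > ``fc_min`` AND the larger group mean exceeds
    ``min_avg``.
    """
    groups = groups.reindex(bulk.columns)
    if groups.isna().any():
        raise ValidationError("group missing for some samples")
    levels = sorted(groups.unique().tolist())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, found {levels}")
    g2 = (groups == levels[1]).values
    if g2.sum() < 2 or (~g2).sum() < 2:
        raise ValidationError("need >= 2 replicates per group")
    if (bulk.values <= 0).any():
        raise ValidationError("bulk expression must be positive (linear scale)")
    logx = np.log2(bulk.values.T)  # samples x genes
    res = _two_group_moderated(logx, g2, trend, None)
    m1 = bulk.loc[:, ~g2].mean(axis=1).values
    m2 = bulk.loc[:, g2].mean(axis=1).values
    hi = np.maximum(m1, m2)
    lo = np.minimum(m1, m2)
    with np.errstate(divide="ignore"):
        fc = np.where(lo > 0, hi / lo, np.inf)
    out = pd.DataFrame(
        {
            "gene": bulk.index,
            f"mean_{levels[0]}": m1,
            f"mean_{levels[1]}": m2,
            "fc": fc,
            "log2FC": res["logFC"].values,
            "t": res["t"].values,
            "P": res["P"].values,
        }
    )
    out["regulated"] = (out["P"] < p_max) & (out["fc"] > fc_min) & (hi > min_avg)
    return out


# ---------------------------------------------------------------------------
# Gene-set enrichment


def gene_set_enrichment(
    query: Mapping[str, float],
    gene_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` genes (gene -> logFC) in gene sets.

    Two-sided Fisher exact P on the 2x2 in-set/out-set x query/non-query
    table against ``background``; BH-adjusted across sets.  The mean
    |logFC| of in-set query genes is reported as the weighting summary.
    Sets with no background overlap are skipped.
    """
    bg = set(background)
    if not query:
        raise ValidationError("empty query")
    stray = set(query) - bg
    if stray:
        raise ValidationError(
            f"{len(stray)} query genes outside background, e.g. {sorted(stray)[:3]}"
        )
    q = set(query)
    rows = []
    for name, genes in gene_sets.items():
        inset = set(genes) & bg
        if not inset:
            continue
        a = len(inset & q)
        b = len(q) - a
        c = len(inset) - a
        d = len(bg) - len(inset) - b
        odds, p = st.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        hits = sorted(inset & q)
        mean_abs_lfc = float(np.mean([abs(query[g]) for g in hits])) if hits else np.nan
        rows.append(
            {
                "set": name,
                "n_set": len(inset),
                "n_overlap": a,
                "odds_ratio": odds,
                "P": p,
                "mean_abs_logFC": mean_abs_lfc,
                "hits": ";".join(hits),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["FDR"] = multipletests(out["P"].values, method="fdr_bh")[1]
        out = out.sort_values("P").reset_index(drop=True)
    return out
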