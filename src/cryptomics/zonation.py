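"""Pseudospatial villus-axis ordering of enterocytes and five-zone profiles.

Cells are placed on the villus bottom -> tip axis by the difference of two
landmark signature scores (tip minus bottom), rank-normalized to a
pseudospace coordinate zeta in [0, 1], and partitioned into k contiguous
equal-frequency zones (default five).  Zone-wise expression profiles and
condition contrasts summarize how a gene's spatial pattern changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SignatureSet, ValidationError
from .scoring import signature_score

__all__ = [
    "ZonationResult",
    "pseudospace_order",
    "partition_zones",
    "zonation_profiles",
]


def pseudospace_order(
    expr: ExpressionMatrix,
    bottom_landmarks: SignatureSet,
    tip_landmarks: SignatureSet,
    n_bins: int = 25,
    n_controls: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Rank-normalized pseudospace coordinate zeta in [0, 1] per cell.

    Raw score = tip signature score - bottom signature score (both computed
    with the same seed so the control machinery is shared); zeta is the
    rank of the raw score divided by (n - 1), with ties broken by the
    stable input cell order.  Larger zeta = closer to the villus tip.
    """
    s_tip = signature_score(expr, tip_landmarks, n_bins, n_controls, seed)
    s_bot = signature_score(expr, bottom_landmarks, n_bins, n_controls, seed)
    raw = s_tip.scores.values - s_bot.scores.values
    n = raw.size
    if n < 2:
        raise ValidationError("need >= 2 cells to order")
    order = np.argsort(raw, kind="stable")
    rank = np.empty(n, dtype=float)
    rank[order] = np.arange(n)
    zeta = rank / (n - 1)
    return pd.Series(zeta, index=expr.cell_ids, name="zeta")


def partition_zones(zeta: pd.Series, k: int = 5) -> pd.Series:
    """Equal-frequency partition of zeta into k contiguous zones (1 = bottom).

    Zone sizes are floor(n/k) or ceil(n/k); the zone index is
    non-decreasing in zeta.
    """
    if k < 2:
        raise ValidationError("need k >= 2 zones")
    n = len(zeta)
    if n < k:
        raise ValidationError(f"cannot split {n} cells into {k} zones")
    order = np.argsort(zeta.values, kind="stable")
    # spread the remainder over the first n % k zones
    base, extra = divmod(n, k)
    sizes = [base + (1 if z < extra else 0) for z in range(k)]
    labels = np.empty(n, dtype=int)
    start = 0
    for z, sz in enumerate(sizes, start=1):
        labels[order[start : start + sz]] = z
        start += sz
    return pd.Series(labels, index=zeta.index, name="zone")


@dataclass
class ZonationResult:
    """Per-cell pseudospace coordinate and zone, plus zone-wise profiles."""

    cells: pd.DataFrame  # zeta, zone, condition
    profiles: pd.DataFrame  # (gene, zone, condition) -> mean expression
    contrasts: pd.DataFrame | None = None


def zonation_profiles(
    expr: ExpressionMatrix,
    zeta: pd.Series,
    condition: pd.Series,
    k: int = 5,
    genes: list[str] | None = None,
    contrast: bool = False,
    fdr_max: float = 0.01,
    lfc_min: float = 0.1,
) -> ZonationResult:
    """Per-zone mean expression profile per condition, with optional
    zone-restricted condition contrasts via the moderated-t machinery.

    Zones are assigned within condition so that compositional differences
    between conditions do not shift zone boundaries.
    """
    condition = condition.reindex(zeta.index)
    if condition.isna().any():
        raise ValidationError("condition missing for some cells")
    zone = pd.Series(index=zeta.index, dtype=int, name="zone")
    for cond in condition.unique():
        mask = condition == cond
        zone.loc[mask] = partition_zones(zeta.loc[mask], k=k).values
    cells = pd.DataFrame({"zeta": zeta, "zone": zone, "condition": condition})

    frame = expr.to_frame().loc[zeta.index]
    if genes is not None:
        frame = frame[[g for g in genes if g in frame.columns]]
    prof_rows = []
    for (cond, z), sub in cells.groupby(["condition", "zone"], sort=True):
        means = frame.loc[sub.index].mean(axis=0)
        for g, m in means.items():
            prof_rows.append({"gene": g, "zone": int(z), "condition": cond, "mean": m})
    profiles = pd.DataFrame(prof_rows)

    contrasts = None
    if contrast:
        from .markers import moderated_de

        sub_expr = ExpressionMatrix(
            frame.values, frame.index.tolist(), frame.columns.tolist(),
            scale=expr.scale,
        )
        res = moderated_de(
            sub_expr,
            condition=cells["condition"],
            strata=cells["zone"].astype(str),
            fdr_max=fdr_max,
            lfc_min=lfc_min,
        )
        contrasts = res.rename(columns={"stratum": "zone"})
    return ZonationResult(cells=cells, profiles=profiles, contrasts=contrasts)
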