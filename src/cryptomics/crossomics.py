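"""Reaction-level transcriptome-metabolome integration and HOMA indices.

A reaction is *affected* when at least one of its genes is significant in
the transcriptome analysis AND at least one of its metabolites is
significant in the metabolome analysis; a pathway is affected when any of
its member reactions is.  The significant sets are taken verbatim from
upstream analyses — no re-thresholding happens here.

HOMA indices (fasting glucose in mg per 100 ml, insulin in uU per ml):

    HOMA-IR   = glucose * insulin / 405
    HOMA-beta = insulin * 360 / (glucose - 63)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core import ValidationError

__all__ = ["IntegrationReport", "integrate_reactions", "homa_indices"]


@dataclass
class IntegrationReport:
    reactions: pd.DataFrame  # reaction, pathway, gene_hits, metabolite_hits, affected
    pathways: pd.DataFrame  # pathway, affected, supporting_reactions

    @property
    def affected_reactions(self) -> list[str]:
        return self.reactions.loc[self.reactions["affected"], "reaction"].tolist()

    @property
    def affected_pathways(self) -> list[str]:
        return self.pathways.loc[self.pathways["affected"], "pathway"].tolist()


def integrate_reactions(
    sig_genes: set[str] | list[str],
    sig_metabolites: set[str] | list[str],
    reaction_map: dict,
) -> IntegrationReport:
    """Joint-significance integration over a gene->reaction->metabolite map.

    ``reaction_map``: {reaction: {'genes': [...], 'metabolites': [...],
    'pathway': id}}.  Warns when a significant set has zero overlap with
    the map's namespace (likely an identifier mismatch).
    """
    sig_genes = set(sig_genes)
    sig_metabolites = set(sig_metabolites)
    gene_universe: set[str] = set()
    met_universe: set[str] = set()
    for entry in reaction_map.values():
        if not entry.get("genes") or not entry.get("metabolites"):
            raise ValidationError("every reaction needs >= 1 gene and >= 1 metabolite")
        gene_universe.update(entry["genes"])
        met_universe.update(entry["metabolites"])
    for name, sig, universe in (
        ("genes", sig_genes, gene_universe),
        ("metabolites", sig_metabolites, met_universe),
    ):
        if sig and not (sig & universe):
            warnings.warn(
                f"no overlap between significant {name} ({len(sig)}) and the "
                f"map's {name} namespace ({len(universe)}); check identifiers",
                UserWarning,
                stacklevel=2,
            )
    rows = []
    for rid in sorted(reaction_map):
        entry = reaction_map[rid]
        ghits = sorted(set(entry["genes"]) & sig_genes)
        mhits = sorted(set(entry["metabolites"]) & sig_metabolites)
        rows.append(
            {
                "reaction": rid,
                "pathway": entry.get("pathway", ""),
                "gene_hits": ";".join(ghits),
                "metabolite_hits": ";".join(mhits),
                "affected": bool(ghits) and bool(mhits),
            }
        )
    reactions = pd.DataFrame(rows)
    pw_rows = []
    for pw, grp in reactions.groupby("pathway", sort=True):
        support = grp.loc[grp["affected"], "reaction"].tolist()
        pw_rows.append(
            {
                "pathway": pw,
                "affected": bool(support),
                "supporting_reactions": ";".join(support),
            }
        )
    return IntegrationReport(reactions=reactions, pathways=pd.DataFrame(pw_rows))


def homa_indices(glucose: float, insulin: float) -> tuple[float, float]:
    """HOMA-IR and HOMA-beta from fasting glucose (mg per 100 ml) and
    fasting insulin (uU per ml).

    HOMA-beta requires glucose > 63 mg per 100 ml (the denominator is
    glucose - 63); below that the index is undefined and an error is raised.
    """
    if glucose <= 0 or insulin <= 0:
        raise ValidationError("glucose and insulin must be positive")
    homa_ir = glucose * insulin / 405.0
    if glucose <= 63.0:
        raise ValidationError(
            f"HOMA-beta undefined for glucose <= 63 mg per 100 ml (got {glucose})"
        )
    homa_beta = insulin * 360.0 / (glucose - 63.0)
    return homa_ir, homa_beta
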