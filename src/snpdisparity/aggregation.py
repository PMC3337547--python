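"""Regional and gene-level aggregation of per-locus disparity calls.

Cytoband summaries count, per band, the studied loci and the subset
flagged as high-disparity (score >= 75), with the mean score over the
flagged loci. Gene collapsing calls a gene a disparity gene when more than
half of its loci are flagged; genes split exactly 50/50 are excluded as
ties. Gene-set comparisons put set membership against the collapsed
outcome in a 2 x 2 table and apply the uncorrected Pearson chi-square.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import ContingencyResult, pearson_chi2
from .cna import AMPLIFICATION, DELETION
from .io import CytobandMap, GeneSet, ValidationError

__all__ = [
    "cytoband_summary",
    "collapse_genes",
    "gene_cna_class",
    "geneset_chi2",
]

UNASSIGNED = "unassigned"
INTERGENIC = "intergenic"


def _bands_for(records: pd.DataFrame, cytobands: CytobandMap | None) -> pd.Series:
    """Band label per record: from the map when given, else the annotation column."""
    if cytobands is not None and len(cytobands) > 0:
        labels = cytobands.assign(records["chromosome"], records["position"])
        return pd.Series(labels, index=records.index, dtype=object)
    band = records.get("cytoband")
    if band is None:
        return pd.Series(None, index=records.index, dtype=object)
    return band


def cytoband_summary(
    records: pd.DataFrame,
    cytobands: CytobandMap | None = None,
    disparity_column: str = "selected",
    highlight_threshold: float = 30.0,
) -> pd.DataFrame:
    """Per-band disparity summary over the studied loci.

    ``records`` is the per-locus disparity table with a boolean
    ``disparity_column`` marking the high-disparity subset. Loci that map
    to no band are grouped under ``unassigned``. Bands whose disparity
    percentage reaches ``highlight_threshold`` are flagged.
    """
    if disparity_column not in records.columns:
        raise ValidationError(f"records lack the {disparity_column!r} column")
    band = _bands_for(records, cytobands).fillna(UNASSIGNED)
    disp = records[disparity_column].astype(bool)
    score = records["score"]

    rows = []
    for name, grp_idx in band.groupby(band).groups.items():
        sel = disp.loc[grp_idx]
        n = len(grp_idx)
        n_disp = int(sel.sum())
        mean_score = float(score.loc[grp_idx][sel].mean()) if n_disp else np.nan
        pct = 100.0 * n_disp / n
        rows.append(
            {
                "band": name,
                "n_snps_in_band": n,
                "n_disparity_snps": n_disp,
                "pct_disparity": pct,
                "mean_score": mean_score,
                "highlighted": pct >= highlight_threshold,
            }
        )
    out = pd.DataFrame(rows).set_index("band")
    return out.sort_values(["pct_disparity", "n_disparity_snps"], ascending=False)


def _gene_lists(genes: pd.Series) -> pd.Series:
    """Split comma-separated gene annotations; empty/missing -> no genes."""
    def split(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return []
        return [g.strip() for g in str(v).split(",") if g.strip()]
    return genes.map(split)


def collapse_genes(
    records: pd.DataFrame,
    disparity_column: str = "selected",
) -> pd.DataFrame:
    """Majority-rule gene calls from per-locus disparity flags.

    A locus annotated to several genes (comma list) counts toward each.
    Call: ``disparity`` when the flagged fraction exceeds 0.5,
    ``excluded_tie`` at exactly 0.5, otherwise ``no_disparity``.
    Intergenic loci (no gene) are excluded.
    """
    if disparity_column not in records.columns:
        raise ValidationError(f"records lack the {disparity_column!r} column")
    lists = _gene_lists(records["gene"])
    disp = records[disparity_column].astype(bool)
    counts: dict[str, list[int]] = {}
    for gene_list, flagged in zip(lists, disp):
        for g in gene_list:
            tot = counts.setdefault(g, [0, 0])
            tot[0] += 1
            tot[1] += int(flagged)
    rows = []
    for gene, (n_loci, n_disp) in sorted(counts.items()):
        frac = n_disp / n_loci
        call = "disparity" if frac > 0.5 else ("excluded_tie" if frac == 0.5 else "no_disparity")
        rows.append({"gene": gene, "n_loci": n_loci, "n_disparity_loci": n_disp, "call": call})
    return pd.DataFrame(rows, columns=["gene", "n_loci", "n_disparity_loci", "call"]).set_index("gene")


def gene_cna_class(
    cna_calls: pd.DataFrame,
    genes: pd.Series,
) -> pd.DataFrame:
    """Majority amplification/deletion class per gene.

    ``cna_calls`` is the int8 locus x sample state matrix; ``genes`` the
    gene annotation for the same loci. A gene is ``amplification`` when its
    amplified locus x sample cells strictly outnumber the deleted ones,
    ``deletion`` in the reverse case, ``excluded_tie`` on equality
    (mirroring the disparity tie rule).
    """
    lists = _gene_lists(genes.loc[cna_calls.index])
    states = cna_calls.to_numpy()
    amp_per_locus = (states == AMPLIFICATION).sum(axis=1)
    del_per_locus = (states == DELETION).sum(axis=1)
    counts: dict[str, list[int]] = {}
    for gene_list, n_amp, n_del in zip(lists, amp_per_locus, del_per_locus):
        for g in gene_list:
            tot = counts.setdefault(g, [0, 0])
            tot[0] += int(n_amp)
            tot[1] += int(n_del)
    rows = []
    for gene, (n_amp, n_del) in sorted(counts.items()):
        if n_amp > n_del:
            call = "amplification"
        elif n_del > n_amp:
            call = "deletion"
        else:
            call = "excluded_tie"
        rows.append({"gene": gene, "n_amp_cells": n_amp, "n_del_cells": n_del, "call": call})
    return pd.DataFrame(rows, columns=["gene", "n_amp_cells", "n_del_cells", "call"]).set_index("gene")


def geneset_chi2(
    gene_calls: pd.DataFrame,
    gene_set: GeneSet,
    contrast: str = "disparity_vs_not",
) -> ContingencyResult:
    """2 x 2 membership x outcome chi-square (uncorrected Pearson).

    ``contrast="disparity_vs_not"`` uses collapsed disparity calls
    (ties excluded); ``contrast="amp_vs_del"`` uses gene CNA classes from
    :func:`gene_cna_class`. Columns are non-members / members.
    """
    if contrast == "disparity_vs_not":
        outcomes = ("no_disparity", "disparity")
    elif contrast == "amp_vs_del":
        outcomes = ("amplification", "deletion")
    else:
        raise ValidationError(f"unknown contrast {contrast!r}")
    usable = gene_calls[gene_calls["call"].isin(outcomes)]
    in_set = usable.index.to_series().isin(gene_set.genes)
    if not in_set.any():
        raise ValidationError(
            f"gene set {gene_set.name!r} has no overlap with the annotated genes"
        )
    table = np.zeros((2, 2))
    for i, outcome in enumerate(outcomes):
        is_outcome = usable["call"] == outcome
        table[i, 0] = int((is_outcome & ~in_set).sum())
        table[i, 1] = int((is_outcome & in_set).sum())
    return pearson_chi2(table, continuity_correction=False)
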