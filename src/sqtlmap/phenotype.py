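"""Construction of the two splicing quantitative traits.

Method 1 (``exon_fraction``): per exon and sample, reads in the exon divided
by the summed transcript reads of the exon's host gene.  Method 2
(``isoform_groups``): per multi-isoform gene, the matrix of isoform-level
expression treated as a multivariate trait.
"""

from __future__ import annotations

import logging
import warnings
from math import prod

import numpy as np
import pandas as pd

from .types import Annotation, IsoformGroup, PhenotypeMatrix

__all__ = ["exon_fraction", "isoform_groups", "dscam_isoform_count"]

log = logging.getLogger(__name__)


def exon_fraction(
    exon_counts: pd.DataFrame,
    transcript_counts: pd.DataFrame,
    annotation: Annotation,
    zero_policy: str = "drop",
    max_missing_frac: float = 0.2,
) -> PhenotypeMatrix:
    """Exon-fraction splicing trait.

    The denominator for an exon is the summed counts of *all* transcripts of
    its host gene in that sample, which stays well defined for exons shared
    between isoforms.  Under ``zero_policy='drop'`` cells with a zero
    denominator become missing and phenotypes missing in more than
    ``max_missing_frac`` of samples are removed; under ``'pseudocount'`` one
    read is added to numerator and denominator instead.

    Exon ids absent from the annotation are skipped with a warning;
    negative counts are a hard error.
    """
    if zero_policy not in ("drop", "pseudocount"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if (exon_counts.to_numpy() < 0).any() or (transcript_counts.to_numpy() < 0).any():
        raise ValueError("negative counts")

    exon_tab = annotation.exon_table().set_index("exon_id")
    known = exon_counts.index.intersection(exon_tab.index)
    n_skipped = len(exon_counts.index) - len(known)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} exon id(s) absent from the annotation were skipped",
            stacklevel=2,
        )
    exon_counts = exon_counts.loc[known]

    tx_gene = pd.Series(
        {t: annotation.gene_of_transcript(t) for t in transcript_counts.index}
    )
    gene_sum = transcript_counts.groupby(tx_gene).sum()  # genes x samples

    genes = exon_tab.loc[known, "gene_id"]
    denom = gene_sum.reindex(genes).to_numpy(dtype=float)
    numer = exon_counts.to_numpy(dtype=float)
    if zero_policy == "pseudocount":
        frac = (numer + 1.0) / (denom + 1.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)

    values = pd.DataFrame(frac, index=known, columns=exon_counts.columns)
    if zero_policy == "drop":
        keep = values.isna().mean(axis=1) <= max_missing_frac
        values = values.loc[keep]
    gene_anchor = annotation.anchors()
    anchors = pd.DataFrame(
        {
            "chrom": gene_anchor.loc[exon_tab.loc[values.index, "gene_id"], "chrom"].to_numpy(),
            "pos": gene_anchor.loc[exon_tab.loc[values.index, "gene_id"], "pos"].to_numpy(),
            "gene_id": exon_tab.loc[values.index, "gene_id"].to_numpy(),
        },
        index=values.index,
    )
    log.info("exon_fraction: %d phenotypes kept of %d exons", len(values), len(known))
    return PhenotypeMatrix(values=values, anchors=anchors, kind="exon_fraction")


def isoform_groups(
    transcript_counts: pd.DataFrame,
    annotation: Annotation,
    min_total: int = 1,
) -> list[IsoformGroup]:
    """Group transcript rows by gene, keeping genes with >= 2 expressed
    isoforms (row present with total count >= ``min_total``).  Single-isoform
    genes carry no isoform-usage information and are excluded."""
    if transcript_counts.empty:
        return []
    groups: list[IsoformGroup] = []
    gene_anchor = annotation.anchors()
    tx_gene = pd.Series(
        {t: annotation.gene_of_transcript(t) for t in transcript_counts.index}
    )
    for gene_id, tx_ids in tx_gene.groupby(tx_gene).groups.items():
        sub = transcript_counts.loc[list(tx_ids)]
        sub = sub[sub.sum(axis=1) >= min_total]
        if len(sub) < 2:
            continue
        groups.append(
            IsoformGroup(
                gene_id=str(gene_id),
                chrom=gene_anchor.loc[gene_id, "chrom"],
                pos=int(gene_anchor.loc[gene_id, "pos"]),
                values=sub.sort_index().astype(float),
            )
        )
    groups.sort(key=lambda g: g.gene_id)
    log.info("isoform_groups: %d multi-isoform groups", len(groups))
    return groups


def dscam_isoform_count(cluster_sizes: list[int]) -> int:
    """Theoretical isoform count under mutually exclusive variant-exon
    clusters (one alternative chosen per cluster), i.e. the product of
    cluster sizes.  The classic fly Dscam1 clusters [12, 48, 33, 2] give
    38,016.  An empty list is the empty product, 1."""
    sizes = [int(s) for s in cluster_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")
    return prod(sizes)
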