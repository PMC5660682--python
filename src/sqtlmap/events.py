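"""Alternative-splicing event typing between transcript pairs of a gene.

A simplified event taxonomy covering the four canonical local events —
exon skipping, intron retention, alternative donor (5' splice site) and
alternative acceptor (3' splice site) — plus ``other`` for structural
differences outside those categories (e.g. alternative first/last exons).
Events are derived from the two transcripts' intron chains within their
overlapping genomic span; donor/acceptor labels are strand-aware.
"""

from __future__ import annotations

import pandas as pd

from .types import Annotation, Transcript

__all__ = ["classify_event", "summarize_events", "EVENT_TYPES"]

EVENT_TYPES = ["exon_skipping", "intron_retention", "alt_donor", "alt_acceptor", "other"]


def _within(iv: tuple[int, int], span: tuple[int, int]) -> bool:
    return iv[0] >= span[0] and iv[1] <= span[1]


def _skipping(a: Transcript, b: Transcript, span: tuple[int, int]) -> bool:
    """An internal exon of ``a`` spliced out by ``b``: b has intron (d, c)
    while a has introns (d, s) and (e, c) flanking exon [s, e)."""
    a_introns = set(a.introns)
    for s, e in a.exons[1:-1]:
        for d, c in b.introns:
            if not _within((d, c), span):
                continue
            if d < s and e < c and (d, s) in a_introns and (e, c) in a_introns:
                return True
    return False


def _retention(a: Transcript, b: Transcript, span: tuple[int, int]) -> bool:
    """An intron of ``a`` fully contained in an exon of ``b``."""
    for i0, i1 in a.introns:
        if not _within((i0, i1), span):
            continue
        for s, e in b.exons:
            if s <= i0 and i1 <= e:
                return True
    return False


def _alt_site_events(
    a: Transcript, b: Transcript, span: tuple[int, int]
) -> set[str]:
    """Intron pairs sharing one boundary and differing at the other.

    For a shared intron start with differing ends (e1 < e2): the transcript
    owning the shorter intron must be purely exonic across (e1, e2) — an
    intron of its own starting in that region means the difference is a
    skipped exon, not a shifted splice site.  Mirrored for shared ends.
    On the plus strand the intron start is the donor and the end the
    acceptor; on the minus strand the roles swap.
    """
    out: set[str] = set()
    plus = a.strand == "+"

    def clean(tx: Transcript, lo: int, hi: int, side: str) -> bool:
        if side == "start":
            return not any(lo < s < hi for s, _ in tx.introns)
        return not any(lo < e < hi for _, e in tx.introns)

    for ia in a.introns:
        if not _within(ia, span):
            continue
        for ib in b.introns:
            if not _within(ib, span):
                continue
            if ia[0] == ib[0] and ia[1] != ib[1]:
                owner = a if ia[1] < ib[1] else b
                lo, hi = min(ia[1], ib[1]), max(ia[1], ib[1])
                if clean(owner, lo, hi, "start"):
                    out.add("alt_acceptor" if plus else "alt_donor")
            elif ia[1] == ib[1] and ia[0] != ib[0]:
                owner = a if ia[0] > ib[0] else b
                lo, hi = min(ia[0], ib[0]), max(ia[0], ib[0])
                if clean(owner, lo, hi, "end"):
                    out.add("alt_donor" if plus else "alt_acceptor")
    return out


def classify_event(tx_a: Transcript, tx_b: Transcript) -> set[str]:
    """Event types distinguishing two transcripts of one gene.

    Identical exon chains yield the empty set; chains that differ only in
    ways outside the four local categories (for instance alternative first
    or last exons) yield ``{"other"}``.  The result is symmetric in the
    argument order.
    """
    if tx_a.chrom != tx_b.chrom or tx_a.strand != tx_b.strand:
        raise ValueError("transcripts must share chromosome and strand")
    if tx_a.exons == tx_b.exons:
        return set()
    span = (
        max(tx_a.span[0], tx_b.span[0]),
        min(tx_a.span[1], tx_b.span[1]),
    )
    events: set[str] = set()
    if span[0] < span[1]:
        if _skipping(tx_a, tx_b, span) or _skipping(tx_b, tx_a, span):
            events.add("exon_skipping")
        if _retention(tx_a, tx_b, span) or _retention(tx_b, tx_a, span):
            events.add("intron_retention")
        events |= _alt_site_events(tx_a, tx_b, span)
    if not events:
        events.add("other")
    return events


def summarize_events(
    calls: pd.DataFrame, annotation: Annotation, dedup_genes: bool = True
) -> pd.DataFrame:
    """Tally event types over the significant sQTL genes.

    For every called gene all isoform pairs are classified; single-isoform
    genes contribute nothing.  Two tallies are reported per event type:
    ``n_pairs`` (each transcript pair counts every type it exhibits) and
    ``n_genes`` (a gene counts at most once per type).  With ``dedup_genes``
    (default) repeated calls on one gene are counted once.
    """
    if calls.empty:
        genes: list[str] = []
    else:
        genes = list(calls["gene_id"])
        if dedup_genes:
            genes = sorted(set(genes))
    pair_counts = dict.fromkeys(EVENT_TYPES, 0)
    gene_counts = dict.fromkeys(EVENT_TYPES, 0)
    for gene_id in genes:
        gene = annotation.genes.get(gene_id)
        if gene is None or len(gene.transcripts) < 2:
            continue
        txs = [gene.transcripts[t] for t in sorted(gene.transcripts)]
        seen: set[str] = set()
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                for ev in classify_event(txs[i], txs[j]):
                    pair_counts[ev] += 1
                    seen.add(ev)
        for ev in seen:
            gene_counts[ev] += 1
    return pd.DataFrame(
        {
            "event": EVENT_TYPES,
            "n_pairs": [pair_counts[e] for e in EVENT_TYPES],
            "n_genes": [gene_counts[e] for e in EVENT_TYPES],
        }
    ).set_index("event")
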