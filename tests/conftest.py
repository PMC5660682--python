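import numpy as np
import pandas as pd
import pytest

import sqtlmap as sq
from sqtlmap.types import Annotation, Gene, Transcript

CHROMS = {"2L": 500_000, "3L": 500_000}


def make_transcript(tx_id, exons, strand="+", gene_id="g", chrom="2L"):
    return Transcript(tx_id, gene_id, chrom, strand, exons)


def build_annotation(spec):
    """spec: {gene_id: {"chrom":, "strand":, "transcripts": {tx_id: exons}}}"""
    genes = {}
    for gid, g in spec.items():
        gene = Gene(gene_id=gid, chrom=g.get("chrom", "2L"), strand=g.get("strand", "+"))
        for tx_id, exons in g["transcripts"].items():
            gene.transcripts[tx_id] = Transcript(
                tx_id, gid, gene.chrom, gene.strand, exons
            )
        genes[gid] = gene
    return Annotation(genes=genes)


@pytest.fixture(scope="session")
def small_panel():
    """A deterministic 30-RIL panel with counts and no planted effects."""
    loci = sq.default_locus_grid(CHROMS, 20_000)
    geno = sq.simulate_founder_mosaics(30, loci, 8, 0.05, seed=11, blur=0.05)
    ann = sq.make_annotation(25, seed=12, chromosomes=CHROMS)
    samples = sq.make_sample_sheet(geno.rils)
    exon_counts, tx_counts, truth = sq.simulate_counts(
        geno, ann, samples, None, seed=13
    )
    return {
        "genotypes": geno,
        "annotation": ann,
        "samples": samples,
        "exon_counts": exon_counts,
        "tx_counts": tx_counts,
        "truth": truth,
        "env": (samples["treatment"] == "pb").to_numpy(float),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_counts():
    """Two genes: gA single-isoform (2 exons), gB two isoforms."""
    ann = build_annotation(
        {
            "gA": {"transcripts": {"gA.t1": [(100, 200), (300, 400)]}},
            "gB": {
                "transcripts": {
                    "gB.t1": [(1000, 1100), (1200, 1300), (1400, 1500)],
                    "gB.t2": [(1000, 1100), (1400, 1500)],
                }
            },
        }
    )
    samples = [f"s{i}" for i in range(4)]
    tx = pd.DataFrame(
        {
            "gA.t1": [20, 10, 40, 8],
            "gB.t1": [12, 6, 10, 4],
            "gB.t2": [8, 2, 10, 16],
        },
        index=samples,
    ).T
    # exon ids follow the gene:start+1-end convention
    ex = pd.DataFrame(
        {
            "gA:101-200": [10, 5, 20, 4],
            "gA:301-400": [10, 5, 20, 4],
            "gB:1001-1100": [5, 4, 8, 5],
            "gB:1201-1300": [6, 2, 4, 1],
            "gB:1401-1500": [9, 2, 8, 14],
        },
        index=samples,
    ).T
    return ann, ex, tx
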