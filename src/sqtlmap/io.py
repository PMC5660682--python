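"""Readers and writers for the pipeline's file formats.

Formats: founder-probability genotypes (TSV: ril, chrom, pos, one column
per founder), exon/transcript count tables (TSV, rows = feature ids,
columns = samples), sample sheets (TSV: sample, ril, treatment), transcript
annotations (GTF, 1-based closed; converted to 0-based half-open
internally), phenotype tables, association tables and BED intervals for
significant loci.
"""

from __future__ import annotations

import os

import gffutils
import numpy as np
import pandas as pd

from .types import Annotation, Gene, GenotypeTensor, PhenotypeMatrix, Transcript

__all__ = [
    "read_genotype_probs",
    "write_genotype_probs",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_phenotypes",
    "write_phenotypes",
    "write_calls_bed",
]

SUM_TOL = 1e-6


def write_genotype_probs(genotypes: GenotypeTensor, path: str) -> None:
    n_r, n_l, _ = genotypes.probs.shape
    loci = genotypes.loci.reset_index(drop=True)
    recs = {
        "ril": np.repeat(genotypes.rils, n_l),
        "chrom": np.tile(loci["chrom"].to_numpy(), n_r),
        "pos": np.tile(loci["pos"].to_numpy(), n_r),
    }
    flat = genotypes.probs.reshape(n_r * n_l, -1)
    for f_i, f in enumerate(genotypes.founders):
        recs[f] = flat[:, f_i]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_genotype_probs(path: str) -> GenotypeTensor:
    """Parse and validate a founder-probability TSV.

    Rows whose probabilities do not sum to 1 (±1e-6) are rejected with
    their line numbers; founder columns are everything after ril/chrom/pos.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["ril", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"genotype file lacks columns {missing}")
    founders = [c for c in df.columns if c not in required]
    if not founders:
        raise ValueError("genotype file has no founder probability columns")
    sums = df[founders].sum(axis=1)
    bad = df.index[np.abs(sums - 1.0) > SUM_TOL]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # +2: header and 1-based
        raise ValueError(
            f"{len(bad)} genotype row(s) with probabilities not summing to 1, "
            f"e.g. file line(s) {lines}"
        )

    rils = list(dict.fromkeys(df["ril"]))
    loci = df.loc[df["ril"] == rils[0], ["chrom", "pos"]].reset_index(drop=True)
    n_l = len(loci)
    probs = np.empty((len(rils), n_l, len(founders)))
    for i, ril in enumerate(rils):
        sub = df[df["ril"] == ril]
        if len(sub) != n_l or not (
            sub["chrom"].to_numpy() == loci["chrom"].to_numpy()
        ).all() or not (sub["pos"].to_numpy() == loci["pos"].to_numpy()).all():
            raise ValueError(f"ril {ril!r} has a locus grid differing from the first ril")
        probs[i] = sub[founders].to_numpy()
    return GenotypeTensor(rils=rils, loci=loci, founders=founders, probs=probs)


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample", "ril", "treatment") if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet lacks columns {missing}")
    bad = sorted(set(df["treatment"]) - {"control", "pb"})
    if bad:
        raise ValueError(f"treatment must be control/pb, found {bad}")
    return df


def write_annotation(annotation: Annotation, path: str) -> None:
    """Emit GTF (1-based closed) with gene, transcript and exon features."""
    with open(path, "w") as fh:
        for gene_id in sorted(annotation.genes):
            g = annotation.genes[gene_id]
            s, e = g.span
            attrs = f'gene_id "{gene_id}";'
            fh.write(
                f"{g.chrom}\tsqtlmap\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx_id in sorted(g.transcripts):
                tx = g.transcripts[tx_id]
                ts, te = tx.span
                tattrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                fh.write(
                    f"{g.chrom}\tsqtlmap\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for xs, xe in tx.exons:
                    fh.write(
                        f"{g.chrom}\tsqtlmap\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def read_annotation(path: str) -> Annotation:
    """Load a GTF through gffutils; exon features lacking a transcript_id
    are an error with their line number."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 9 and fields[2] == "exon" and "transcript_id" not in fields[8]:
                raise ValueError(f"exon without transcript_id at line {ln}")
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, Gene] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.features_of_type("exon"):
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        tx_exons.setdefault(tx_id, []).append((feat.start - 1, feat.end))
        tx_meta[tx_id] = (gene_id, feat.seqid, feat.strand)
    for tx_id, exons in tx_exons.items():
        gene_id, chrom, strand = tx_meta[tx_id]
        gene = genes.setdefault(gene_id, Gene(gene_id=gene_id, chrom=chrom, strand=strand))
        gene.transcripts[tx_id] = Transcript(tx_id, gene_id, chrom, strand, exons)
    return Annotation(genes=genes)


def write_phenotypes(phenos: PhenotypeMatrix, path: str) -> None:
    out = phenos.anchors.join(phenos.values)
    out.to_csv(path, sep="\t", index_label=phenos.values.index.name or "phenotype_id")


def read_phenotypes(path: str, kind: str) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    anchor_cols = ["chrom", "pos", "gene_id"]
    missing = [c for c in anchor_cols if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    return PhenotypeMatrix(
        values=df.drop(columns=anchor_cols), anchors=df[anchor_cols], kind=kind
    )


def write_calls_bed(calls: pd.DataFrame, path: str, bin_size: int = 1) -> None:
    """Significant locus positions as BED (0-based half-open) intervals."""
    with open(path, "w") as fh:
        for _, row in calls.iterrows():
            start = int(row["locus_pos"])
            fh.write(
                f"{row['locus_chrom']}\t{start}\t{start + bin_size}\t"
                f"{row['phenotype_id']}\t0\t+\n"
            )


def ensure_exists(path: str, what: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(f"{what} path does not exist: {path}")
    return path
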