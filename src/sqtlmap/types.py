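"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open throughout the package; GTF (1-based
closed) and BED (0-based half-open) conventions are honoured only at the
file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTensor",
    "Transcript",
    "Gene",
    "Annotation",
    "PlantedEffect",
    "SimTruth",
    "PhenotypeMatrix",
    "IsoformGroup",
    "ModelFit",
    "NormalizationReport",
]

PROB_TOL = 1e-9


@dataclass
class GenotypeTensor:
    """Founder-probability genotypes for a panel of recombinant inbred lines.

    ``probs[i, j, f]`` is the probability that RIL ``i`` carries founder
    ``f``'s haplotype at locus ``j``.  Loci live on a genomic grid sorted by
    (chromosome, position).
    """

    rils: list[str]
    loci: pd.DataFrame  # columns: chrom, pos
    founders: list[str]
    probs: np.ndarray  # (n_rils, n_loci, n_founders)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        expected = (len(self.rils), len(self.loci), len(self.founders))
        if self.probs.shape != expected:
            raise ValueError(
                f"probability tensor has shape {self.probs.shape}, expected {expected}"
            )
        self.validate()

    def validate(self) -> None:
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = np.argwhere(np.abs(sums - 1.0) > 1e-6)
            i, j = bad[0]
            raise ValueError(
                f"founder probabilities must sum to 1: ril {self.rils[i]} "
                f"locus index {j} sums to {sums[i, j]:.6f}"
            )
        if (self.probs < -PROB_TOL).any():
            raise ValueError("negative founder probabilities")
        loci = self.loci.reset_index(drop=True)
        for chrom, grp in loci.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"loci on {chrom} are not strictly increasing")

    @property
    def n_rils(self) -> int:
        return len(self.rils)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def ril_index(self, rils: list[str]) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.rils)}
        try:
            return np.array([lookup[r] for r in rils], dtype=int)
        except KeyError as exc:
            raise KeyError(f"RIL {exc.args[0]!r} not present in genotypes") from exc


@dataclass
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.tx_id}: empty/inverted exon [{s},{e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.tx_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts.values()]
        ends = [t.span[1] for t in self.transcripts.values()]
        return min(starts), max(ends)

    @property
    def anchor(self) -> tuple[str, int]:
        """Genomic anchor: midpoint of the gene span."""
        s, e = self.span
        return self.chrom, (s + e) // 2

    def exon_ids(self) -> dict[str, tuple[int, int]]:
        """Distinct exon intervals across isoforms, keyed by a stable id.

        Ids encode 1-based closed coordinates so they round-trip through GTF.
        """
        out: dict[str, tuple[int, int]] = {}
        for tx in self.transcripts.values():
            for s, e in tx.exons:
                out[f"{self.gene_id}:{s + 1}-{e}"] = (s, e)
        return dict(sorted(out.items(), key=lambda kv: kv[1]))


@dataclass
class Annotation:
    """Gene -> transcript -> exon structure for one genome."""

    genes: dict[str, Gene]

    def __post_init__(self) -> None:
        self._tx_to_gene = {
            tx_id: g.gene_id
            for g in self.genes.values()
            for tx_id in g.transcripts
        }

    @property
    def transcripts(self) -> dict[str, Transcript]:
        return {
            tx_id: tx
            for g in self.genes.values()
            for tx_id, tx in g.transcripts.items()
        }

    def gene_of_transcript(self, tx_id: str) -> str:
        return self._tx_to_gene[tx_id]

    def exon_table(self) -> pd.DataFrame:
        """One row per distinct exon: exon_id, gene_id, chrom, start, end,
        member transcript ids (comma-free list)."""
        rows = []
        for g in self.genes.values():
            ids = g.exon_ids()
            membership: dict[str, list[str]] = {eid: [] for eid in ids}
            for tx_id, tx in g.transcripts.items():
                for s, e in tx.exons:
                    membership[f"{g.gene_id}:{s + 1}-{e}"].append(tx_id)
            for eid, (s, e) in ids.items():
                rows.append(
                    {
                        "exon_id": eid,
                        "gene_id": g.gene_id,
                        "chrom": g.chrom,
                        "start": s,
                        "end": e,
                        "transcripts": tuple(sorted(membership[eid])),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["exon_id", "gene_id", "chrom", "start", "end", "transcripts"],
        )

    def anchors(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g.gene_id, "chrom": g.anchor[0], "pos": g.anchor[1]}
            for g in self.genes.values()
        ]
        return pd.DataFrame(rows).set_index("gene_id")


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effect planted by the simulator.

    kind:
        ``cis_gxe`` — founder- and environment-specific usage shift of one
        isoform, at a locus near the host gene.
        ``trans_hotspot`` — the same shift applied to many genes from a
        single distant locus.
    delta is the shift applied to the target isoform's log mean count for a
    sample carrying the founder haplotype (G=1) in the exposed condition
    (E=1); the realised shift is ``delta * G_fj * E_n``.
    """

    kind: str
    gene_id: str
    tx_id: str
    locus_index: int
    founder_index: int
    delta: float


@dataclass
class SimTruth:
    effects: list[PlantedEffect]
    seed: int

    def validate(self, genotypes: GenotypeTensor, annotation: Annotation) -> None:
        for eff in self.effects:
            if eff.kind not in ("cis_gxe", "trans_hotspot", "null"):
                raise ValueError(f"unknown effect kind {eff.kind!r}")
            if not 0 <= eff.locus_index < genotypes.n_loci:
                raise ValueError(f"planted locus index {eff.locus_index} out of range")
            if not 0 <= eff.founder_index < genotypes.n_founders:
                raise ValueError(f"planted founder index {eff.founder_index} out of range")
            if eff.gene_id not in annotation.genes:
                raise ValueError(f"planted gene {eff.gene_id!r} not in annotation")
            if eff.tx_id not in annotation.genes[eff.gene_id].transcripts:
                raise ValueError(
                    f"planted transcript {eff.tx_id!r} not in gene {eff.gene_id!r}"
                )


@dataclass
class PhenotypeMatrix:
    """Quantitative splicing traits: phenotypes x samples.

    ``anchors`` carries one row per phenotype with columns chrom, pos,
    gene_id (the host gene's midpoint anchors the phenotype for cis/trans
    classification and the sQTL map).
    """

    values: pd.DataFrame
    anchors: pd.DataFrame
    kind: str  # exon_fraction | isoform_dosage

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.anchors.index):
            raise ValueError("values and anchors must share the same phenotype index")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate phenotype ids")


@dataclass
class IsoformGroup:
    """All isoforms of one multi-isoform gene, as a complete samples-by-
    isoform block of normalized expression values."""

    gene_id: str
    chrom: str
    pos: int
    values: pd.DataFrame  # isoforms (rows) x samples (columns)

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError(f"{self.gene_id}: isoform group needs >= 2 isoforms")

    @property
    def isoforms(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ModelFit:
    """One OLS fit: coefficients keyed by design-column name, residual sum of
    squares, residual degrees of freedom, and residuals."""

    coef: pd.Series
    rss: float
    df_resid: int
    rank: int
    resid: np.ndarray


@dataclass
class NormalizationReport:
    n_pc: int
    variance_fractions: list[float]
    target_quantiles: np.ndarray | None = None

    def __post_init__(self) -> None:
        fr = np.asarray(self.variance_fractions, dtype=float)
        if fr.size and ((fr < -1e-12).any() or (fr > 1 + 1e-12).any()):
            raise ValueError("variance fractions must lie in [0, 1]")
        if fr.size > 1 and (np.diff(fr) > 1e-12).any():
            raise ValueError("variance fractions must be non-increasing")
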