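"""Synthetic eight-founder RIL panel with planted splicing G×E effects.

Emulates the structure of a DSPR-style study — ~79 recombinant inbred lines
assayed once in each of two rearing conditions (control vs lead-exposed) —
well enough to exercise the whole mapping pipeline without any download:

* founder-mosaic genotypes as probabilities on a regular locus grid,
  generated by a founder-label Markov chain along each chromosome with an
  optional Dirichlet blur (the real panel's HMM genotyping is not
  re-implemented; the pipeline consumes probabilities, whatever produced
  them);
* a gene/transcript/exon annotation in which extra isoforms of a gene are
  derived from a base transcript by concrete alternative-splicing moves
  (exon skipping, intron retention, donor/acceptor shifts), so downstream
  event classification has real structure to find;
* negative-binomial exon and transcript counts on top of logistic-normal
  isoform proportions, with registered (``SimTruth``) founder-specific,
  environment-conditional isoform-usage effects — either cis (one gene, a
  nearby locus) or a trans hotspot (one locus pushing many genes).

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import Annotation, Gene, GenotypeTensor, PlantedEffect, SimTruth, Transcript

__all__ = [
    "default_locus_grid",
    "simulate_founder_mosaics",
    "make_annotation",
    "make_sample_sheet",
    "design_truth",
    "simulate_counts",
]

DEFAULT_CHROMOSOMES = {"2L": 2_000_000, "2R": 2_000_000, "3L": 2_000_000}
DEFAULT_SPACING = 10_000
DEFAULT_ISOFORM_DIST = {1: 0.45, 2: 0.30, 3: 0.15, 4: 0.10}


def default_locus_grid(
    chromosomes: dict[str, int] | None = None, spacing: int = DEFAULT_SPACING
) -> pd.DataFrame:
    """Regularly spaced locus grid (default 10 kb), one row per locus."""
    chromosomes = chromosomes or DEFAULT_CHROMOSOMES
    rows = [
        {"chrom": chrom, "pos": pos}
        for chrom, length in chromosomes.items()
        for pos in range(spacing, length + 1, spacing)
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def simulate_founder_mosaics(
    n_rils: int,
    loci: pd.DataFrame,
    n_founders: int = 8,
    breakpoint_rate: float = 0.02,
    seed: int = 0,
    blur: float = 0.0,
) -> GenotypeTensor:
    """Generate founder-mosaic genotypes as a label Markov chain per RIL.

    Along each chromosome the founder label switches between consecutive
    grid loci with probability ``breakpoint_rate`` (the new label is drawn
    uniformly among the other founders, so the observed switch frequency
    equals the rate).  Chromosomes restart independently.  With ``blur`` > 0
    the one-hot labels are softened to ``(1-blur)*onehot + blur*Dirichlet(1)``,
    mimicking genotyping uncertainty while keeping each row on the simplex.
    """
    if n_rils < 1:
        raise ValueError("n_rils must be >= 1")
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if not math.isfinite(breakpoint_rate) or breakpoint_rate < 0:
        raise ValueError(f"breakpoint_rate must be finite and >= 0, got {breakpoint_rate}")
    if not 0 <= blur < 1:
        raise ValueError("blur must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    loci = loci.reset_index(drop=True)
    n_loci = len(loci)
    chrom_start = loci["chrom"].ne(loci["chrom"].shift()).to_numpy()

    labels = np.empty((n_rils, n_loci), dtype=int)
    for j in range(n_loci):
        if chrom_start[j]:
            labels[:, j] = rng.integers(0, n_founders, size=n_rils)
        else:
            switch = rng.random(n_rils) < breakpoint_rate
            # a switch always lands on a *different* founder
            offset = rng.integers(1, n_founders, size=n_rils)
            labels[:, j] = np.where(
                switch, (labels[:, j - 1] + offset) % n_founders, labels[:, j - 1]
            )

    probs = np.zeros((n_rils, n_loci, n_founders))
    np.put_along_axis(probs, labels[:, :, None], 1.0, axis=2)
    if blur > 0:
        noise = rng.dirichlet(np.ones(n_founders), size=(n_rils, n_loci))
        probs = (1.0 - blur) * probs + blur * noise

    founders = [f"A{i + 1}" for i in range(n_founders)]
    rils = [f"RIL{i + 1:04d}" for i in range(n_rils)]
    return GenotypeTensor(rils=rils, loci=loci, founders=founders, probs=probs)


def _derive_isoform(
    base_exons: list[tuple[int, int]], rng: np.random.Generator
) -> list[tuple[int, int]] | None:
    """Apply one random alternative-splicing move to a base exon chain."""
    n = len(base_exons)
    moves = []
    if n >= 3:
        moves.append("skip")
    if n >= 2:
        moves.extend(["retain", "alt_donor", "alt_acceptor"])
    if not moves:
        return None
    move = moves[rng.integers(len(moves))]
    exons = list(base_exons)
    if move == "skip":
        drop = int(rng.integers(1, n - 1))  # internal exon only
        del exons[drop]
    elif move == "retain":
        i = int(rng.integers(0, n - 1))  # merge exon i with i+1 across the intron
        exons[i] = (exons[i][0], exons[i + 1][1])
        del exons[i + 1]
    elif move == "alt_donor":
        i = int(rng.integers(0, n - 1))
        gap = exons[i + 1][0] - exons[i][1]
        shift = min(60, max(10, gap // 3))
        exons[i] = (exons[i][0], exons[i][1] + shift)
    else:  # alt_acceptor
        i = int(rng.integers(0, n - 1))
        gap = exons[i + 1][0] - exons[i][1]
        shift = min(60, max(10, gap // 3))
        exons[i + 1] = (exons[i + 1][0] - shift, exons[i + 1][1])
    return exons


def make_annotation(
    n_genes: int,
    seed: int = 0,
    chromosomes: dict[str, int] | None = None,
    isoforms_per_gene: dict[int, float] | None = None,
    exons_per_transcript: tuple[int, int] = (3, 8),
    exon_length: tuple[int, int] = (80, 400),
    intron_length: tuple[int, int] = (200, 2_000),
) -> Annotation:
    """Random but structured annotation: each extra isoform of a gene differs
    from the gene's base transcript by one alternative-splicing move, so
    isoforms genuinely differ in exon content.

    ``isoforms_per_gene`` is a {count: probability} distribution (default
    mirrors a genome where roughly half the genes are single-isoform).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    chromosomes = chromosomes or DEFAULT_CHROMOSOMES
    iso_dist = isoforms_per_gene or DEFAULT_ISOFORM_DIST
    counts = np.array(sorted(iso_dist), dtype=int)
    weights = np.array([iso_dist[c] for c in counts], dtype=float)
    if (counts < 1).any():
        raise ValueError("isoform counts must be >= 1")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    chrom_names = list(chromosomes)
    genes: dict[str, Gene] = {}
    for gi in range(n_genes):
        gene_id = f"g{gi + 1:04d}"
        chrom = chrom_names[gi % len(chrom_names)]
        start = int(rng.integers(1_000, max(2_000, chromosomes[chrom] - 60_000)))
        n_exons = int(rng.integers(exons_per_transcript[0], exons_per_transcript[1] + 1))
        pos = start
        base: list[tuple[int, int]] = []
        for _ in range(n_exons):
            length = int(rng.integers(*exon_length))
            base.append((pos, pos + length))
            pos += length + int(rng.integers(*intron_length))
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.choice(counts, p=weights))
        gene = Gene(gene_id=gene_id, chrom=chrom, strand=strand)
        gene.transcripts[f"{gene_id}.t1"] = Transcript(
            f"{gene_id}.t1", gene_id, chrom, strand, base
        )
        made = 1
        attempts = 0
        while made < n_iso and attempts < 20 * n_iso:
            attempts += 1
            exons = _derive_isoform(base, rng)
            if exons is None:
                break
            if any(exons == tx.exons for tx in gene.transcripts.values()):
                continue
            made += 1
            gene.transcripts[f"{gene_id}.t{made}"] = Transcript(
                f"{gene_id}.t{made}", gene_id, chrom, strand, exons
            )
        genes[gene_id] = gene
    return Annotation(genes=genes)


def make_sample_sheet(rils: list[str]) -> pd.DataFrame:
    """Paired design: every RIL assayed once per condition (control, pb)."""
    rows = [
        {"sample": f"{ril}_{cond}", "ril": ril, "treatment": cond}
        for ril in rils
        for cond in ("control", "pb")
    ]
    return pd.DataFrame(rows, columns=["sample", "ril", "treatment"])


def design_truth(
    genotypes: GenotypeTensor,
    annotation: Annotation,
    seed: int,
    n_cis_gxe: int = 0,
    cis_delta: float = 1.5,
    hotspot_genes: int = 0,
    hotspot_delta: float = 1.5,
    founder: str | int = "A3",
) -> SimTruth:
    """Build a planted-effect registry.

    cis effects target multi-isoform genes, each at the grid locus nearest
    the gene's midpoint; the hotspot is one locus (drawn away from its
    target genes) whose haplotype shifts isoform usage of ``hotspot_genes``
    genes in the exposed condition only.
    """
    rng = np.random.default_rng(seed)
    f_idx = (
        genotypes.founders.index(founder) if isinstance(founder, str) else int(founder)
    )
    multi = [g for g in annotation.genes.values() if len(g.transcripts) >= 2]
    need = n_cis_gxe + hotspot_genes
    if need > len(multi):
        raise ValueError(
            f"requested {need} target genes but only {len(multi)} multi-isoform genes exist"
        )
    chosen = list(rng.choice(len(multi), size=need, replace=False))
    loci = genotypes.loci

    def nearest_locus(chrom: str, pos: int) -> int:
        on = loci.index[loci["chrom"] == chrom]
        if len(on) == 0:
            raise ValueError(f"no loci on chromosome {chrom}")
        return int(on[np.argmin(np.abs(loci.loc[on, "pos"].to_numpy() - pos))])

    effects: list[PlantedEffect] = []
    for g_i in chosen[:n_cis_gxe]:
        gene = multi[g_i]
        chrom, mid = gene.anchor
        tx_ids = sorted(gene.transcripts)
        tx = tx_ids[1 + rng.integers(len(tx_ids) - 1)]  # a non-base isoform
        effects.append(
            PlantedEffect(
                "cis_gxe", gene.gene_id, tx, nearest_locus(chrom, mid), f_idx, cis_delta
            )
        )
    if hotspot_genes:
        hot = int(rng.integers(genotypes.n_loci))
        for g_i in chosen[n_cis_gxe:]:
            gene = multi[g_i]
            tx_ids = sorted(gene.transcripts)
            tx = tx_ids[1 + rng.integers(len(tx_ids) - 1)]
            effects.append(
                PlantedEffect("trans_hotspot", gene.gene_id, tx, hot, f_idx, hotspot_delta)
            )
    truth = SimTruth(effects=effects, seed=int(seed))
    truth.validate(genotypes, annotation)
    return truth


def simulate_counts(
    genotypes: GenotypeTensor,
    annotation: Annotation,
    samples: pd.DataFrame,
    truth: SimTruth | None,
    nb_dispersion: float = 0.05,
    depth: float = 200_000.0,
    seed: int = 0,
    sigma_gene: float = 1.0,
    sigma_isoform: float = 0.8,
    sigma_noise: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw exon- and transcript-level count tables.

    Per gene g: relative expression ~ lognormal(``sigma_gene``) across genes
    (normalised to ``depth`` reads per sample in expectation); isoform
    baseline log-proportions ~ N(0, ``sigma_isoform``); per sample the
    isoform log-means receive iid N(0, ``sigma_noise``) biological noise plus
    any planted shift ``delta * G_fj * E_n`` before softmax.  Transcript
    counts are negative binomial with variance ``mu + nb_dispersion * mu^2``;
    exon counts partition each transcript's reads across its exons by a
    length-proportional multinomial, so exon-level and transcript-level
    tables are consistent by construction.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    truth = truth if truth is not None else SimTruth(effects=[], seed=int(seed))
    truth.validate(genotypes, annotation)

    rng = np.random.default_rng(seed)
    samples = samples.reset_index(drop=True)
    sample_ids = samples["sample"].tolist()
    ril_idx = genotypes.ril_index(samples["ril"].tolist())
    env = (samples["treatment"].to_numpy() == "pb").astype(float)
    n_samp = len(samples)

    gene_ids = sorted(annotation.genes)
    rel = np.exp(rng.normal(0.0, sigma_gene, size=len(gene_ids)))
    rel /= rel.sum()

    # planted shifts grouped by transcript
    shifts: dict[str, np.ndarray] = {}
    for eff in truth.effects:
        if eff.kind == "null" or eff.delta == 0:
            continue
        dose = genotypes.probs[ril_idx, eff.locus_index, eff.founder_index]
        shifts.setdefault(eff.tx_id, np.zeros(n_samp))
        shifts[eff.tx_id] += eff.delta * dose * env

    tx_rows: dict[str, np.ndarray] = {}
    exon_rows: dict[str, np.ndarray] = {}
    for g_i, gene_id in enumerate(gene_ids):
        gene = annotation.genes[gene_id]
        tx_ids = sorted(gene.transcripts)
        K = len(tx_ids)
        eta0 = rng.normal(0.0, sigma_isoform, size=K)
        eta = (
            eta0[None, :]
            + rng.normal(0.0, sigma_noise, size=(n_samp, K))
        )
        eta -= eta.max(axis=1, keepdims=True)
        props = np.exp(eta)
        props /= props.sum(axis=1, keepdims=True)
        mu = depth * rel[g_i] * props  # (n_samp, K)
        # planted usage shifts multiply the target isoform's mean count, so
        # the realised effect is exactly delta*G*E on the log-count scale
        for k, tx_id in enumerate(tx_ids):
            if tx_id in shifts:
                mu[:, k] = mu[:, k] * np.exp(shifts[tx_id])

        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mu * nb_dispersion)
        counts = rng.poisson(lam)  # (n_samp, K)

        gene_exons = gene.exon_ids()
        exon_counts = {eid: np.zeros(n_samp, dtype=int) for eid in gene_exons}
        for k, tx_id in enumerate(tx_ids):
            tx = gene.transcripts[tx_id]
            lens = np.array([e - s for s, e in tx.exons], dtype=float)
            p = lens / lens.sum()
            alloc = rng.multinomial(counts[:, k], p)  # (n_samp, n_exons)
            for x, (s, e) in enumerate(tx.exons):
                exon_counts[f"{gene_id}:{s + 1}-{e}"] += alloc[:, x]
            tx_rows[tx_id] = counts[:, k]
        exon_rows.update(exon_counts)

    tx_df = pd.DataFrame(tx_rows, index=sample_ids).T.astype(int)
    exon_df = pd.DataFrame(exon_rows, index=sample_ids).T.astype(int)
    tx_df.index.name = "transcript_id"
    exon_df.index.name = "exon_id"
    return exon_df, tx_df, truth
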