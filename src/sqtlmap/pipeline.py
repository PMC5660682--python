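"""End-to-end orchestration: simulate (optional) -> phenotypes -> normalize
-> scan -> FDR/classification/hotspots -> AS events -> differential
expression.  Every stage's output is written under the configured output
directory together with a manifest of all parameters and seeds, so a rerun
with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import fdr, io, normalize, phenotype, simulate
from .events import summarize_events
from .scan import ScanConfig, differential_expression, scan
from .types import Annotation, GenotypeTensor

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_rils: int = 79
    n_founders: int = 8
    chromosomes: dict[str, int] = field(
        default_factory=lambda: dict(simulate.DEFAULT_CHROMOSOMES)
    )
    spacing: int = simulate.DEFAULT_SPACING
    breakpoint_rate: float = 0.02
    blur: float = 0.05
    n_genes: int = 60
    depth: float = 200_000.0
    nb_dispersion: float = 0.05
    n_cis_gxe: int = 3
    cis_delta: float = 1.5
    hotspot_genes: int = 0
    hotspot_delta: float = 1.5
    founder: str = "A3"


@dataclass
class NormalizeConfig:
    n_pc_exon: int = 3
    n_pc_isoform: int = 4
    protect_environment: bool = True
    zero_policy: str = "drop"
    max_missing_frac: float = 0.2


@dataclass
class ThresholdConfig:
    p_thresh: float = fdr.DEFAULT_P_THRESH
    q_thresh: float = fdr.DEFAULT_Q_THRESH
    cis_window: int = fdr.DEFAULT_CIS_WINDOW
    bin_size: int = 100_000
    n_perm: int = 2_000

    def __post_init__(self) -> None:
        if not 0 < self.p_thresh <= 1 or not 0 < self.q_thresh <= 1:
            raise ValueError("p_thresh and q_thresh must lie in (0, 1]")
        if self.cis_window < 0 or self.bin_size <= 0:
            raise ValueError("cis_window must be >= 0 and bin_size > 0")


@dataclass
class PathConfig:
    genotypes: str | None = None
    exon_counts: str | None = None
    transcript_counts: str | None = None
    annotation: str | None = None
    samples: str | None = None


@dataclass
class PipelineConfig:
    outdir: str = "sqtlmap_out"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    paths: PathConfig = field(default_factory=PathConfig)
    model: ScanConfig = field(default_factory=ScanConfig)

    def validate(self) -> None:
        if not self.simulate.enabled:
            for name in ("genotypes", "exon_counts", "transcript_counts", "annotation", "samples"):
                path = getattr(self.paths, name)
                if path is None:
                    raise ValueError(
                        f"simulation disabled but no {name} path configured"
                    )
                io.ensure_exists(path, name)


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(
        outdir=raw.get("outdir", "sqtlmap_out"),
        seed=int(raw.get("seed", 0)),
        simulate=SimulateConfig(**raw.get("simulate", {})),
        normalize=NormalizeConfig(**raw.get("normalize", {})),
        thresholds=ThresholdConfig(**raw.get("thresholds", {})),
        paths=PathConfig(**raw.get("paths", {})),
        model=ScanConfig(**raw.get("model", {})),
    )
    cfg.validate()
    return cfg


def _simulate_inputs(cfg: PipelineConfig, outdir: str):
    sc = cfg.simulate
    loci = simulate.default_locus_grid(sc.chromosomes, sc.spacing)
    genotypes = simulate.simulate_founder_mosaics(
        sc.n_rils, loci, sc.n_founders, sc.breakpoint_rate, seed=cfg.seed, blur=sc.blur
    )
    annotation = simulate.make_annotation(
        sc.n_genes, seed=cfg.seed + 1, chromosomes=sc.chromosomes
    )
    samples = simulate.make_sample_sheet(genotypes.rils)
    truth = simulate.design_truth(
        genotypes,
        annotation,
        seed=cfg.seed + 2,
        n_cis_gxe=sc.n_cis_gxe,
        cis_delta=sc.cis_delta,
        hotspot_genes=sc.hotspot_genes,
        hotspot_delta=sc.hotspot_delta,
        founder=sc.founder,
    )
    exon_counts, tx_counts, truth = simulate.simulate_counts(
        genotypes,
        annotation,
        samples,
        truth,
        nb_dispersion=sc.nb_dispersion,
        depth=sc.depth,
        seed=cfg.seed + 3,
    )
    io.write_genotype_probs(genotypes, os.path.join(outdir, "genotypes.tsv"))
    io.write_annotation(annotation, os.path.join(outdir, "annotation.gtf"))
    io.write_sample_sheet(samples, os.path.join(outdir, "samples.tsv"))
    io.write_counts(exon_counts, os.path.join(outdir, "exon_counts.tsv"))
    io.write_counts(tx_counts, os.path.join(outdir, "transcript_counts.tsv"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump([dataclasses.asdict(e) for e in truth.effects], fh, indent=1)
    return genotypes, annotation, samples, exon_counts, tx_counts, truth


def _load_inputs(cfg: PipelineConfig):
    p = cfg.paths
    genotypes = io.read_genotype_probs(p.genotypes)
    annotation = io.read_annotation(p.annotation)
    samples = io.read_sample_sheet(p.samples)
    exon_counts = io.read_counts(p.exon_counts)
    tx_counts = io.read_counts(p.transcript_counts)
    return genotypes, annotation, samples, exon_counts, tx_counts, None


def _normalized_phenotypes(
    exon_counts: pd.DataFrame,
    tx_counts: pd.DataFrame,
    annotation: Annotation,
    samples: pd.DataFrame,
    ncfg: NormalizeConfig,
):
    """Both traits, quantile-normalized with leading PCs removed."""
    env = None
    if ncfg.protect_environment:
        sheet = samples.set_index("sample")
        env = (sheet.loc[exon_counts.columns, "treatment"].to_numpy() == "pb").astype(float)

    frac = phenotype.exon_fraction(
        exon_counts,
        tx_counts,
        annotation,
        zero_policy=ncfg.zero_policy,
        max_missing_frac=ncfg.max_missing_frac,
    )
    qn = normalize.quantile_normalize(frac.values)
    resid, exon_report = normalize.remove_pcs(qn, ncfg.n_pc_exon, protect=env)
    frac.values.iloc[:, :] = resid

    logtx = np.log2(tx_counts.astype(float) + 1.0)
    qn_tx = normalize.quantile_normalize(logtx)
    resid_tx, iso_report = normalize.remove_pcs(qn_tx, ncfg.n_pc_isoform, protect=env)
    groups = phenotype.isoform_groups(tx_counts, annotation)
    for g in groups:
        g.values = resid_tx.loc[g.values.index]
    return frac, groups, exon_report, iso_report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle in memory and
    writes every table under ``config.outdir``."""
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)

    if config.simulate.enabled:
        genotypes, annotation, samples, exon_counts, tx_counts, truth = _simulate_inputs(
            config, outdir
        )
    else:
        genotypes, annotation, samples, exon_counts, tx_counts, truth = _load_inputs(config)

    stage = "phenotypes"
    try:
        frac, groups, exon_report, iso_report = _normalized_phenotypes(
            exon_counts, tx_counts, annotation, samples, config.normalize
        )
        io.write_phenotypes(frac, os.path.join(outdir, "exon_fraction.tsv"))

        stage = "scan"
        assoc_exon = scan(frac, genotypes, samples, config.model,
                          out=os.path.join(outdir, "assoc_exon.tsv"))
        assoc_iso = scan(groups, genotypes, samples, config.model,
                         out=os.path.join(outdir, "assoc_isoform.tsv"))

        stage = "fdr_classify"
        th = config.thresholds
        calls_exon = fdr.call_significant(assoc_exon, th.p_thresh, th.q_thresh)
        calls_iso = fdr.call_significant(assoc_iso, th.p_thresh, th.q_thresh)
        union, overlap = fdr.combine_methods(calls_exon, calls_iso)
        union = fdr.classify_cis_trans(union, th.cis_window)
        hotspots, profile = fdr.find_hotspots(
            union, bin_size=th.bin_size, n_perm=th.n_perm, seed=config.seed + 4
        )
        union.to_csv(os.path.join(outdir, "calls.tsv"), sep="\t", index=False)
        io.write_calls_bed(union, os.path.join(outdir, "calls.bed"))
        hotspots.to_csv(os.path.join(outdir, "hotspots.tsv"), sep="\t", index=False)
        profile.to_csv(os.path.join(outdir, "hotspot_profile.tsv"), sep="\t", index=False)
        map_df = union[["locus_chrom", "locus_pos", "pheno_chrom", "pheno_pos"]]
        map_df.to_csv(os.path.join(outdir, "sqtl_map.tsv"), sep="\t", index=False)

        stage = "as_events"
        events = summarize_events(union, annotation)
        events.to_csv(os.path.join(outdir, "as_events.tsv"), sep="\t")

        stage = "differential_expression"
        de = differential_expression(tx_counts, samples)
        de.to_csv(os.path.join(outdir, "differential_expression.tsv"), sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "simulate": dataclasses.asdict(config.simulate),
        "normalize": dataclasses.asdict(config.normalize),
        "thresholds": dataclasses.asdict(config.thresholds),
        "model": dataclasses.asdict(config.model),
        "counts": {
            "exon_phenotypes": int(len(frac.values)),
            "isoform_groups": int(len(groups)),
            "loci": int(genotypes.n_loci),
            "assoc_exon": int(len(assoc_exon)),
            "assoc_isoform": int(len(assoc_iso)),
            "calls_exon": int(len(calls_exon)),
            "calls_isoform": int(len(calls_iso)),
            "overlap": overlap,
            "hotspots": int(len(hotspots)),
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("pipeline complete: %s", json.dumps(manifest["counts"]))
    return {
        "genotypes": genotypes,
        "annotation": annotation,
        "samples": samples,
        "truth": truth,
        "exon_phenotypes": frac,
        "isoform_groups": groups,
        "assoc_exon": assoc_exon,
        "assoc_isoform": assoc_iso,
        "calls_exon": calls_exon,
        "calls_isoform": calls_iso,
        "union": union,
        "overlap": overlap,
        "hotspots": hotspots,
        "hotspot_profile": profile,
        "events": events,
        "de": de,
        "manifest": manifest,
    }
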