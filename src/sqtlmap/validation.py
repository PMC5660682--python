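"""Synthetic-benchmark validation scenarios.

Self-contained experiments that exercise the pipeline on generated panels
with known ground truth: null calibration of the two nested models,
planted-effect recovery, realized false-discovery proportion under FDR
calls, and trans-hotspot detection.  Problem sizes are chosen so each
scenario runs in seconds to a few minutes on one CPU; the methods note
documents them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import fdr, simulate
from .normalize import quantile_normalize, remove_pcs
from .phenotype import exon_fraction, isoform_groups
from .scan import fit_exon_model, fit_isoform_model, scan

__all__ = [
    "null_pvalues",
    "recovery_rate",
    "fdp_at_q",
    "hotspot_recovery",
    "hotspot_null_rate",
]

TWO_CHROMS = {"2L": 1_000_000, "3L": 1_000_000}


def _panel(seed, n_rils, n_genes, chromosomes, spacing, breakpoint_rate,
           truth_kwargs=None, isoforms_per_gene=None):
    loci = simulate.default_locus_grid(chromosomes, spacing)
    geno = simulate.simulate_founder_mosaics(
        n_rils, loci, 8, breakpoint_rate, seed=seed, blur=0.05
    )
    ann = simulate.make_annotation(
        n_genes, seed=seed + 1, chromosomes=chromosomes,
        isoforms_per_gene=isoforms_per_gene,
    )
    samples = simulate.make_sample_sheet(geno.rils)
    truth = (
        simulate.design_truth(geno, ann, seed=seed + 2, **truth_kwargs)
        if truth_kwargs
        else None
    )
    exon_counts, tx_counts, truth = simulate.simulate_counts(
        geno, ann, samples, truth, seed=seed + 3
    )
    return geno, ann, samples, exon_counts, tx_counts, truth


def _env(samples: pd.DataFrame) -> np.ndarray:
    return (samples["treatment"].to_numpy() == "pb").astype(float)


def _normalized_fraction(exon_counts, tx_counts, ann, env, n_pc=3):
    frac = exon_fraction(exon_counts, tx_counts, ann)
    resid, _ = remove_pcs(quantile_normalize(frac.values), n_pc, protect=env)
    frac.values = resid
    return frac


def _normalized_transcripts(tx_counts, env, n_pc=4):
    qn = quantile_normalize(np.log2(tx_counts.astype(float) + 1.0))
    if n_pc == 0:
        return qn
    resid, _ = remove_pcs(qn, n_pc, protect=env)
    return resid


def null_pvalues(seed: int, n_tests: int = 2_000) -> tuple[np.ndarray, np.ndarray]:
    """p-values from ``n_tests`` null fits of each model on an effect-free
    panel (79 RILs, both conditions, full normalization).  Loci are drawn
    with a high recombination rate so the sampled tests are nearly
    independent."""
    geno, ann, samples, exon_counts, tx_counts, _ = _panel(
        seed, 79, 120, TWO_CHROMS, 10_000, breakpoint_rate=0.5
    )
    env = _env(samples)
    ril_idx = geno.ril_index(samples["ril"].tolist())
    rng = np.random.default_rng(seed + 9)

    frac = _normalized_fraction(exon_counts, tx_counts, ann, env)
    pids = list(frac.values.index)
    p_exon = []
    for _ in range(n_tests):
        y = frac.values.loc[pids[rng.integers(len(pids))]].to_numpy()
        j = rng.integers(geno.n_loci)
        _, _, rec = fit_exon_model(y, geno.probs[ril_idx, j, :], env)
        p_exon.append(rec["p"])

    resid_tx = _normalized_transcripts(tx_counts, env)
    groups = isoform_groups(tx_counts, ann)
    p_iso = []
    for _ in range(n_tests):
        grp = groups[rng.integers(len(groups))]
        j = rng.integers(geno.n_loci)
        _, _, rec = fit_isoform_model(
            resid_tx.loc[grp.values.index].to_numpy(), geno.probs[ril_idx, j, :], env
        )
        p_iso.append(rec["p"])

    def clean(p):
        p = np.asarray(p, dtype=float)
        return p[np.isfinite(p)]

    return clean(p_exon), clean(p_iso)


def planted_pair_pvalue(seed: int, delta: float = 1.5, n_rils: int = 100) -> float:
    """Smallest p-value either splicing trait achieves for one planted
    founder-specific G×E effect, at the planted locus, after the full
    normalization stack."""
    geno, ann, samples, exon_counts, tx_counts, truth = _panel(
        seed, n_rils, 100, TWO_CHROMS, 10_000, breakpoint_rate=0.02,
        truth_kwargs={"n_cis_gxe": 1, "cis_delta": delta},
    )
    env = _env(samples)
    ril_idx = geno.ril_index(samples["ril"].tolist())
    eff = truth.effects[0]
    G_j = geno.probs[ril_idx, eff.locus_index, :]

    resid_tx = _normalized_transcripts(tx_counts, env)
    tx_ids = sorted(ann.genes[eff.gene_id].transcripts)
    _, _, rec = fit_isoform_model(resid_tx.loc[tx_ids].to_numpy(), G_j, env)
    best = rec["p"] if np.isfinite(rec["p"]) else 1.0

    frac = _normalized_fraction(exon_counts, tx_counts, ann, env)
    for pid in frac.values.index[frac.anchors["gene_id"] == eff.gene_id]:
        _, _, r = fit_exon_model(frac.values.loc[pid].to_numpy(), G_j, env)
        if np.isfinite(r["p"]):
            best = min(best, r["p"])
    return float(best)


def recovery_rate(
    seed: int, n_seeds: int = 20, delta: float = 1.5, p_thresh: float = 1e-4
) -> float:
    """Fraction of independent panels in which the planted (phenotype,
    locus) pair reaches ``p_thresh``."""
    hits = sum(
        planted_pair_pvalue(seed + 1_000 * s, delta=delta) < p_thresh
        for s in range(n_seeds)
    )
    return hits / n_seeds


def fdp_at_q(
    seed: int,
    n_seeds: int = 20,
    q_thresh: float = 0.39,
    n_genes: int = 200,
    planted_frac: float = 0.05,
    truth_window: int = 500_000,
) -> float:
    """Mean realized false-discovery proportion among exon-fraction scan
    calls at ``q <= q_thresh``, over ``n_seeds`` panels with
    ``planted_frac`` of the genes carrying a cis G×E effect.  A call is
    true when its gene is planted and its locus lies within
    ``truth_window`` of the planted locus on the same chromosome."""
    fdps = []
    for s in range(n_seeds):
        sd = seed + 1_000 * s
        geno, ann, samples, exon_counts, tx_counts, truth = _panel(
            sd, 79, n_genes, TWO_CHROMS, 25_000, breakpoint_rate=0.05,
            truth_kwargs={
                "n_cis_gxe": max(1, round(planted_frac * n_genes)),
                "cis_delta": 1.5,
            },
        )
        env = _env(samples)
        frac = _normalized_fraction(exon_counts, tx_counts, ann, env)
        assoc = scan(frac, geno, samples)
        q, _ = fdr.qvalues(assoc["p"].to_numpy())
        assoc["q"] = q
        calls = assoc[assoc["q"] <= q_thresh]
        planted = {
            e.gene_id: (
                geno.loci.iloc[e.locus_index]["chrom"],
                int(geno.loci.iloc[e.locus_index]["pos"]),
            )
            for e in truth.effects
        }
        if calls.empty:
            fdps.append(0.0)
            continue
        hit = planted.get
        fp = 0
        for gene, lc, lp in zip(calls["gene_id"], calls["locus_chrom"], calls["locus_pos"]):
            pl = hit(gene)
            if not (pl and lc == pl[0] and abs(lp - pl[1]) <= truth_window):
                fp += 1
        fdps.append(fp / len(calls))
    return float(np.mean(fdps))


@dataclass
class HotspotResult:
    n_hotspots: int
    planted_inside: bool
    peak_genes: int


def hotspot_recovery(seed: int, n_target_genes: int = 50) -> HotspotResult:
    """One panel with a planted trans hotspot driving ``n_target_genes``
    genes; the isoform-dosage scan is run genome-wide on quantile-normalized
    data (no PC removal: at this panel size the hotspot genes are a
    macroscopic variance fraction and leading PCs would absorb the very
    signal; see the methods note)."""
    chroms = {"2L": 1_500_000, "3L": 1_500_000}
    geno, ann, samples, exon_counts, tx_counts, truth = _panel(
        seed, 79, 150, chroms, 25_000, breakpoint_rate=0.05,
        truth_kwargs={"hotspot_genes": n_target_genes, "hotspot_delta": 1.5},
        isoforms_per_gene={2: 0.5, 3: 0.3, 4: 0.2},
    )
    env = _env(samples)
    resid_tx = _normalized_transcripts(tx_counts, env, n_pc=0)
    groups = isoform_groups(tx_counts, ann)
    for grp in groups:
        grp.values = resid_tx.loc[grp.values.index]
    assoc = scan(groups, geno, samples)
    calls = fdr.classify_cis_trans(fdr.call_significant(assoc))
    hot, _ = fdr.find_hotspots(
        calls, bin_size=200_000, n_perm=500, seed=seed + 4, loci=geno.loci
    )
    hc = geno.loci.iloc[truth.effects[0].locus_index]
    inside = bool(
        len(hot)
        and (
            (hot["chrom"] == hc["chrom"])
            & (hot["start"] <= int(hc["pos"]))
            & (int(hc["pos"]) < hot["end"])
        ).any()
    )
    peak = int(hot["n_genes"].max()) if len(hot) else 0
    return HotspotResult(n_hotspots=len(hot), planted_inside=inside, peak_genes=peak)


def hotspot_null_rate(seed: int, n_seeds: int = 20) -> float:
    """Fraction of uniformly-scattered synthetic call tables yielding zero
    hotspots at the Bonferroni cutoff."""
    loci = simulate.default_locus_grid({"2L": 1_500_000, "3L": 1_500_000}, 25_000)
    zero = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1_000 * s)
        n = 200
        idx = rng.integers(0, len(loci), n)
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in rng.integers(0, 150, n)],
                "locus_chrom": loci["chrom"].to_numpy()[idx],
                "locus_pos": loci["pos"].to_numpy()[idx],
                "p": rng.uniform(0.0, 1e-4, n),
                "cis_trans": "trans",
            }
        )
        hot, _ = fdr.find_hotspots(
            calls, bin_size=200_000, n_perm=500, seed=seed + s, loci=loci
        )
        zero += len(hot) == 0
    return zero / n_seeds


def ks_uniform(p: np.ndarray) -> tuple[float, float]:
    """Kolmogorov–Smirnov statistic and p-value of p-values against U(0,1)."""
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)
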