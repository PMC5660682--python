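"""Nested genotype-by-environment linear models and the genome scan.

At every (phenotype, locus) pair two ordinary-least-squares models are fit
and compared by a partial F-test:

exon-fraction trait (univariate response Y_n):

    H0:  Y_n = mu + bE * E_n + eps_n
    HA:  Y_n = mu + bE * E_n + sum_i (bG_i * G_ij + bGxE_i * G_ij * E_n) + eps_n

isoform-dosage trait (long-format response Y_nk over isoforms k):

    H0:  Y_nk = mu_k + sum_i bG_i * G_ij + sum_k bE_k * T_k * E_n + eps_nk
    HA:  Y_nk = mu_k + sum_ik (bG_ik * G_ij * T_k + bGxE_ik * T_k * G_ij * E_n)
               + sum_k bE_k * T_k * E_n + eps_nk

G_ij is the probability that the sample's RIL descends from founder i at
locus j; E_n is the 0/1 environment (control vs lead).  Because the eight
founder probabilities sum to one, one founder column (default the last) is
dropped from genotype and interaction blocks; the F statistic is invariant
to that choice since only the column span matters.  Degrees of freedom come
from design-matrix ranks, so all-zero founder columns never change the
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeTensor, IsoformGroup, ModelFit, PhenotypeMatrix

__all__ = [
    "ScanConfig",
    "fit_exon_model",
    "fit_isoform_model",
    "scan",
    "n_tests",
    "differential_expression",
]

log = logging.getLogger(__name__)

ASSOC_COLUMNS = [
    "phenotype_id",
    "gene_id",
    "pheno_chrom",
    "pheno_pos",
    "locus_chrom",
    "locus_pos",
    "method",
    "F",
    "df1",
    "df2",
    "p",
    "top_founder",
]


@dataclass
class ScanConfig:
    ref_founder: str | None = None  # default: last founder
    tested_block: str = "as_printed"  # or "gxe_only"
    sample_intercepts: bool = True  # per-sample intercepts in the isoform model
    cis_window: int | None = None  # restrict loci to +/- window around the anchor
    min_founder_mass: float = 0.0  # drop founder columns with less total mass

    def __post_init__(self) -> None:
        if self.tested_block not in ("as_printed", "gxe_only"):
            raise ValueError(f"unknown tested_block {self.tested_block!r}")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares via lstsq: (coef, rss, rank)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid), int(rank)


def _partial_f(
    rss0: float, rank0: int, rss1: float, rank1: int, n_obs: int
) -> tuple[float, int, int, float]:
    """Partial F-test between nested fits; returns (F, df1, df2, p)."""
    df1 = rank1 - rank0
    df2 = n_obs - rank1
    if df1 <= 0 or df2 <= 0:
        return np.nan, max(df1, 0), max(df2, 0), np.nan
    if rss0 <= 1e-12:  # constant/perfectly-explained response under H0
        return 0.0, df1, df2, 1.0
    F = ((rss0 - rss1) / df1) / (rss1 / df2)
    F = max(F, 0.0)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def _founder_blocks(
    G: np.ndarray, founders: list[str], ref: str | None, min_mass: float
) -> tuple[np.ndarray, list[str]]:
    """Drop the reference founder column plus any carrying (almost) no mass.

    If the reference column itself is empty, the simplex redundancy with the
    intercept is still present among the remaining founders, so the last
    kept column takes over as the reference.  This makes the statistic
    invariant to padding G with zero-probability dummy founders.
    """
    ref = ref if ref is not None else founders[-1]
    if ref not in founders:
        raise ValueError(f"reference founder {ref!r} not in {founders}")
    keep = [
        i
        for i, f in enumerate(founders)
        if f != ref and G[:, i].sum() > max(min_mass, 1e-12)
    ]
    if keep and np.allclose(G[:, keep].sum(axis=1), 1.0, atol=1e-6):
        keep = keep[:-1]  # dropped columns carried no mass: re-drop a reference
    return G[:, keep], [founders[i] for i in keep]


def fit_exon_model(
    y: np.ndarray,
    G_j: np.ndarray,
    E: np.ndarray,
    founders: list[str] | None = None,
    ref_founder: str | None = None,
    min_founder_mass: float = 0.0,
) -> tuple[ModelFit, ModelFit, dict]:
    """Fit the univariate nested pair at one locus.

    Missing phenotype values are dropped pairwise.  Returns the H0 fit, the
    HA fit and a record dict with F, df1, df2, p, top_founder and a
    ``flagged`` marker (True with p = NaN when the alternative design is
    rank-deficient beyond the planned reference drop, or when fewer than two
    samples remain per environment).
    """
    y = np.asarray(y, dtype=float)
    G_j = np.asarray(G_j, dtype=float)
    E = np.asarray(E, dtype=float)
    founders = founders or [f"A{i + 1}" for i in range(G_j.shape[1])]
    mask = ~np.isnan(y)
    y, G_j, E = y[mask], G_j[mask], E[mask]
    n = y.size

    record = {"F": np.nan, "df1": 0, "df2": 0, "p": np.nan, "top_founder": "", "flagged": True}
    empty = ModelFit(coef=pd.Series(dtype=float), rss=np.nan, df_resid=0, rank=0, resid=np.array([]))
    if n == 0 or min((E == 0).sum(), (E == 1).sum()) < 2:
        return empty, empty, record

    Gk, kept = _founder_blocks(G_j, founders, ref_founder, min_founder_mass)
    ones = np.ones(n)
    X0 = np.column_stack([ones, E])
    XA = np.column_stack([ones, E, Gk, Gk * E[:, None]])
    names0 = ["mu", "bE"]
    namesA = names0 + [f"bG[{f}]" for f in kept] + [f"bGxE[{f}]" for f in kept]

    c0, rss0, rank0 = _ols(X0, y)
    cA, rss1, rank1 = _ols(XA, y)
    deficient = rank1 < XA.shape[1]
    F, df1, df2, p = _partial_f(rss0, rank0, rss1, rank1, n)
    if deficient or np.isnan(F):
        F, p = np.nan, np.nan

    gxe = cA[2 + len(kept) :]
    top = kept[int(np.argmax(np.abs(gxe)))] if len(kept) and np.isfinite(F) else ""
    record.update(
        F=F, df1=df1, df2=df2, p=p, top_founder=top, flagged=bool(deficient or not np.isfinite(F))
    )
    fit0 = ModelFit(pd.Series(c0, index=names0), rss0, n - rank0, rank0, y - X0 @ c0)
    fitA = ModelFit(pd.Series(cA, index=namesA), rss1, n - rank1, rank1, y - XA @ cA)
    return fit0, fitA, record


def _isoform_design(
    Y: np.ndarray,
    E: np.ndarray,
    kept: list[str],
    Gk: np.ndarray,
    tested_block: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Long-format nested designs.  Y is (K isoforms, n samples); the long
    vector is isoform-major (all samples of isoform 0, then isoform 1, ...)."""
    K, n = Y.shape
    y_long = Y.reshape(-1)
    T = np.repeat(np.eye(K), n, axis=0)  # (K*n, K) isoform dummies
    Gl = np.tile(Gk, (K, 1))  # shared founder columns
    El = np.tile(E, K)
    ET = T * El[:, None]  # per-isoform environment
    GT = np.concatenate([T[:, [k]] * Gl for k in range(K)], axis=1)
    GET = GT * El[:, None]

    names_common = [f"mu[{k}]" for k in range(K)] + [f"bE[{k}]" for k in range(K)]
    gt_names = [f"bG[{f},{k}]" for k in range(K) for f in kept]
    get_names = [f"bGxE[{f},{k}]" for k in range(K) for f in kept]
    if tested_block == "as_printed":
        X0 = np.column_stack([T, ET, Gl])
        names0 = names_common + [f"bG[{f}]" for f in kept]
    else:  # gxe_only: genotype-by-isoform main effects already under H0
        X0 = np.column_stack([T, ET, GT])
        names0 = names_common + gt_names
    XA = np.column_stack([T, ET, GT, GET])
    namesA = names_common + gt_names + get_names
    return y_long, X0, XA, names0, namesA


def _absorb_samples(M: np.ndarray, K: int, n: int) -> np.ndarray:
    """Within-sample demeaning over the K isoform cells — the projection
    equivalent of adding one intercept dummy per sample."""
    A = M.reshape(K, n, -1) if M.ndim == 2 else M.reshape(K, n)
    out = A - A.mean(axis=0, keepdims=True)
    return out.reshape(M.shape)


def fit_isoform_model(
    group: IsoformGroup | np.ndarray,
    G_j: np.ndarray,
    E: np.ndarray,
    founders: list[str] | None = None,
    ref_founder: str | None = None,
    tested_block: str = "as_printed",
    sample_intercepts: bool = True,
    min_founder_mass: float = 0.0,
) -> tuple[ModelFit, ModelFit, dict]:
    """Fit the long-format nested pair for one multi-isoform gene.

    Under ``as_printed`` the null carries genotype main effects shared
    across isoforms and the alternative adds genotype-by-isoform and
    genotype-by-environment-by-isoform blocks (joint partial F).  Under
    ``gxe_only`` the genotype-by-isoform block is already in the null and
    only the three-way block is tested.

    With ``sample_intercepts`` (default) both models additionally carry one
    intercept per sample, absorbed by within-sample demeaning: isoform
    counts of one gene share sample-level noise (library size, overall
    expression), and without the intercepts the homoscedastic-independence
    F-test is anti-conservative under the null.  The tested interaction
    blocks then measure purely isoform-differential (usage) effects.
    Setting it False reproduces the bare long-format design.
    """
    Y = group.values.to_numpy(dtype=float) if isinstance(group, IsoformGroup) else np.asarray(group, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("isoform response must be a (K>=2, n) matrix")
    if np.isnan(Y).any():
        raise ValueError("isoform groups must form a complete block (no missing cells)")
    G_j = np.asarray(G_j, dtype=float)
    E = np.asarray(E, dtype=float)
    founders = founders or [f"A{i + 1}" for i in range(G_j.shape[1])]
    K, n = Y.shape

    record = {"F": np.nan, "df1": 0, "df2": 0, "p": np.nan, "top_founder": "", "flagged": True}
    empty = ModelFit(coef=pd.Series(dtype=float), rss=np.nan, df_resid=0, rank=0, resid=np.array([]))
    if min((E == 0).sum(), (E == 1).sum()) < 2:
        return empty, empty, record

    Gk, kept = _founder_blocks(G_j, founders, ref_founder, min_founder_mass)
    y_long, X0, XA, names0, namesA = _isoform_design(Y, E, kept, Gk, tested_block)

    if sample_intercepts:
        y_fit = _absorb_samples(y_long, K, n)
        X0f = _absorb_samples(X0, K, n)
        XAf = _absorb_samples(XA, K, n)
        absorbed = n
    else:
        y_fit, X0f, XAf, absorbed = y_long, X0, XA, 0
    c0, rss0, rank0 = _ols(X0f, y_fit)
    cA, rss1, rank1 = _ols(XAf, y_fit)
    rank0 += absorbed
    rank1 += absorbed

    F_eff = len(kept)  # informative founder columns after pruning
    if sample_intercepts:
        expected_df1 = (2 if tested_block == "as_printed" else 1) * F_eff * (K - 1)
    else:
        expected_df1 = F_eff * (2 * K - 1) if tested_block == "as_printed" else F_eff * K
    F, df1, df2, p = _partial_f(rss0, rank0, rss1, rank1, y_long.size)
    deficient = df1 < expected_df1
    if deficient or np.isnan(F):
        F, p = np.nan, np.nan

    n_get = len(kept) * K
    gxe = cA[-n_get:] if n_get else np.array([])
    if gxe.size and np.isfinite(F):
        per_founder = np.abs(gxe.reshape(K, len(kept))).max(axis=0)
        top = kept[int(np.argmax(per_founder))]
    else:
        top = ""
    record.update(
        F=F, df1=df1, df2=df2, p=p, top_founder=top, flagged=bool(deficient or not np.isfinite(F))
    )
    fit0 = ModelFit(pd.Series(c0, index=names0), rss0, y_long.size - rank0, rank0, y_fit - X0f @ c0)
    fitA = ModelFit(pd.Series(cA, index=namesA), rss1, y_long.size - rank1, rank1, y_fit - XAf @ cA)
    return fit0, fitA, record


def n_tests(n_phenotypes: int, n_loci: int) -> int:
    """Size of the full scan cross-product (never materialized)."""
    if n_phenotypes < 0 or n_loci < 0:
        raise ValueError("counts must be non-negative")
    return int(n_phenotypes) * int(n_loci)


def _scan_exon_locus_batch(
    Y: np.ndarray,
    G_j: np.ndarray,
    E: np.ndarray,
    founders: list[str],
    ref_founder: str | None,
    min_founder_mass: float,
) -> tuple[np.ndarray, int, int, np.ndarray, list[str]]:
    """All complete-case phenotypes at one locus in a single multi-RHS
    solve.  Y is (n_phen, n_samples) without missing cells.  Returns
    (F, df1, df2, p, top_founder) arrays; falls back to NaN when the
    alternative design is rank-deficient."""
    n = Y.shape[1]
    Gk, kept = _founder_blocks(G_j, founders, ref_founder, min_founder_mass)
    ones = np.ones(n)
    X0 = np.column_stack([ones, E])
    XA = np.column_stack([ones, E, Gk, Gk * E[:, None]])

    q0, r0m = np.linalg.qr(X0)
    qA, rAm = np.linalg.qr(XA)
    rank0 = int((np.abs(np.diag(r0m)) > 1e-10 * max(1, abs(r0m[0, 0]))).sum())
    rankA = int(np.linalg.matrix_rank(XA))
    deficient = rankA < XA.shape[1]

    Yt = Y.T  # (n_samples, n_phen)
    tot = (Yt**2).sum(axis=0)
    rss0 = tot - ((q0.T @ Yt) ** 2).sum(axis=0)
    rss1 = tot - ((qA.T @ Yt) ** 2).sum(axis=0)
    df1 = rankA - rank0
    df2 = n - rankA
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    F = np.clip(F, 0.0, None)
    p = stats.f.sf(F, df1, df2)
    const = rss0 <= 1e-12
    F = np.where(const, 0.0, F)
    p = np.where(const, 1.0, p)
    if deficient or df1 <= 0 or df2 <= 0:
        F = np.full(Y.shape[0], np.nan)
        p = np.full(Y.shape[0], np.nan)
        top = [""] * Y.shape[0]
    else:
        coef, *_ = np.linalg.lstsq(XA, Yt, rcond=None)
        gxe = coef[2 + len(kept) :, :]  # (n_kept, n_phen)
        top = [kept[i] for i in np.argmax(np.abs(gxe), axis=0)]
    return F, df1, df2, p, top


def _align_samples(
    sample_ids: list[str], samples: pd.DataFrame, genotypes: GenotypeTensor
) -> tuple[np.ndarray, np.ndarray]:
    sheet = samples.set_index("sample")
    missing = [s for s in sample_ids if s not in sheet.index]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing}")
    rils = sheet.loc[sample_ids, "ril"].tolist()
    ril_idx = genotypes.ril_index(rils)
    treatment = sheet.loc[sample_ids, "treatment"]
    bad = sorted(set(treatment) - {"control", "pb"})
    if bad:
        raise ValueError(f"unknown treatment labels: {bad}")
    E = (treatment.to_numpy() == "pb").astype(float)
    if min((E == 0).sum(), (E == 1).sum()) == 0:
        raise ValueError("both environments must be present")
    return ril_idx, E


def scan(
    phenotypes: PhenotypeMatrix | list[IsoformGroup],
    genotypes: GenotypeTensor,
    samples: pd.DataFrame,
    config: ScanConfig | None = None,
    out: str | None = None,
) -> pd.DataFrame:
    """Fit the nested model pair at every (phenotype, locus) combination.

    Returns one association record per pair, phenotype-major and
    locus-minor; with ``out`` set the table is also streamed to TSV in
    per-phenotype chunks.  Sample alignment between phenotype columns, the
    sample sheet and the genotype panel is strict.
    """
    config = config or ScanConfig()
    loci = genotypes.loci.reset_index(drop=True)

    if isinstance(phenotypes, PhenotypeMatrix):
        items = [
            (
                pid,
                phenotypes.anchors.loc[pid, "gene_id"],
                phenotypes.anchors.loc[pid, "chrom"],
                int(phenotypes.anchors.loc[pid, "pos"]),
                phenotypes.values.loc[pid].to_numpy(dtype=float),
            )
            for pid in phenotypes.values.index
        ]
        sample_ids = list(phenotypes.values.columns)
        method = phenotypes.kind
    else:
        if not phenotypes:
            return pd.DataFrame(columns=ASSOC_COLUMNS)
        sample_ids = list(phenotypes[0].values.columns)
        for g in phenotypes:
            if list(g.values.columns) != sample_ids:
                raise ValueError(f"isoform group {g.gene_id} has mismatched samples")
        items = [(g.gene_id, g.gene_id, g.chrom, g.pos, g) for g in phenotypes]
        method = "isoform_dosage"

    ril_idx, E = _align_samples(sample_ids, samples, genotypes)
    G = genotypes.probs[ril_idx]  # (n_samples, n_loci, n_founders)
    n_loci = len(loci)
    n_phen = len(items)

    if method != "isoform_dosage":
        # one shared design per (missingness pattern, locus): solve all
        # phenotypes with that pattern in a single multi-RHS pass
        Yall = np.vstack([it[4] for it in items]) if items else np.empty((0, len(sample_ids)))
        present = ~np.isnan(Yall)
        Fm = np.full((n_phen, n_loci), np.nan)
        pm = np.full((n_phen, n_loci), np.nan)
        d1m = np.zeros((n_phen, n_loci), dtype=int)
        d2m = np.zeros((n_phen, n_loci), dtype=int)
        topm = np.full((n_phen, n_loci), "", dtype=object)
        by_mask: dict[bytes, list[int]] = {}
        for i in range(n_phen):
            by_mask.setdefault(present[i].tobytes(), []).append(i)
        for mask_key, idxs in by_mask.items():
            m = present[idxs[0]]
            Esub = E[m]
            if m.sum() == 0 or min((Esub == 0).sum(), (Esub == 1).sum()) < 2:
                continue
            Ysub = Yall[np.ix_(idxs, np.flatnonzero(m))]
            for j in range(n_loci):
                F, df1, df2, p, top = _scan_exon_locus_batch(
                    Ysub, G[m, j, :], Esub,
                    genotypes.founders, config.ref_founder, config.min_founder_mass,
                )
                Fm[idxs, j] = F
                pm[idxs, j] = p
                d1m[idxs, j] = df1
                d2m[idxs, j] = df2
                topm[idxs, j] = top

    writer = open(out, "w") if out else None
    if writer:
        writer.write("\t".join(ASSOC_COLUMNS) + "\n")
    rows: list[dict] = []
    chroms = loci["chrom"].tolist()
    positions = loci["pos"].astype(int).tolist()
    for i, (pid, gene_id, p_chrom, p_pos, y) in enumerate(items):
        pheno_rows: list[dict] = []
        for j in range(n_loci):
            l_chrom, l_pos = chroms[j], positions[j]
            if config.cis_window is not None and (
                l_chrom != p_chrom or abs(l_pos - p_pos) > config.cis_window
            ):
                continue
            if method == "isoform_dosage":
                _, _, rec = fit_isoform_model(
                    y, G[:, j, :], E,
                    founders=genotypes.founders,
                    ref_founder=config.ref_founder,
                    tested_block=config.tested_block,
                    sample_intercepts=config.sample_intercepts,
                    min_founder_mass=config.min_founder_mass,
                )
                Fv, d1v, d2v, pv, topv = (
                    rec["F"], rec["df1"], rec["df2"], rec["p"], rec["top_founder"]
                )
            else:
                Fv, d1v, d2v, pv, topv = Fm[i, j], d1m[i, j], d2m[i, j], pm[i, j], topm[i, j]
            pheno_rows.append(
                {
                    "phenotype_id": pid,
                    "gene_id": gene_id,
                    "pheno_chrom": p_chrom,
                    "pheno_pos": p_pos,
                    "locus_chrom": l_chrom,
                    "locus_pos": l_pos,
                    "method": method,
                    "F": Fv,
                    "df1": d1v,
                    "df2": d2v,
                    "p": pv,
                    "top_founder": topv,
                }
            )
        log.info("scan: %s phenotype %s done (%d/%d)", method, pid, i + 1, n_phen)
        if writer and pheno_rows:
            chunk = pd.DataFrame(pheno_rows, columns=ASSOC_COLUMNS)
            chunk.to_csv(writer, sep="\t", header=False, index=False)
        rows.extend(pheno_rows)
    result = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    if writer:
        writer.close()
    return result


def differential_expression(
    transcript_counts: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Treatment contrast per transcript with the RIL as covariate.

    Expression is library-size normalized (counts per million) and log2
    transformed; in the balanced paired design the OLS fit of
    ``expression ~ treatment + RIL`` reduces exactly to the paired contrast,
    computed here per RIL pair.  RILs lacking one of the two conditions are
    excluded with a warning.  Output columns: M (log2 Pb/control of mean
    expression), A (mean log2 abundance), p, fdr (Benjamini-Hochberg).
    """
    import warnings

    from statsmodels.stats.multitest import multipletests

    sheet = samples.set_index("sample")
    cols = [c for c in transcript_counts.columns if c in sheet.index]
    sheet = sheet.loc[cols]
    pairs: dict[str, dict[str, str]] = {}
    for s, row in sheet.iterrows():
        pairs.setdefault(row["ril"], {})[row["treatment"]] = s
    complete = {r: d for r, d in pairs.items() if {"control", "pb"} <= set(d)}
    dropped = sorted(set(pairs) - set(complete))
    if dropped:
        warnings.warn(f"unpaired RILs excluded from DE: {dropped}", stacklevel=2)
    if not complete:
        raise ValueError("no complete control/pb RIL pairs")

    lib = transcript_counts.sum(axis=0).astype(float)
    cpm = transcript_counts.astype(float) / lib * 1e6
    logx = np.log2(cpm + pseudocount)

    ctrl_cols = [d["control"] for d in complete.values()]
    pb_cols = [d["pb"] for d in complete.values()]
    diff = logx[pb_cols].to_numpy() - logx[ctrl_cols].to_numpy()
    t, p = stats.ttest_rel(logx[pb_cols], logx[ctrl_cols], axis=1)
    p = np.where(np.isnan(p), 1.0, p)

    mean_c = cpm[ctrl_cols].mean(axis=1)
    mean_p = cpm[pb_cols].mean(axis=1)
    M = np.log2((mean_p + pseudocount) / (mean_c + pseudocount))
    A = 0.5 * (np.log2(mean_c + pseudocount) + np.log2(mean_p + pseudocount))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"transcript_id": transcript_counts.index, "M": M.to_numpy(), "A": A.to_numpy(), "p": p, "fdr": fdr}
    ).set_index("transcript_id")
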