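"""q-value FDR control, significance calls, cis/trans labels, method
overlap, and trans-hotspot detection.

Significance follows the two-threshold convention of the study design the
package targets: an association is called when both p <= p_thresh (default
1e-4) and Storey q <= q_thresh (default 0.39).  A trans hotspot is a locus
bin whose number of distinct significant target genes is extreme against a
permutation null that shuffles locus assignments among the significant
calls (per-bin empirical p, Bonferroni over bins).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "qvalues",
    "call_significant",
    "combine_methods",
    "classify_cis_trans",
    "find_hotspots",
]

log = logging.getLogger(__name__)

DEFAULT_P_THRESH = 1e-4
DEFAULT_Q_THRESH = 0.39
DEFAULT_CIS_WINDOW = 1_000_000


def qvalues(
    p: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values.

    pi0 (the null proportion) is estimated by the smoother: compute
    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid (default
    0.05..0.95 step 0.05), fit a cubic smooth and take its value at the
    largest lambda, clipped to (0, 1].  q_i = pi0 * m * p_(i) / i followed
    by a right-to-left cumulative minimum; NaN p-values get NaN q-values.
    Forcing ``pi0=1`` reproduces Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    pv = p[valid]
    if pv.size == 0:
        return np.full_like(p, np.nan), np.nan
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size

    if pi0 is None:
        grid = (
            np.asarray(lambda_grid, dtype=float)
            if lambda_grid is not None
            else np.arange(0.05, 0.96, 0.05)
        )
        grid = np.sort(grid)
        pi0_l = np.array([(pv > lam).mean() / (1.0 - lam) for lam in grid])
        if len(grid) >= 4 and np.ptp(pi0_l) > 0:
            coefs = np.polyfit(grid, pi0_l, 3)
            pi0_hat = float(np.polyval(coefs, grid.max()))
        else:
            pi0_hat = float(pi0_l[-1])
        pi0_hat = min(max(pi0_hat, 1.0 / m), 1.0)
    else:
        if not 0 < pi0 <= 1:
            raise ValueError("pi0 must lie in (0, 1]")
        pi0_hat = float(pi0)

    order = np.argsort(pv, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0_hat * m * pv[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = q_sorted
    out = np.full_like(p, np.nan)
    out[valid] = qv
    return out, pi0_hat


def call_significant(
    assoc: pd.DataFrame,
    p_thresh: float = DEFAULT_P_THRESH,
    q_thresh: float = DEFAULT_Q_THRESH,
    add_qvalues: bool = True,
) -> pd.DataFrame:
    """Filter an association table to significant calls (p and q both at or
    below their thresholds).  q-values are computed over the table's
    p-values when absent."""
    assoc = assoc.copy()
    if assoc.empty:
        if "q" not in assoc.columns:
            assoc["q"] = pd.Series(dtype=float)
        return assoc
    if "q" not in assoc.columns:
        if not add_qvalues:
            raise ValueError("association table lacks q-values")
        q, pi0 = qvalues(assoc["p"].to_numpy())
        assoc["q"] = q
        log.info("call_significant: pi0 estimate %.3f", pi0)
    keep = (assoc["p"] <= p_thresh) & (assoc["q"] <= q_thresh)
    return assoc[keep.fillna(False)].reset_index(drop=True)


def combine_methods(
    calls_exon: pd.DataFrame,
    calls_isoform: pd.DataFrame,
    key: tuple[str, ...] = ("gene_id", "locus_chrom", "locus_pos"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Union of the two methods' calls on a shared gene-by-locus key.

    Returns the union table, each row labelled ``exon_only``,
    ``isoform_only`` or ``shared``, plus the overlap arithmetic
    {nA, nB, nShared, nUnion} with nUnion = nA + nB - nShared.  Duplicate
    keys within a method are deduplicated to the best (smallest) p with a
    warning.
    """
    key = list(key)

    def dedup(df: pd.DataFrame, name: str) -> pd.DataFrame:
        if df.empty:
            return df.copy()
        if df.duplicated(key).any():
            warnings.warn(f"duplicate keys in {name} calls deduplicated to best p", stacklevel=2)
            df = df.sort_values("p", kind="mergesort").drop_duplicates(key)
        return df

    a = dedup(calls_exon, "exon")
    b = dedup(calls_isoform, "isoform")
    a_keys = set(map(tuple, a[key].itertuples(index=False))) if not a.empty else set()
    b_keys = set(map(tuple, b[key].itertuples(index=False))) if not b.empty else set()
    shared = a_keys & b_keys

    def label(df: pd.DataFrame, own: str) -> pd.DataFrame:
        df = df.copy()
        if df.empty:
            df["overlap"] = pd.Series(dtype=object)
            return df
        k = list(map(tuple, df[key].itertuples(index=False)))
        df["overlap"] = ["shared" if t in shared else own for t in k]
        return df

    a = label(a, "exon_only")
    b = label(b, "isoform_only")
    union = pd.concat([a, b[~b["overlap"].eq("shared")] if not b.empty else b])
    counts = {
        "nA": len(a_keys),
        "nB": len(b_keys),
        "nShared": len(shared),
        "nUnion": len(a_keys | b_keys),
    }
    assert counts["nUnion"] == counts["nA"] + counts["nB"] - counts["nShared"]
    return union.reset_index(drop=True), counts


def classify_cis_trans(
    calls: pd.DataFrame, cis_window: int = DEFAULT_CIS_WINDOW
) -> pd.DataFrame:
    """Label each call cis (same chromosome, |anchor - locus| <= window,
    closed bound) or trans; rows with unknown chromosomes are labelled
    ``unclassified``."""
    calls = calls.copy()
    if calls.empty:
        calls["cis_trans"] = pd.Series(dtype=object)
        return calls
    same = calls["pheno_chrom"] == calls["locus_chrom"]
    dist = (calls["pheno_pos"] - calls["locus_pos"]).abs()
    labels = np.where(same & (dist <= cis_window), "cis", "trans")
    known = calls["pheno_chrom"].notna() & calls["locus_chrom"].notna()
    calls["cis_trans"] = np.where(known, labels, "unclassified")
    return calls


def find_hotspots(
    calls: pd.DataFrame,
    bin_size: int = 100_000,
    n_perm: int = 2_000,
    seed: int = 0,
    alpha: float = 0.05,
    trans_only: bool = True,
    loci: pd.DataFrame | None = None,
    collapse: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect trans-hotspot locus bins.

    The profile counts, per locus bin, the distinct significant target
    genes (the vertical-band summary of an sQTL map).  Linkage replicates
    one underlying QTL across neighbouring grid loci, so with ``collapse``
    (default) each gene's calls are first reduced to its best (smallest-p)
    locus per chromosome.  The empirical null rescatters the collapsed
    calls uniformly over the locus-grid bins ``n_perm`` times (pass
    ``loci`` for the full grid; otherwise the bins observed among the calls
    are used); bins with empirical p below ``alpha / n_bins`` (Bonferroni)
    are significant, and runs of adjacent significant bins are merged into
    one hotspot reported with its peak gene count and smallest p.

    Returns (hotspots, profile); both empty/zero for empty input.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable permutation null", stacklevel=2)
    cols_h = ["chrom", "start", "end", "n_genes", "p_emp"]
    cols_p = ["chrom", "start", "end", "n_genes"]
    if calls.empty:
        return pd.DataFrame(columns=cols_h), pd.DataFrame(columns=cols_p)
    df = calls
    if trans_only and "cis_trans" in df.columns:
        df = df[df["cis_trans"] == "trans"]
    if df.empty:
        return pd.DataFrame(columns=cols_h), pd.DataFrame(columns=cols_p)
    if collapse:
        df = df.sort_values("p", kind="mergesort").drop_duplicates(
            ["gene_id", "locus_chrom"]
        )

    bins = pd.DataFrame(
        {
            "chrom": df["locus_chrom"].to_numpy(),
            "start": (df["locus_pos"].to_numpy() // bin_size) * bin_size,
            "gene": df["gene_id"].to_numpy(),
        }
    )
    bins["bin"] = list(zip(bins["chrom"], bins["start"]))
    if loci is not None:
        # rescatter uniformly over grid *loci*: bins carry unequal numbers
        # of loci, so the null must weight bins accordingly
        grid_bins = [
            (c, (int(p) // bin_size) * bin_size)
            for c, p in zip(loci["chrom"], loci["pos"])
        ]
        uniq_bins = sorted(set(grid_bins) | set(bins["bin"]))
        bin_idx = {b: i for i, b in enumerate(uniq_bins)}
        weights = np.bincount(
            [bin_idx[b] for b in grid_bins], minlength=len(uniq_bins)
        ).astype(float)
    else:
        uniq_bins = sorted(set(bins["bin"]))
        bin_idx = {b: i for i, b in enumerate(uniq_bins)}
        # fallback: weight by the distinct call loci observed per bin
        obs_loci = {(c, int(p)) for c, p in zip(df["locus_chrom"], df["locus_pos"])}
        weights = np.bincount(
            [bin_idx[(c, (p // bin_size) * bin_size)] for c, p in obs_loci],
            minlength=len(uniq_bins),
        ).astype(float)
    weights /= weights.sum()
    genes, gene_codes = np.unique(bins["gene"].to_numpy(), return_inverse=True)
    assign = np.array([bin_idx[b] for b in bins["bin"]])
    n_bins = len(uniq_bins)
    n_calls = len(bins)

    def gene_counts(assignment: np.ndarray) -> np.ndarray:
        pairs = assignment.astype(np.int64) * len(genes) + gene_codes
        uniq = np.unique(pairs)
        return np.bincount(uniq // len(genes), minlength=n_bins)

    obs = gene_counts(assign)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_bins, dtype=int)
    for _ in range(n_perm):
        draw = rng.choice(n_bins, size=n_calls, p=weights)
        exceed += gene_counts(draw) >= obs
    p_emp = (1.0 + exceed) / (n_perm + 1.0)

    profile = pd.DataFrame(
        {
            "chrom": [b[0] for b in uniq_bins],
            "start": [b[1] for b in uniq_bins],
            "end": [b[1] + bin_size for b in uniq_bins],
            "n_genes": obs,
        }
    )
    cutoff = alpha / n_bins
    sig = profile[p_emp < cutoff].copy()
    sig["p_emp"] = p_emp[p_emp < cutoff]
    # merge runs of adjacent significant bins into single hotspots
    merged: list[dict] = []
    for _, row in sig.sort_values(["chrom", "start"]).iterrows():
        if (
            merged
            and merged[-1]["chrom"] == row["chrom"]
            and row["start"] <= merged[-1]["end"]
        ):
            merged[-1]["end"] = max(merged[-1]["end"], row["end"])
            merged[-1]["n_genes"] = max(merged[-1]["n_genes"], row["n_genes"])
            merged[-1]["p_emp"] = min(merged[-1]["p_emp"], row["p_emp"])
        else:
            merged.append(row[cols_h].to_dict())
    hot = pd.DataFrame(merged, columns=cols_h)
    hot = hot.sort_values("n_genes", ascending=False).reset_index(drop=True)
    return hot, profile
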