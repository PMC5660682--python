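"""Cross-sample quantile normalization and PCA confounder removal.

The normalization recipe for both splicing traits is: quantile-normalize
phenotype values across samples, then regress the leading principal
components of the sample space out of every phenotype (3 components for
exon fractions, 4 for isoform dosages, by default).  Because the downstream
test targets genotype-by-environment interaction, the environment vector
can be protected: each principal component is orthogonalised against it
before removal, so treatment signal is never absorbed into the confounder
subspace.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import NormalizationReport

__all__ = ["quantile_normalize", "remove_pcs"]

DEFAULT_N_PC = {"exon_fraction": 3, "isoform_dosage": 4}


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the cross-sample mean order-statistic
    distribution.

    For complete columns, each column's sorted values are replaced by the
    row-wise mean of all sorted columns; ties within a column receive the
    mean of their tied target values.  Columns with missing cells are
    normalized through interpolation of the mean quantile function at their
    non-missing quantile positions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    counts = (~np.isnan(X)).sum(axis=0)
    if (counts == 0).any():
        bad = matrix.columns[np.where(counts == 0)[0][0]]
        raise ValueError(f"sample {bad!r} has no non-missing values")

    # mean quantile function on a common grid of n_rows probabilities
    grid = (np.arange(n_rows) + 0.5) / n_rows
    curves = np.empty((n_rows, n_cols))
    for c in range(n_cols):
        vals = np.sort(X[~np.isnan(X[:, c]), c])
        q = (np.arange(vals.size) + 0.5) / vals.size
        curves[:, c] = np.interp(grid, q, vals)
    target = curves.mean(axis=1)

    out = np.full_like(X, np.nan)
    for c in range(n_cols):
        mask = ~np.isnan(X[:, c])
        vals = X[mask, c]
        m = vals.size
        if m == n_rows:
            order = np.argsort(vals, kind="mergesort")
            mapped = np.empty(m)
            mapped[order] = target
        else:
            q = (np.arange(m) + 0.5) / m
            tq = np.interp(q, grid, target)
            order = np.argsort(vals, kind="mergesort")
            mapped = np.empty(m)
            mapped[order] = tq
        # ties get the mean of their mapped targets
        sorted_vals = vals[order]
        ties = np.flatnonzero(np.diff(sorted_vals) == 0)
        if ties.size:
            srt = mapped[order]
            i = 0
            while i < m:
                j = i
                while j + 1 < m and sorted_vals[j + 1] == sorted_vals[i]:
                    j += 1
                if j > i:
                    srt[i : j + 1] = srt[i : j + 1].mean()
                i = j + 1
            mapped[order] = srt
        out[mask, c] = mapped
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def remove_pcs(
    matrix: pd.DataFrame,
    n_pc: int,
    protect: np.ndarray | None = None,
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Center each phenotype across samples and regress out the top ``n_pc``
    sample-space principal components.

    ``protect`` (e.g. the 0/1 environment vector) is orthogonalised out of
    every component before removal so the protected contrast survives.
    Missing cells are mean-imputed for the decomposition and restored
    afterwards.  Residuals are orthogonal to the removed components.
    """
    n_samples = matrix.shape[1]
    if not 0 <= n_pc < n_samples:
        raise ValueError(f"n_pc must satisfy 0 <= n_pc < n_samples ({n_samples})")
    X = matrix.to_numpy(dtype=float)
    missing = np.isnan(X)
    if missing.any():
        row_mean = np.nanmean(X, axis=1, keepdims=True)
        X = np.where(missing, row_mean, X)
    X = X - X.mean(axis=1, keepdims=True)

    if n_pc == 0:
        out = X.copy()
        report = NormalizationReport(n_pc=0, variance_fractions=[])
    else:
        # sample-space components = right singular vectors of phenotypes x samples
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        total = float((s**2).sum())
        comps = vt[:n_pc].T  # (n_samples, n_pc)
        fracs = [float(sv**2 / total) if total > 0 else 0.0 for sv in s[:n_pc]]
        if protect is not None:
            p = np.asarray(protect, dtype=float).reshape(n_samples, 1)
            p = p - p.mean()
            nrm = float((p.T @ p)[0, 0])
            if nrm > 0:
                comps = comps - p @ (p.T @ comps) / nrm
        q, r = np.linalg.qr(comps)
        # drop numerically null directions (protection can collapse a PC)
        keep = np.abs(np.diag(r)) > 1e-10
        q = q[:, keep]
        out = X - (X @ q) @ q.T
        report = NormalizationReport(n_pc=n_pc, variance_fractions=fracs)

    out[missing] = np.nan
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), report
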