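"""Independent least-squares oracles shared by the model tests.

These build the nested design matrices from scratch and solve the normal
equations with a pseudoinverse — no code shared with the implementation
under test.
"""

import numpy as np
from scipy import stats


def oracle_partial_f(X0, XA, y, absorbed_rank=0):
    """Partial F between two nested designs, solved from scratch.

    The residual sum of squares comes from projecting y onto an SVD-derived
    orthonormal basis of each design's column space (the normal equations in
    stable form); ranks come from ``matrix_rank``.
    """
    def rss_rank(X):
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        rank = int((s > s[0] * max(X.shape) * np.finfo(float).eps).sum())
        q = u[:, :rank]
        resid = y - q @ (q.T @ y)
        return float(resid @ resid), rank + absorbed_rank

    rss0, rank0 = rss_rank(X0)
    rss1, rank1 = rss_rank(XA)
    df1, df2 = rank1 - rank0, y.size - rank1
    F = ((rss0 - rss1) / df1) / (rss1 / df2)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def exon_designs(G, E, drop=-1):
    keep = [i for i in range(G.shape[1]) if i != drop % G.shape[1]]
    Gk = G[:, keep]
    X0 = np.column_stack([np.ones(len(E)), E])
    XA = np.column_stack([X0, Gk, Gk * E[:, None]])
    return X0, XA


def isoform_designs(Y, G, E, tested_block, sample_intercepts, drop=-1):
    K, n = Y.shape
    keep = [i for i in range(G.shape[1]) if i != drop % G.shape[1]]
    Gk = G[:, keep]
    T = np.repeat(np.eye(K), n, axis=0)
    Gl = np.tile(Gk, (K, 1))
    El = np.tile(E, K)
    ET = T * El[:, None]
    GT = np.concatenate([T[:, [k]] * Gl for k in range(K)], axis=1)
    GET = GT * El[:, None]
    S = np.tile(np.eye(n), (K, 1))
    base = [S] if sample_intercepts else []
    if tested_block == "as_printed":
        X0 = np.column_stack(base + [T, ET, Gl])
    else:
        X0 = np.column_stack(base + [T, ET, GT])
    XA = np.column_stack(base + [T, ET, GT, GET])
    return Y.reshape(-1), X0, XA
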