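"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the code paths they check: dense matrix inversion
instead of eigen-rotation for GLS, and an explicit step-up loop for the FDR
adjustment.
"""

import numpy as np
from scipy import stats


def brute_force_gls(y, X, g_col, V):
    """Per-SNP GLS Wald test with an explicit V inverse."""
    Vi = np.linalg.inv(V)
    Xf = np.column_stack([X, g_col])
    A = Xf.T @ Vi @ Xf
    beta = np.linalg.solve(A, Xf.T @ Vi @ y)
    resid = y - Xf @ beta
    df = len(y) - Xf.shape[1]
    sigma2 = float(resid @ Vi @ resid) / df
    se = np.sqrt(sigma2 * np.linalg.inv(A)[-1, -1])
    t = beta[-1] / se
    return float(beta[-1]), float(2 * stats.t.sf(abs(t), df))


def bh_stepup_oracle(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up walk."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
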