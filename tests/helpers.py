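"""Shared independent oracles for the test suite."""

import numpy as np
from scipy import linalg


def oracle_cca(X, Ym):
    """Brute-force largest canonical correlation via the generalized
    eigenproblem  Cxy Cyy^-1 Cyx w = rho^2 Cxx w  (independent of the
    package's whitened-SVD path)."""
    X = np.atleast_2d(np.asarray(X, float))
    Ym = np.asarray(Ym, float)
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Ym - Ym.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    A = Cxy @ linalg.solve(Cyy, Cxy.T)
    vals = linalg.eigh(A, Cxx, eigvals_only=True)
    return float(np.sqrt(np.clip(vals[-1], 0.0, 1.0)))
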