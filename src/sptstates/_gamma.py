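"""Weighted maximum-likelihood estimation for the gamma distribution.

Shared by the gamma-mixture EM and the gamma-emission HMM M-step.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma


def weighted_gamma_mle(
    x: np.ndarray, w: np.ndarray | None = None, max_iter: int = 100, tol: float = 1e-12
) -> tuple[float, float]:
    """Weighted MLE of gamma shape and scale.

    Solves ``ln(a) - psi(a) = ln(mean) - mean(ln x)`` for the shape ``a`` by
    Newton iteration from Minka's closed-form starting point; the scale is
    then ``mean/a``. Weights need not be normalized.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("gamma MLE requires strictly positive data")
    if w is None:
        w = np.ones_like(x)
    W = w.sum()
    if W <= 0:
        raise ValueError("weights sum to zero")
    m = float((w * x).sum() / W)
    mlog = float((w * np.log(x)).sum() / W)
    s = np.log(m) - mlog
    if s <= 0:  # numerically degenerate (all x equal): huge shape
        return 1e8, m / 1e8
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = np.log(a) - digamma(a) - s
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < tol * a:
            a = a_new
            break
        a = a_new
    return float(a), float(m / a)
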