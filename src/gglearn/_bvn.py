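"""Standard bivariate normal CDF via Owen's T function.

Computes Phi2(h, k, rho) = P(Z1 <= h, Z2 <= k) for standard normal
(Z1, Z2) with correlation rho, using the classical identity

    Phi2(h, k, rho) = (Phi(h) + Phi(k)) / 2
                      - T(h, (k - rho h) / (h sqrt(1 - rho^2)))
                      - T(k, (h - rho k) / (k sqrt(1 - rho^2)))
                      - [hk < 0 or (hk = 0 and h + k < 0)] / 2

with ``scipy.special.owens_t`` supplying T.  Vectorized over (h, k) for a
scalar rho; handles infinite limits and the |rho| -> 1 boundary exactly.
Accuracy is that of owens_t (~1e-14), ample for likelihood work.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf"]

_EPS = 1e-15


def bvn_cdf(h, k, rho: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")

    if rho == 1.0:
        return ndtr(np.minimum(h, k))
    if rho == -1.0:
        return np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)

    out = np.empty(h.shape, dtype=float)
    neg_inf = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    finite = ~(neg_inf | h_inf | k_inf)

    out[neg_inf] = 0.0
    # one infinite upper limit reduces to the univariate CDF
    out[h_inf & ~neg_inf] = ndtr(k[h_inf & ~neg_inf])
    out[k_inf & ~neg_inf & ~h_inf] = ndtr(h[k_inf & ~neg_inf & ~h_inf])

    if np.any(finite):
        hf = h[finite].copy()
        kf = k[finite].copy()
        # nudge exact zeros off the axis; Phi2 is continuous so the error
        # is O(eps), far below the owens_t accuracy
        hf[hf == 0.0] = _EPS
        kf[kf == 0.0] = _EPS
        denom = np.sqrt(1.0 - rho * rho)
        a_h = (kf - rho * hf) / (hf * denom)
        a_k = (hf - rho * kf) / (kf * denom)
        correction = np.where((hf * kf < 0) | ((hf * kf == 0) & (hf + kf < 0)), 0.5, 0.0)
        val = 0.5 * (ndtr(hf) + ndtr(kf)) - owens_t(hf, a_h) - owens_t(kf, a_k) - correction
        out[finite] = np.clip(val, 0.0, 1.0)
    return out
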