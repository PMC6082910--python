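"""Vectorised standard bivariate normal CDF and density.

The rectangle probabilities behind polychoric likelihoods require
``P(X <= h, Y <= k)`` for a standard bivariate normal with correlation
``rho`` at every corner of a threshold grid.  Owen's T function gives an
accurate closed form that broadcasts over numpy arrays, which matters
because the estimation code evaluates thousands of corners per scoring
iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.special import owens_t
from scipy.stats import norm

__all__ = ["bvn_cdf", "bvn_pdf"]

# |rho| is kept strictly inside (-1, 1); the polychoric optimiser never
# needs the exactly singular case and the Owen formula degenerates there.
_RHO_MAX = 0.99995
_EPS = 1e-12


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    All arguments broadcast; ``h``/``k`` may be +/-inf.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    out = np.empty(h.shape, dtype=float)

    ninf = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    both_inf = h_inf & k_inf
    only_h = h_inf & ~k_inf & ~ninf
    only_k = k_inf & ~h_inf & ~ninf
    finite = ~(ninf | h_inf | k_inf)

    out[ninf] = 0.0
    out[both_inf] = 1.0
    out[only_h] = norm.cdf(k[only_h])
    out[only_k] = norm.cdf(h[only_k])

    if np.any(finite):
        hf = h[finite]
        kf = k[finite]
        rf = np.clip(rho[finite], -_RHO_MAX, _RHO_MAX)
        # nudge exact zeros so the Owen decomposition's sign bookkeeping
        # stays well defined (error is O(phi(0)*eps))
        hf = np.where(np.abs(hf) < _EPS, _EPS, hf)
        kf = np.where(np.abs(kf) < _EPS, _EPS, kf)
        s = np.sqrt(1.0 - rf * rf)
        ah = (kf - rf * hf) / (hf * s)
        ak = (hf - rf * kf) / (kf * s)
        val = (
            0.5 * (norm.cdf(hf) + norm.cdf(kf))
            - owens_t(hf, ah)
            - owens_t(kf, ak)
        )
        val = np.where(hf * kf < 0, val - 0.5, val)
        out[finite] = np.clip(val, 0.0, 1.0)
    return out


def bvn_pdf(h, k, rho):
    """Standard bivariate normal density; zero at infinite coordinates."""
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    rho = np.clip(rho, -_RHO_MAX, _RHO_MAX)
    fin = np.isfinite(h) & np.isfinite(k)
    out = np.zeros(h.shape, dtype=float)
    if np.any(fin):
        hf, kf, rf = h[fin], k[fin], rho[fin]
        om = 1.0 - rf * rf
        z = (hf * hf - 2.0 * rf * hf * kf + kf * kf) / om
        out[fin] = np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(om))
    return out
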