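"""Model-based omega reliability coefficients for a bifactor solution.

For a bifactor model with general loadings ``lambda_g``, block-specific
loadings ``lambda_s`` and residual variances ``theta`` (all on the
standardized latent-response scale), the coefficients are variance ratios
of the unit-weighted total/subscale scores:

  omega   = [ (sum lambda_g)^2 + sum_blocks (sum lambda_s)^2 ] / total var
  omega_H = (sum lambda_g)^2 / total var

with total var = (sum lambda_g)^2 + sum_blocks (sum lambda_s)^2 + sum theta.
The subscale variants ``omega_S`` / ``omega_HS`` apply the same ratios to
one block's items, the hierarchical-subscale version crediting only that
block's specific factor (the general factor partialled out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurement import FittedMeasurementModel

__all__ = ["OmegaSet", "compute_omegas", "omega_from_loadings"]


@dataclass
class OmegaSet:
    omega_total: float
    omega_hierarchical: float
    omega_subscale: dict  # block -> omega_S
    omega_hierarchical_subscale: dict  # block -> omega_HS
    scale: str = "latent-response (polychoric), standardized loadings"

    def to_dict(self) -> dict:
        return {
            "omega": self.omega_total,
            "omega_h": self.omega_hierarchical,
            "blocks": {
                b: {
                    "omega_s": self.omega_subscale[b],
                    "omega_hs": self.omega_hierarchical_subscale[b],
                }
                for b in self.omega_subscale
            },
            "scale": self.scale,
        }


def omega_from_loadings(general, specific, block_index, block_names=None) -> OmegaSet:
    """Omegas straight from bifactor loading vectors (population algebra)."""
    lam_g = np.asarray(general, float)
    lam_s = np.asarray(specific, float)
    bidx = np.asarray(block_index, int)
    theta = 1.0 - lam_g**2 - lam_s**2
    if np.any(theta < 0):
        raise ValueError("negative residual variance (Heywood case); omegas undefined")
    nb = bidx.max() + 1
    if block_names is None:
        block_names = [f"block_{b + 1}" for b in range(nb)]
    spec_sums = np.array([lam_s[bidx == b].sum() for b in range(nb)])
    gen_sum = lam_g.sum()
    total_var = gen_sum**2 + (spec_sums**2).sum() + theta.sum()
    omega = (gen_sum**2 + (spec_sums**2).sum()) / total_var
    omega_h = gen_sum**2 / total_var
    om_s, om_hs = {}, {}
    for b, name in enumerate(block_names):
        sel = bidx == b
        g_b = lam_g[sel].sum()
        s_b = lam_s[sel].sum()
        var_b = g_b**2 + s_b**2 + theta[sel].sum()
        om_s[name] = float((g_b**2 + s_b**2) / var_b)
        om_hs[name] = float(s_b**2 / var_b)
    return OmegaSet(
        omega_total=float(omega),
        omega_hierarchical=float(omega_h),
        omega_subscale=om_s,
        omega_hierarchical_subscale=om_hs,
    )


def compute_omegas(fitted: FittedMeasurementModel) -> OmegaSet:
    """Omega coefficients from a fitted bifactor measurement model."""
    if fitted.structure != "bifactor":
        raise ValueError("omega decomposition requires a bifactor solution")
    if np.any(fitted.heywood):
        raise ValueError("Heywood items present; omegas undefined")
    lam = fitted.loadings_matrix()
    bidx = fitted.spec.block_index()
    lam_s = lam[np.arange(lam.shape[0]), bidx + 1]
    return omega_from_loadings(
        lam[:, 0], lam_s, bidx, block_names=fitted.spec.block_names
    )
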