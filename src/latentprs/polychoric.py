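"""Thresholds, polychoric and polyserial correlations for ordinal items.

Ordinal questionnaire items are modelled as coarsened observations of
latent standard-normal responses: item ``j`` shows category ``c`` when its
latent response falls between thresholds ``tau_{j,c}`` and ``tau_{j,c+1}``.
The polychoric correlation between two items is the correlation of the
underlying bivariate normal, estimated in two stages (Olsson): thresholds
from the univariate margins, then the correlation by maximising the
bivariate contingency likelihood with thresholds held fixed.

The whole item-by-item matrix is estimated in one vectorised Fisher-scoring
sweep across pairs, which keeps 51-item problems fast enough for
replication studies.  Per-observation influence functions (thresholds held
fixed) are returned on request; they feed the diagonal weight matrix and
the full asymptotic covariance used by the mean-and-variance-adjusted
chi-square downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from ._bvnorm import bvn_cdf, bvn_pdf

__all__ = [
    "PolychoricSummary",
    "as_ordinal_codes",
    "ordinal_thresholds",
    "estimate_polychoric",
    "polychoric_matrix",
    "polyserial_vector",
]

_RHO_BOUND = 0.999
_PI_FLOOR = 1e-300


def as_ordinal_codes(items) -> np.ndarray:
    """Coerce an item table to an integer matrix with -1 marking missing."""
    if isinstance(items, pd.DataFrame):
        arr = items.to_numpy(dtype=float, na_value=np.nan)
    else:
        arr = np.asarray(items, dtype=float)
    if arr.ndim != 2:
        raise ValueError("item table must be 2-dimensional")
    codes = np.full(arr.shape, -1, dtype=np.int64)
    obs = np.isfinite(arr)
    vals = arr[obs]
    if np.any(vals < 0) or np.any(vals != np.round(vals)):
        raise ValueError("item categories must be non-negative integers")
    codes[obs] = vals.astype(np.int64)
    return codes


def ordinal_thresholds(y, n_categories: int | None = None, weights=None) -> np.ndarray:
    """Normal-quantile thresholds from the univariate category margins.

    ``tau_c`` is the standard-normal quantile of the (weighted) cumulative
    proportion through category ``c``; categories never observed yield
    infinite thresholds.
    """
    y = np.asarray(y)
    obs = y >= 0
    if weights is None:
        w = np.ones(y.shape, dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    w = np.where(obs, w, 0.0)
    if n_categories is None:
        n_categories = int(y[obs].max()) + 1 if obs.any() else 0
    if n_categories < 2 or len(np.unique(y[obs])) < 2:
        raise ValueError("item has fewer than 2 observed categories; unidentifiable")
    counts = np.bincount(y[obs], weights=w[obs], minlength=n_categories)[:n_categories]
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return norm.ppf(cum)


@dataclass
class PolychoricSummary:
    """Two-stage polychoric summary of an ordinal item table."""

    thresholds: list[np.ndarray]
    corr: np.ndarray
    n_categories: np.ndarray
    pair_rows: np.ndarray  # item index j of each pair (j < k)
    pair_cols: np.ndarray
    pair_n: np.ndarray  # effective (weighted) count per pair
    asy_var: np.ndarray  # sampling variance of each pairwise estimate
    n_obs: int
    influence: np.ndarray | None = None  # n_obs x n_pairs, thresholds fixed
    converged: bool = True
    item_names: list[str] | None = field(default=None)

    @property
    def n_items(self) -> int:
        return self.corr.shape[0]

    @property
    def pair_values(self) -> np.ndarray:
        return self.corr[self.pair_rows, self.pair_cols]

    def gamma(self) -> np.ndarray:
        """Asymptotic covariance of the pairwise correlations (per-obs scale)."""
        if self.influence is None:
            raise ValueError("summary was built without influence functions")
        ifc = self.influence - self.influence.mean(axis=0, keepdims=True)
        return ifc.T @ ifc / self.n_obs

    @classmethod
    def from_population(cls, corr: np.ndarray, thresholds: list[np.ndarray]):
        """Wrap a population correlation matrix (unit weights, no sampling noise)."""
        corr = np.asarray(corr, dtype=float)
        p = corr.shape[0]
        jj, kk = np.triu_indices(p, k=1)
        ncat = np.array([len(t) + 1 for t in thresholds])
        return cls(
            thresholds=[np.asarray(t, float) for t in thresholds],
            corr=corr,
            n_categories=ncat,
            pair_rows=jj,
            pair_cols=kk,
            pair_n=np.full(jj.size, np.inf),
            asy_var=np.ones(jj.size),
            n_obs=0,
        )


def _pair_boundaries(thresholds, n_categories):
    """Stack per-item thresholds into a padded boundary matrix (+inf padding)."""
    p = len(thresholds)
    kmax = int(max(n_categories))
    bnd = np.full((p, kmax + 1), np.inf)
    bnd[:, 0] = -np.inf
    for j, tau in enumerate(thresholds):
        bnd[j, 1 : len(tau) + 1] = tau
    return bnd, kmax


def _cell_probs(bnd_j, bnd_k, rho):
    """Rectangle probabilities and their rho-derivatives for padded grids."""
    a = bnd_j[:, :, None]
    b = bnd_k[:, None, :]
    r = rho[:, None, None]
    big_phi = bvn_cdf(a, b, r)
    small_phi = bvn_pdf(a, b, r)
    pi = (
        big_phi[:, 1:, 1:]
        - big_phi[:, :-1, 1:]
        - big_phi[:, 1:, :-1]
        + big_phi[:, :-1, :-1]
    )
    dpi = (
        small_phi[:, 1:, 1:]
        - small_phi[:, :-1, 1:]
        - small_phi[:, 1:, :-1]
        + small_phi[:, :-1, :-1]
    )
    n_pair = pi.shape[0]
    return pi.reshape(n_pair, -1), dpi.reshape(n_pair, -1)


def _pair_loglik(counts, pi):
    return np.where(counts > 0, counts * np.log(np.maximum(pi, _PI_FLOOR)), 0.0).sum(axis=1)


def polychoric_matrix(
    items,
    weights=None,
    n_categories=None,
    compute_influence: bool = False,
    max_iter: int = 60,
    tol: float = 1e-8,
    item_names=None,
) -> PolychoricSummary:
    """Estimate all pairwise polychoric correlations of an ordinal table.

    Missing responses are handled by pairwise deletion.  ``weights`` (e.g.
    inverse-probability weights) enter the margins, the contingency counts
    and the influence functions alike, so the unweighted path is exactly
    the all-weights-one path.
    """
    if isinstance(items, pd.DataFrame) and item_names is None:
        item_names = list(items.columns)
    y = as_ordinal_codes(items)
    n, p = y.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be a non-negative vector of length n")
        w = w * (n / w.sum())  # mean-one scale: estimates invariant to rescaling
    if n_categories is None:
        ncat = np.array([int(y[:, j][y[:, j] >= 0].max()) + 1 for j in range(p)])
    else:
        ncat = np.asarray(n_categories, dtype=int)
    thresholds = [ordinal_thresholds(y[:, j], ncat[j], weights=w) for j in range(p)]
    bnd, kmax = _pair_boundaries(thresholds, ncat)

    jj, kk = np.triu_indices(p, k=1)
    n_pair = jj.size
    ncell = kmax * kmax

    # per-pair weighted contingency counts via a single flat bincount;
    # rows with either item missing go to a dump cell
    yj = y[:, jj]
    yk = y[:, kk]
    miss = (yj < 0) | (yk < 0)
    code = np.where(miss, ncell, yj * kmax + yk)
    flat = code + np.arange(n_pair)[None, :] * (ncell + 1)
    if weights is None:
        counts = np.bincount(flat.ravel(), minlength=n_pair * (ncell + 1)).astype(float)
    else:
        counts = np.bincount(
            flat.ravel(),
            weights=np.repeat(w, n_pair),
            minlength=n_pair * (ncell + 1),
        )
    counts = counts.reshape(n_pair, ncell + 1)[:, :ncell]
    pair_n = counts.sum(axis=1)
    if np.any(pair_n < 10):
        warnings.warn("some item pairs have fewer than 10 complete observations")

    # moment start values from the contingency table itself
    vi = (np.arange(ncell) // kmax).astype(float)
    vj = (np.arange(ncell) % kmax).astype(float)
    tot = np.maximum(pair_n, 1.0)
    mi = counts @ vi / tot
    mj = counts @ vj / tot
    sij = counts @ (vi * vj) / tot - mi * mj
    si = np.sqrt(np.maximum(counts @ (vi * vi) / tot - mi * mi, 1e-12))
    sj = np.sqrt(np.maximum(counts @ (vj * vj) / tot - mj * mj, 1e-12))
    rho = np.clip(sij / (si * sj), -0.9, 0.9)

    bnd_j = bnd[jj]
    bnd_k = bnd[kk]
    pi, dpi = _cell_probs(bnd_j, bnd_k, rho)
    ll = _pair_loglik(counts, pi)
    converged = False
    for _ in range(max_iter):
        ratio = dpi / np.maximum(pi, _PI_FLOOR)
        score = (counts * ratio).sum(axis=1)
        info = (dpi * ratio).sum(axis=1)  # per-observation Fisher information
        step = score / np.maximum(pair_n * info, 1e-12)
        # measure the step after clipping so boundary pairs count as converged
        step = np.clip(rho + step, -_RHO_BOUND, _RHO_BOUND) - rho
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        # damped update: halve any step that decreases its pair's likelihood
        for _half in range(12):
            cand = np.clip(rho + step, -_RHO_BOUND, _RHO_BOUND)
            pi_c, dpi_c = _cell_probs(bnd_j, bnd_k, cand)
            ll_c = _pair_loglik(counts, pi_c)
            bad = ll_c < ll - 1e-12
            if not np.any(bad):
                break
            step = np.where(bad, step * 0.5, step)
        rho, pi, dpi, ll = cand, pi_c, dpi_c, ll_c
    if not converged:
        warnings.warn("polychoric scoring reached max_iter without full convergence")

    ratio = dpi / np.maximum(pi, _PI_FLOOR)
    info = (dpi * ratio).sum(axis=1)
    asy_var = 1.0 / np.maximum(pair_n * info, 1e-12)

    corr = np.eye(p)
    corr[jj, kk] = rho
    corr[kk, jj] = rho

    influence = None
    if compute_influence:
        # IF_i = n * w_i * s_i(rho_hat) / (W_pair * info); zero when missing
        dlogpi = np.concatenate([ratio, np.zeros((n_pair, 1))], axis=1)
        s_obs = dlogpi[np.arange(n_pair)[None, :], code]  # n x n_pair gather
        influence = (w[:, None] * s_obs) * (
            n / np.maximum(pair_n * info, 1e-12)
        )[None, :]
        ifc = influence - influence.mean(axis=0, keepdims=True)
        asy_var = (ifc * ifc).sum(axis=0) / (n * n)

    return PolychoricSummary(
        thresholds=thresholds,
        corr=corr,
        n_categories=ncat,
        pair_rows=jj,
        pair_cols=kk,
        pair_n=pair_n,
        asy_var=asy_var,
        n_obs=n,
        influence=influence,
        converged=converged,
        item_names=item_names,
    )


def estimate_polychoric(x, y, weights=None):
    """Polychoric correlation of two ordinal vectors.

    Returns ``(rho, asymptotic_variance)`` from the same two-stage
    estimator as :func:`polychoric_matrix`.
    """
    table = np.column_stack([np.asarray(x), np.asarray(y)])
    summ = polychoric_matrix(table, weights=weights)
    return float(summ.corr[0, 1]), float(summ.asy_var[0])


def _polyserial_loglik(x, ycodes, tau, rho, weights):
    bounds = np.concatenate([[-np.inf], tau, [np.inf]])
    s = np.sqrt(max(1.0 - rho * rho, 1e-10))
    lo = (bounds[ycodes] - rho * x) / s
    hi = (bounds[ycodes + 1] - rho * x) / s
    pr = np.maximum(norm.cdf(hi) - norm.cdf(lo), _PI_FLOOR)
    return np.log(pr), pr


def polyserial_vector(x, items, weights=None, n_categories=None, thresholds=None):
    """Polyserial correlations between one continuous variable and each item.

    Two-stage ML: thresholds from the item margins, the continuous variable
    treated as observed normal (it is standardised internally).  Returns
    ``(rho, asy_var, influence)`` with influence functions on the same
    per-observation scale as :meth:`PolychoricSummary.gamma`.
    """
    x = np.asarray(x, dtype=float)
    y = as_ordinal_codes(items)
    n, p = y.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w * (n / w.sum())
    wsum = w.sum()
    xm = (x * w).sum() / wsum
    xs = np.sqrt(((x - xm) ** 2 * w).sum() / wsum)
    xz = (x - xm) / xs
    if n_categories is None:
        ncat = np.array([int(y[:, j][y[:, j] >= 0].max()) + 1 for j in range(p)])
    else:
        ncat = np.asarray(n_categories, dtype=int)
    if thresholds is None:
        thresholds = [ordinal_thresholds(y[:, j], ncat[j], weights=w) for j in range(p)]

    rhos = np.empty(p)
    avar = np.empty(p)
    influence = np.zeros((n, p))
    for j in range(p):
        obs = y[:, j] >= 0
        xo, yo, wo = xz[obs], y[obs, j], w[obs]
        wo_sum = wo.sum()
        tau = thresholds[j]

        def nll(r):
            lp, _ = _polyserial_loglik(xo, yo, tau, r, wo)
            return -(wo * lp).sum()

        res = minimize_scalar(nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
                              options={"xatol": 1e-8})
        r = float(res.x)
        rhos[j] = r
        # numeric per-observation score for the influence function
        h = 1e-5
        lp_hi, _ = _polyserial_loglik(xo, yo, tau, r + h, wo)
        lp_lo, _ = _polyserial_loglik(xo, yo, tau, r - h, wo)
        s_i = (lp_hi - lp_lo) / (2 * h)
        info = (wo * s_i * s_i).sum() / wo_sum
        info = max(info, 1e-12)
        influence[obs, j] = n * wo * s_i / (wo_sum * info)
        col = influence[:, j] - influence[:, j].mean()
        avar[j] = (col @ col) / (n * n)
    return rhos, avar, influence
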