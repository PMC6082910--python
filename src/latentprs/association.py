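"""Simultaneous latent-factor-on-PRS regression with sensitivity analyses.

The structural model is a MIMIC design: the ordinal measurement model
(correlated-factors or bifactor) is retained and every factor is
regressed simultaneously on one standardized polygenic score.  Factors
keep unit total variance, so each coefficient is an SD change in latent
trait per SD change in PRS.  Estimation is limited-information: the
polychoric item matrix is augmented with item-PRS polyserial
correlations and the joint structure is fitted by diagonally weighted
least squares; standard errors are sandwich estimates built from the
asymptotic covariance of the correlation estimates (delta method).

Sensitivity analyses mirror common practice for cohort analyses:
max-T step-down permutation of the PRS against MAP factor scores for
family-wise adjusted P-values, and inverse-probability weighting for
covariate-dependent inclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .measurement import FittedMeasurementModel, ModelSpec, build_model
from .polychoric import (
    as_ordinal_codes,
    polychoric_matrix,
    polyserial_vector,
)

__all__ = [
    "StructuralResult",
    "PermutationResult",
    "IpwWeights",
    "fit_structural",
    "weighted_structural",
    "estimate_factor_scores",
    "permutation_adjusted_p",
    "estimate_ipw",
    "StructuralModel",
]


@dataclass
class StructuralResult:
    """Standardized factor-on-PRS estimates for one structure."""

    structure: str
    table: pd.DataFrame  # outcome, beta, se, lci, uci, p
    n_analyzed: int
    measurement: FittedMeasurementModel
    gamma: np.ndarray
    converged: bool = True
    weighted: bool = False

    def beta(self, outcome: str) -> float:
        return float(self.table.set_index("outcome").loc[outcome, "beta"])


@dataclass
class PermutationResult:
    table: pd.DataFrame  # outcome, t, p_unadjusted, p_adjusted
    n_permutations: int
    seed: int


@dataclass
class IpwWeights:
    probability: np.ndarray
    weight: np.ndarray
    truncated: np.ndarray
    truncate_at: float | None
    model: object = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# structural DWLS


class _StructuralLayout:
    """Parameter map for the MIMIC model on the PRS-augmented matrix.

    theta = [loadings (measurement pattern), residual factor correlations
    (correlated structure only), gamma (one per factor)].  Residual factor
    variances are ``1 - gamma^2`` so every factor keeps unit total
    variance and gamma is the standardized effect.
    """

    def __init__(self, spec: ModelSpec, jj, kk):
        if spec.structure not in ("correlated", "bifactor"):
            raise ValueError("structural model requires correlated or bifactor structure")
        self.spec = spec
        self.jj = jj  # item-item pairs
        self.kk = kk
        self.p = spec.n_items
        self.nf = spec.n_factors
        self.block = spec.block_index()
        if spec.structure == "bifactor":
            rows = np.concatenate([np.arange(self.p), np.arange(self.p)])
            cols = np.concatenate([np.zeros(self.p, int), self.block + 1])
        else:
            rows = np.arange(self.p)
            cols = self.block
        self.load_rows = rows
        self.load_cols = cols
        self.n_load = rows.size
        if spec.structure == "correlated":
            nb = self.nf
            self.psi_pairs = [(a, b) for a in range(nb) for b in range(a + 1, nb)]
        else:
            self.psi_pairs = []
        self.n_params = self.n_load + len(self.psi_pairs) + self.nf

    def start(self):
        x0 = np.full(self.n_load, 0.55)
        if self.spec.structure == "bifactor":
            x0[self.p :] = 0.35
        return np.concatenate([x0, np.full(len(self.psi_pairs), 0.4), np.zeros(self.nf)])

    def bounds(self):
        lo = np.full(self.n_params, -0.995)
        hi = np.full(self.n_params, 0.995)
        return lo, hi

    def split(self, theta):
        lam = np.zeros((self.p, self.nf))
        lam[self.load_rows, self.load_cols] = theta[: self.n_load]
        k = self.n_load
        psi_resid = np.zeros((self.nf, self.nf))
        for val, (a, b) in zip(theta[k : k + len(self.psi_pairs)], self.psi_pairs):
            psi_resid[a, b] = psi_resid[b, a] = val
        gamma = theta[self.n_load + len(self.psi_pairs) :]
        return lam, psi_resid, gamma

    def psi_eta(self, psi_resid, gamma):
        """Marginal factor covariance: gamma gamma' + residual part."""
        psi = np.outer(gamma, gamma) + psi_resid
        np.fill_diagonal(psi, 1.0)
        return psi

    def implied(self, theta):
        lam, psi_resid, gamma = self.split(theta)
        psi = self.psi_eta(psi_resid, gamma)
        sigma = lam @ psi @ lam.T
        return np.concatenate([sigma[self.jj, self.kk], lam @ gamma])

    def jacobian(self, theta):
        lam, psi_resid, gamma = self.split(theta)
        psi = self.psi_eta(psi_resid, gamma)
        jj, kk = self.jj, self.kk
        n_ii = jj.size
        n_resid = n_ii + self.p
        J = np.zeros((n_resid, self.n_params))
        m = psi @ lam.T  # F x p
        lam_gamma = lam @ gamma  # p
        rows_ii = np.arange(n_ii)
        # loadings
        for t in range(self.n_load):
            i, f = self.load_rows[t], self.load_cols[t]
            hit_j = jj == i
            hit_k = kk == i
            J[rows_ii[hit_j], t] += m[f, kk[hit_j]]
            J[rows_ii[hit_k], t] += m[f, jj[hit_k]]
            J[n_ii + i, t] += gamma[f]
        # residual factor correlations
        k0 = self.n_load
        for q, (a, b) in enumerate(self.psi_pairs):
            J[rows_ii, k0 + q] = lam[jj, a] * lam[kk, b] + lam[jj, b] * lam[kk, a]
        # gamma
        g0 = k0 + len(self.psi_pairs)
        for f in range(self.nf):
            d_ii = (
                lam[jj, f] * (lam[kk] @ gamma)
                + lam_gamma[jj] * lam[kk, f]
                - 2.0 * gamma[f] * lam[jj, f] * lam[kk, f]
            )
            J[rows_ii, g0 + f] = d_ii
            J[n_ii :, g0 + f] = lam[:, f]
        return J


def _align_prs(items: pd.DataFrame, prs) -> np.ndarray:
    from .prs import PolygenicScore

    if isinstance(prs, PolygenicScore):
        prs = prs.to_series()
    if isinstance(prs, pd.Series):
        if not items.index.isin(prs.index).all():
            missing = items.index[~items.index.isin(prs.index)]
            raise ValueError(
                f"{len(missing)} respondents have items but no PRS (e.g. {list(missing[:3])})"
            )
        return prs.reindex(items.index).to_numpy(dtype=float)
    arr = np.asarray(prs, dtype=float).ravel()
    if arr.size != len(items):
        raise ValueError("PRS vector length does not match the item table")
    return arr


def fit_structural(
    items: pd.DataFrame,
    prs,
    spec: ModelSpec | str = "bifactor",
    item_blocks: dict | None = None,
    weights=None,
    compute_se: bool = True,
) -> StructuralResult:
    """One-step MIMIC fit of all factors on one standardized PRS.

    Returns standardized betas with delta-method (sandwich) standard
    errors, Wald 95% CIs and normal-theory P-values, one row per factor
    (including GENERAL for the bifactor structure).
    """
    if not isinstance(items, pd.DataFrame):
        items = pd.DataFrame(np.asarray(items))
    if isinstance(spec, str):
        spec = build_model(spec, item_blocks, item_names=list(items.columns))
    x = _align_prs(items, prs)
    n = len(items)
    if np.nanstd(x) < 1e-12:
        raise ValueError("PRS is constant; structural model unidentified")

    poly = polychoric_matrix(items, weights=weights, compute_influence=compute_se)
    rho_ps, var_ps, infl_ps = polyserial_vector(
        x, items, weights=weights, n_categories=poly.n_categories,
        thresholds=poly.thresholds,
    )
    jj, kk = poly.pair_rows, poly.pair_cols
    layout = _StructuralLayout(spec, jj, kk)
    s_obs = np.concatenate([poly.pair_values, rho_ps])
    gamma_diag = np.concatenate(
        [np.maximum(poly.asy_var * n, 1e-12), np.maximum(var_ps * n, 1e-12)]
    )
    wdiag = 1.0 / gamma_diag
    sqw = np.sqrt(wdiag)

    from scipy.optimize import least_squares

    sol = least_squares(
        lambda t: sqw * (layout.implied(t) - s_obs),
        layout.start(),
        jac=lambda t: sqw[:, None] * layout.jacobian(t),
        bounds=layout.bounds(),
        method="trf",
        xtol=1e-12,
        ftol=1e-14,
        gtol=1e-10,
        max_nfev=500,
    )
    if not sol.success:
        raise RuntimeError(f"structural DWLS did not converge: {sol.message}")
    theta = sol.x
    lam, psi_resid, gamma = layout.split(theta)
    psi = layout.psi_eta(psi_resid, gamma)

    se = np.full(layout.n_params, np.nan)
    if compute_se:
        infl = np.concatenate([poly.influence, infl_ps], axis=1)
        infl = infl - infl.mean(axis=0, keepdims=True)
        gam_full = infl.T @ infl / n
        delta = layout.jacobian(theta)
        wd = wdiag[:, None] * delta
        h = delta.T @ wd
        hinv = np.linalg.pinv(h)
        meat = wd.T @ gam_full @ wd
        cov = hinv @ meat @ hinv / n
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    g0 = layout.n_load + len(layout.psi_pairs)
    gamma_se = se[g0:]
    z = np.divide(gamma, gamma_se, out=np.full_like(gamma, np.nan), where=gamma_se > 0)
    pvals = 2 * norm.sf(np.abs(z))
    crit = norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "outcome": spec.factor_names,
            "beta": gamma,
            "se": gamma_se,
            "lci": gamma - crit * gamma_se,
            "uci": gamma + crit * gamma_se,
            "p": pvals,
        }
    )
    fitted = FittedMeasurementModel(
        spec=spec,
        loadings=pd.DataFrame(lam, index=spec.item_names, columns=spec.factor_names),
        thresholds=list(poly.thresholds),
        factor_corr=pd.DataFrame(psi, index=spec.factor_names, columns=spec.factor_names),
        residual_variances=1.0 - np.einsum("jf,fg,jg->j", lam, psi, lam),
        discrepancy=float(sol.fun @ sol.fun),
        chi2=None,
        df=None,
        naive_df=int(s_obs.size - layout.n_params),
        n_parameters=spec.n_parameters(poly.n_categories) + spec.n_factors,
        n_obs=n,
        converged=bool(sol.success),
        gradient_norm=float(np.max(np.abs(sol.jac.T @ sol.fun))),
        heywood=1.0 - np.einsum("jf,fg,jg->j", lam, psi, lam) < 0,
        n_categories=poly.n_categories,
    )
    return StructuralResult(
        structure=spec.structure,
        table=table,
        n_analyzed=n,
        measurement=fitted,
        gamma=gamma,
        converged=bool(sol.success),
        weighted=weights is not None,
    )


def weighted_structural(
    items: pd.DataFrame,
    prs,
    spec: ModelSpec | str,
    ipw: IpwWeights | np.ndarray,
    item_blocks: dict | None = None,
    compute_se: bool = True,
) -> StructuralResult:
    """IPW-weighted structural fit; all estimating equations are weighted.

    With all weights equal to one this is exactly the unweighted fit (the
    same code path runs).
    """
    w = ipw.weight if isinstance(ipw, IpwWeights) else np.asarray(ipw, dtype=float)
    if np.any(w <= 0):
        raise ValueError("IPW weights must be positive")
    return fit_structural(
        items, prs, spec, item_blocks=item_blocks, weights=w, compute_se=compute_se
    )


# ---------------------------------------------------------------------------
# factor scores


def estimate_factor_scores(
    fitted: FittedMeasurementModel, items: pd.DataFrame, max_iter: int = 60, tol: float = 1e-7
) -> pd.DataFrame:
    """Maximum a posteriori factor scores under the ordinal model.

    The posterior mode of the latent factors given a respondent's
    responses (missing items marginalised by omission) is found by a
    damped Newton iteration vectorised over respondents.  Respondents
    with no observed responses get NaN scores.
    """
    if not isinstance(items, pd.DataFrame):
        items = pd.DataFrame(np.asarray(items))
    y = as_ordinal_codes(items[fitted.spec.item_names])
    n, p = y.shape
    lam = fitted.loadings_matrix()
    nf = lam.shape[1]
    psi = fitted.factor_corr.to_numpy()
    psi_inv = np.linalg.inv(psi)
    theta = np.clip(fitted.residual_variances, 1e-4, None)
    s = np.sqrt(theta)

    kmax = int(max(len(t) for t in fitted.thresholds)) + 1
    bnd = np.full((p, kmax + 1), np.inf)
    bnd[:, 0] = -np.inf
    for j, tau in enumerate(fitted.thresholds):
        bnd[j, 1 : len(tau) + 1] = tau
    ycl = np.clip(y, 0, None)
    lo = bnd[np.arange(p)[None, :], ycl]
    hi = bnd[np.arange(p)[None, :], ycl + 1]
    obs = y >= 0
    any_obs = obs.any(axis=1)

    eta = np.zeros((n, nf))

    def stats(eta):
        m = eta @ lam.T
        u_lo = np.clip((lo - m) / s[None, :], -37.0, 37.0)
        u_hi = np.clip((hi - m) / s[None, :], -37.0, 37.0)
        # evaluate the interval mass in whichever tail is numerically stable
        pr = np.where(
            u_lo > 0,
            norm.sf(u_lo) - norm.sf(u_hi),
            norm.cdf(u_hi) - norm.cdf(u_lo),
        )
        pr = np.clip(pr, 1e-290, None)
        phi_lo = norm.pdf(u_lo)
        phi_hi = norm.pdf(u_hi)
        g = np.where(obs, (phi_lo - phi_hi) / (s[None, :] * pr), 0.0)
        g = np.clip(g, -1e8, 1e8)
        t_lo = u_lo * phi_lo
        t_hi = u_hi * phi_hi
        h = (t_lo - t_hi) / (theta[None, :] * pr) - g * g
        # the ordinal-probit loglik is concave in m; clip away round-off
        h = np.where(obs, np.clip(h, -1e12, 0.0), 0.0)
        logp = np.where(obs, np.log(pr), 0.0).sum(axis=1)
        logpost = logp - 0.5 * np.einsum("nf,fg,ng->n", eta, psi_inv, eta)
        return g, h, logpost

    g, h, logpost = stats(eta)
    for _ in range(max_iter):
        grad = g @ lam - eta @ psi_inv
        if np.max(np.abs(grad[any_obs])) < tol:
            break
        hess = np.einsum("nj,jf,jg->nfg", h, lam, lam) - psi_inv[None, :, :]
        step = np.linalg.solve(-hess, grad[:, :, None])[:, :, 0]
        # trust-region cap keeps early iterations out of the far tails
        norms = np.linalg.norm(step, axis=1)
        step *= np.minimum(1.0, 4.0 / np.maximum(norms, 1e-12))[:, None]
        alpha = np.ones(n)
        for _half in range(15):
            eta_new = eta + alpha[:, None] * step
            g_new, h_new, lp_new = stats(eta_new)
            worse = (lp_new < logpost - 1e-10) | ~np.isfinite(lp_new)
            if not np.any(worse & any_obs):
                break
            alpha = np.where(worse, alpha * 0.5, alpha)
        eta, g, h, logpost = eta_new, g_new, h_new, lp_new
    eta[~any_obs] = np.nan
    return pd.DataFrame(eta, index=items.index, columns=fitted.spec.factor_names)


# ---------------------------------------------------------------------------
# permutation adjustment


def _t_stats(x: np.ndarray, scores: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    xc = (x - x.mean()) / x.std()
    sc = scores - scores.mean(axis=0, keepdims=True)
    sd = sc.std(axis=0)
    r = xc @ sc / (n * np.maximum(sd, 1e-300))
    r = np.clip(r, -0.999999, 0.999999)
    return r * np.sqrt((n - 2) / (1.0 - r * r))


def permutation_adjusted_p(
    scores, prs, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Max-T step-down family-wise adjusted P-values for score-on-PRS tests.

    The PRS vector is permuted jointly against all outcomes (preserving
    inter-factor correlation); each observed |t| is compared to the
    permutation distribution of the running maximum over the remaining
    family.  ``p = (1 + exceedances) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if isinstance(scores, pd.DataFrame):
        names = list(scores.columns)
        sc = scores.to_numpy(dtype=float)
    else:
        sc = np.asarray(scores, dtype=float)
        if sc.ndim == 1:
            sc = sc[:, None]
        names = [f"factor_{i + 1}" for i in range(sc.shape[1])]
    x = np.asarray(prs, dtype=float).ravel()
    keep = np.isfinite(x) & np.isfinite(sc).all(axis=1)
    x, sc = x[keep], sc[keep]
    if x.std() < 1e-12:
        raise ValueError("PRS is constant; permutation test undefined")
    rng = np.random.default_rng(seed)
    t_obs = _t_stats(x, sc)
    k = t_obs.size
    order = np.argsort(-np.abs(t_obs))
    abs_obs = np.abs(t_obs)

    t_perm = np.empty((n_perm, k))
    for b in range(n_perm):
        t_perm[b] = _t_stats(x[rng.permutation(x.size)], sc)
    abs_perm = np.abs(t_perm)

    p_unadj = (1.0 + (abs_perm >= abs_obs[None, :]).sum(axis=0)) / (1.0 + n_perm)
    # step-down running maxima over the ordered family
    run_max = np.maximum.accumulate(abs_perm[:, order][:, ::-1], axis=1)[:, ::-1]
    exceed = (run_max >= abs_obs[order][None, :]).sum(axis=0)
    p_sorted = (1.0 + exceed) / (1.0 + n_perm)
    p_sorted = np.maximum.accumulate(p_sorted)  # enforce monotonicity
    p_adj = np.empty(k)
    p_adj[order] = p_sorted
    p_adj = np.maximum(p_adj, p_unadj)
    table = pd.DataFrame(
        {"outcome": names, "t": t_obs, "p_unadjusted": p_unadj, "p_adjusted": p_adj}
    )
    return PermutationResult(table=table, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# inverse probability weighting


def estimate_ipw(
    included, covariates: pd.DataFrame, truncate_at: float | None = 0.99
) -> IpwWeights:
    """Logistic inclusion model and inverse-probability weights.

    Weights ``1/p_hat`` are returned for included respondents (NaN for the
    rest); weights above the ``truncate_at`` quantile are truncated, with
    the truncation logged in the result.
    """
    inc = np.asarray(included, dtype=float)
    X = sm.add_constant(np.asarray(covariates, dtype=float))
    model = sm.GLM(inc, X, family=sm.families.Binomial()).fit()
    if np.any(np.abs(model.params[1:]) > 30):
        j = int(np.argmax(np.abs(model.params[1:])))
        name = list(covariates.columns)[j] if hasattr(covariates, "columns") else str(j)
        raise ValueError(f"separation in the inclusion model (covariate {name!r})")
    prob = np.asarray(model.predict(X))
    weight = np.where(inc > 0, 1.0 / prob, np.nan)
    truncated = np.zeros(len(prob), dtype=bool)
    if truncate_at is not None:
        finite = np.isfinite(weight)
        cap = np.nanquantile(weight[finite], truncate_at)
        truncated = finite & (weight > cap)
        weight = np.where(truncated, cap, weight)
    return IpwWeights(
        probability=prob,
        weight=weight,
        truncated=truncated,
        truncate_at=truncate_at,
        model=model,
    )


class StructuralModel(BaseEstimator):
    """Scikit-learn style wrapper for the MIMIC structural fit.

    ``fit(X, y)`` takes the ordinal item table as ``X`` and the
    standardized PRS as ``y``; fitted attributes expose the per-factor
    results (``results_``, ``betas_``, ``se_``, ``pvalues_``).
    """

    def __init__(
        self,
        structure: str = "bifactor",
        item_blocks: dict | None = None,
        compute_se: bool = True,
    ):
        self.structure = structure
        self.item_blocks = item_blocks
        self.compute_se = compute_se

    def fit(self, X, y, sample_weight=None):
        res = fit_structural(
            X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X)),
            y,
            self.structure,
            item_blocks=self.item_blocks,
            weights=sample_weight,
            compute_se=self.compute_se,
        )
        self.result_ = res
        self.results_ = res.table
        self.betas_ = res.table.set_index("outcome")["beta"]
        self.se_ = res.table.set_index("outcome")["se"]
        self.pvalues_ = res.table.set_index("outcome")["p"]
        self.n_analyzed_ = res.n_analyzed
        self.measurement_ = res.measurement
        return self

    def factor_scores(self, X) -> pd.DataFrame:
        return estimate_factor_scores(
            self.measurement_, X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        )
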