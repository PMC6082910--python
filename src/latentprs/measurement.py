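"""Ordinal confirmatory factor models by polychoric + DWLS estimation.

Four competing measurement structures for a blocked item battery are
supported: four *uncorrelated* group factors, a single *unidimensional*
factor, four *correlated* group factors, and a *bifactor* structure (one
general factor loading on every item plus orthogonal block-specific
factors).  Estimation follows the WLSMV convention: item thresholds and
polychoric correlations are estimated first, then standardized loadings
(and factor correlations) minimise a diagonally weighted least-squares
discrepancy between observed and model-implied polychoric correlations.
The delta parameterization is used throughout — latent responses have
unit variance and factor variances are fixed at 1 — so loadings are
reported on the standardized scale.

The chi-square statistic carries a Satterthwaite mean-and-variance
adjustment computed from the full asymptotic covariance of the polychoric
estimates; absolute fit is summarised by RMSEA (with 90% CI), CFI and
TLI, and relative fit by AIC/BIC/ssaBIC from a marginal (full-information)
likelihood evaluated by quasi-Monte-Carlo integration over the factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.special import logsumexp
from scipy.stats import ncx2, norm, qmc
from sklearn.base import BaseEstimator, TransformerMixin

from .polychoric import (
    PolychoricSummary,
    as_ordinal_codes,
    polychoric_matrix,
)

__all__ = [
    "ModelSpec",
    "FittedMeasurementModel",
    "FitIndices",
    "STRUCTURES",
    "build_model",
    "fit_dwls",
    "fit_baseline",
    "compute_fit_indices",
    "marginal_loglik",
    "fit_marginal_ml",
    "apply_inclusion_filter",
    "MeasurementModel",
]

STRUCTURES = ("uncorrelated", "unidimensional", "correlated", "bifactor")
_LOAD_BOUND = 0.995


@dataclass
class ModelSpec:
    """Free-parameter skeleton for one measurement structure."""

    structure: str
    item_names: list[str]
    item_blocks: dict | None = None  # item -> block name
    block_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; choose from {STRUCTURES}")
        if self.structure != "unidimensional":
            if not self.item_blocks:
                raise ValueError(f"{self.structure} structure requires item_blocks")
            missing = [i for i in self.item_names if i not in self.item_blocks]
            if missing:
                raise ValueError(f"items without a block assignment: {missing[:5]}")
            if not self.block_names:
                # block-map insertion order, so factor order (and hence the
                # QMC dimension assignment) is invariant to item column order
                present = {self.item_blocks[i] for i in self.item_names}
                seen = []
                for b in self.item_blocks.values():
                    if b in present and b not in seen:
                        seen.append(b)
                self.block_names = seen

    @property
    def n_items(self) -> int:
        return len(self.item_names)

    @property
    def factor_names(self) -> list[str]:
        if self.structure == "unidimensional":
            return ["GENERAL"]
        if self.structure == "bifactor":
            return ["GENERAL", *self.block_names]
        return list(self.block_names)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def block_index(self) -> np.ndarray:
        if self.structure == "unidimensional":
            return np.zeros(self.n_items, dtype=int)
        lut = {b: i for i, b in enumerate(self.block_names)}
        return np.array([lut[self.item_blocks[i]] for i in self.item_names])

    @property
    def n_free_loadings(self) -> int:
        return 2 * self.n_items if self.structure == "bifactor" else self.n_items

    @property
    def n_factor_correlations(self) -> int:
        if self.structure != "correlated":
            return 0
        b = len(self.block_names)
        return b * (b - 1) // 2

    def n_parameters(self, n_categories) -> int:
        """Free parameters: loadings + thresholds + factor correlations."""
        n_thresh = int(np.sum(np.asarray(n_categories) - 1))
        return self.n_free_loadings + n_thresh + self.n_factor_correlations


def build_model(structure: str, item_blocks: dict | None, item_names=None) -> ModelSpec:
    """Construct a :class:`ModelSpec`; factor variances are fixed at 1."""
    if item_names is None:
        if not item_blocks:
            raise ValueError("item_names required when item_blocks is empty")
        item_names = list(item_blocks)
    return ModelSpec(structure=structure, item_names=list(item_names), item_blocks=item_blocks)


# ---------------------------------------------------------------------------
# structure parameterizations


class _Layout:
    """Maps the free-parameter vector to implied correlations and Jacobians."""

    def __init__(self, spec: ModelSpec, jj: np.ndarray, kk: np.ndarray):
        self.spec = spec
        self.jj = jj
        self.kk = kk
        self.p = spec.n_items
        self.block = spec.block_index()
        self.same = self.block[jj] == self.block[kk]
        self.n_pairs = jj.size
        s = spec.structure
        if s == "bifactor":
            self.n_params = 2 * self.p
        elif s == "correlated":
            nb = len(spec.block_names)
            self.psi_pairs = [(a, b) for a in range(nb) for b in range(a + 1, nb)]
            self.n_params = self.p + len(self.psi_pairs)
        else:
            self.n_params = self.p

    def start(self) -> np.ndarray:
        s = self.spec.structure
        if s == "bifactor":
            return np.concatenate([np.full(self.p, 0.55), np.full(self.p, 0.35)])
        if s == "correlated":
            return np.concatenate([np.full(self.p, 0.6), np.full(len(self.psi_pairs), 0.4)])
        return np.full(self.p, 0.6)

    def bounds(self):
        lo = np.full(self.n_params, -_LOAD_BOUND)
        hi = np.full(self.n_params, _LOAD_BOUND)
        return lo, hi

    def _psi_matrix(self, theta):
        nb = len(self.spec.block_names)
        psi = np.eye(nb)
        for val, (a, b) in zip(theta[self.p :], self.psi_pairs):
            psi[a, b] = psi[b, a] = val
        return psi

    def implied(self, theta: np.ndarray) -> np.ndarray:
        s = self.spec.structure
        jj, kk = self.jj, self.kk
        if s == "unidimensional":
            lam = theta
            return lam[jj] * lam[kk]
        if s == "uncorrelated":
            lam = theta
            return np.where(self.same, lam[jj] * lam[kk], 0.0)
        if s == "correlated":
            lam = theta[: self.p]
            psi = self._psi_matrix(theta)
            return lam[jj] * lam[kk] * psi[self.block[jj], self.block[kk]]
        lam_g = theta[: self.p]
        lam_s = theta[self.p :]
        return lam_g[jj] * lam_g[kk] + np.where(self.same, lam_s[jj] * lam_s[kk], 0.0)

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        s = self.spec.structure
        jj, kk = self.jj, self.kk
        rows = np.arange(self.n_pairs)
        J = np.zeros((self.n_pairs, self.n_params))
        if s in ("unidimensional", "uncorrelated"):
            lam = theta
            fac = 1.0 if s == "unidimensional" else self.same.astype(float)
            np.add.at(J, (rows, jj), fac * lam[kk])
            np.add.at(J, (rows, kk), fac * lam[jj])
            return J
        if s == "correlated":
            lam = theta[: self.p]
            psi = self._psi_matrix(theta)
            pw = psi[self.block[jj], self.block[kk]]
            np.add.at(J, (rows, jj), pw * lam[kk])
            np.add.at(J, (rows, kk), pw * lam[jj])
            for q, (a, b) in enumerate(self.psi_pairs):
                hit = (
                    ((self.block[jj] == a) & (self.block[kk] == b))
                    | ((self.block[jj] == b) & (self.block[kk] == a))
                )
                J[hit, self.p + q] = lam[jj[hit]] * lam[kk[hit]]
            return J
        lam_g = theta[: self.p]
        lam_s = theta[self.p :]
        np.add.at(J, (rows, jj), lam_g[kk])
        np.add.at(J, (rows, kk), lam_g[jj])
        same = self.same
        np.add.at(J, (rows[same], self.p + jj[same]), lam_s[kk[same]])
        np.add.at(J, (rows[same], self.p + kk[same]), lam_s[jj[same]])
        return J

    def unpack(self, theta: np.ndarray):
        """(loadings item x factor, factor correlation matrix)."""
        spec = self.spec
        lam = np.zeros((self.p, spec.n_factors))
        psi = np.eye(spec.n_factors)
        s = spec.structure
        if s == "unidimensional":
            lam[:, 0] = theta
        elif s in ("uncorrelated", "correlated"):
            lam[np.arange(self.p), self.block] = theta[: self.p]
            if s == "correlated":
                psi = self._psi_matrix(theta)
        else:
            lam[:, 0] = theta[: self.p]
            lam[np.arange(self.p), self.block + 1] = theta[self.p :]
        return lam, psi


@dataclass
class FittedMeasurementModel:
    """DWLS solution for one structure, with adjusted test statistic."""

    spec: ModelSpec
    loadings: pd.DataFrame  # item x factor, standardized
    thresholds: list[np.ndarray]
    factor_corr: pd.DataFrame
    residual_variances: np.ndarray
    discrepancy: float
    chi2: float | None
    df: float | None
    naive_df: int
    n_parameters: int
    n_obs: int
    converged: bool
    gradient_norm: float
    heywood: np.ndarray
    n_categories: np.ndarray
    # internals reused by fit indices / structural standard errors
    _jac: np.ndarray | None = None
    _wdiag: np.ndarray | None = None
    _gamma: np.ndarray | None = None

    @property
    def structure(self) -> str:
        return self.spec.structure

    def loadings_matrix(self) -> np.ndarray:
        return self.loadings.to_numpy()


def _adjusted_chi2(resid_w, wdiag, jac, gamma, n):
    """Satterthwaite mean-variance adjustment of the DWLS chi-square.

    T = n F is a quadratic form in the asymptotically normal polychoric
    deviations; its distribution is matched to a scaled chi-square with
    estimated (non-integer) degrees of freedom via the first two moments
    of tr-based formulas.
    """
    t_raw = n * float(resid_w)
    if jac is None or jac.size == 0:
        awg = wdiag[:, None] * gamma
    else:
        wj = wdiag[:, None] * jac
        h = jac.T @ wj
        try:
            hinv = np.linalg.inv(h)
        except np.linalg.LinAlgError:
            hinv = np.linalg.pinv(h)
        proj = np.eye(jac.shape[0]) - jac @ (hinv @ wj.T)
        awg = (proj.T * wdiag) @ proj @ gamma
    t1 = float(np.trace(awg))
    t2 = float(np.einsum("ij,ji->", awg, awg))
    if t1 <= 0 or t2 <= 0:
        return 0.0, 0.0
    df_adj = t1 * t1 / t2
    return t_raw * t1 / t2, df_adj


def fit_dwls(
    poly: PolychoricSummary,
    spec: ModelSpec,
    n: int | None = None,
    compute_stats: bool = True,
) -> FittedMeasurementModel:
    """Diagonally weighted least squares on the polychoric correlations.

    Minimises ``sum_w (rho_obs - rho_model(theta))^2`` with weights the
    inverse asymptotic variances of the pairwise estimates; the full
    asymptotic covariance enters only the mean-variance chi-square
    adjustment (requires the summary's influence functions).
    """
    n = poly.n_obs if n is None else n
    jj, kk = poly.pair_rows, poly.pair_cols
    layout = _Layout(spec, jj, kk)
    s_obs = poly.pair_values
    gamma_diag = np.maximum(poly.asy_var * max(n, 1), 1e-12)
    wdiag = 1.0 / gamma_diag
    sqw = np.sqrt(wdiag)

    def resid(theta):
        return sqw * (layout.implied(theta) - s_obs)

    def jac(theta):
        return sqw[:, None] * layout.jacobian(theta)

    sol = least_squares(
        resid,
        layout.start(),
        jac=jac,
        bounds=layout.bounds(),
        method="trf",
        xtol=1e-12,
        ftol=1e-14,
        gtol=1e-10,
        max_nfev=400,
    )
    grad_norm = float(np.max(np.abs(sol.jac.T @ sol.fun))) if sol.jac is not None else np.inf
    if not sol.success:
        raise RuntimeError(
            f"DWLS did not converge for {spec.structure}: {sol.message} "
            f"(last gradient norm {grad_norm:.3e})"
        )
    theta = sol.x
    lam, psi = layout.unpack(theta)
    resid_var = 1.0 - np.einsum("jf,fg,jg->j", lam, psi, lam)
    heywood = resid_var < 0
    if heywood.any():
        warnings.warn(
            f"Heywood case: {int(heywood.sum())} item(s) with negative residual "
            "variance; loadings are at the boundary constraint"
        )
    discrepancy = float(sol.fun @ sol.fun)

    chi2 = df_adj = None
    gamma = None
    jac_opt = layout.jacobian(theta)
    if compute_stats and poly.influence is not None:
        gamma = poly.gamma()
        chi2, df_adj = _adjusted_chi2(discrepancy, wdiag, jac_opt, gamma, n)

    return FittedMeasurementModel(
        spec=spec,
        loadings=pd.DataFrame(lam, index=spec.item_names, columns=spec.factor_names),
        thresholds=list(poly.thresholds),
        factor_corr=pd.DataFrame(psi, index=spec.factor_names, columns=spec.factor_names),
        residual_variances=resid_var,
        discrepancy=discrepancy,
        chi2=chi2,
        df=df_adj,
        naive_df=int(jj.size - layout.n_params),
        n_parameters=spec.n_parameters(poly.n_categories),
        n_obs=n,
        converged=bool(sol.success),
        gradient_norm=grad_norm,
        heywood=heywood,
        n_categories=poly.n_categories,
        _jac=jac_opt,
        _wdiag=wdiag,
        _gamma=gamma,
    )


def fit_baseline(poly: PolychoricSummary, n: int | None = None):
    """Independence baseline (free thresholds, all correlations zero).

    Returns ``(chi2_adjusted, df_adjusted)`` for CFI/TLI.
    """
    n = poly.n_obs if n is None else n
    gamma_diag = np.maximum(poly.asy_var * max(n, 1), 1e-12)
    wdiag = 1.0 / gamma_diag
    s_obs = poly.pair_values
    f0 = float(np.sum(wdiag * s_obs * s_obs))
    if poly.influence is None:
        return n * f0, float(s_obs.size)
    gamma = poly.gamma()
    return _adjusted_chi2(f0, wdiag, None, gamma, n)


@dataclass
class FitIndices:
    rmsea: float
    rmsea_ci: tuple
    cfi: float
    tli: float
    chi2: float
    df: float
    aic: float | None = None
    bic: float | None = None
    ssa_bic: float | None = None
    n_integration_points: int | None = None
    rmsea_undefined: bool = False

    def format_rmsea(self) -> str:
        return f"{self.rmsea:.3f} ({self.rmsea_ci[0]:.3f}, {self.rmsea_ci[1]:.3f})"


def _rmsea_ci(chi2, df, n, level=0.90):
    """90% CI by noncentral chi-square root finding on the noncentrality."""
    alpha = (1.0 - level) / 2.0

    def upper_tail(lam):
        return ncx2.cdf(chi2, df, lam)

    hi = max(chi2 * 5, df * 5, 10.0)
    lo_l = 0.0
    if upper_tail(0.0) > 1 - alpha:  # chi2 well beyond central: lower bound > 0
        lo_l = brentq(lambda l: upper_tail(l) - (1 - alpha), 0.0, hi, xtol=1e-8)
    hi_l = 0.0
    if upper_tail(0.0) > alpha:
        hi_l = brentq(lambda l: upper_tail(l) - alpha, 0.0, hi, xtol=1e-8)
    return (np.sqrt(lo_l / (df * n)), np.sqrt(hi_l / (df * n)))


def compute_fit_indices(
    fitted: FittedMeasurementModel,
    baseline: tuple[float, float],
    n: int | None = None,
) -> FitIndices:
    """RMSEA (with 90% CI), CFI and TLI from adjusted chi-squares.

    ``baseline`` is the ``(chi2, df)`` of the independence model on the
    same data (see :func:`fit_baseline`).
    """
    n = fitted.n_obs if n is None else n
    chi2_m, df_m = fitted.chi2, fitted.df
    if chi2_m is None:
        raise ValueError("fitted model lacks an adjusted chi-square (compute_stats=False?)")
    chi2_b, df_b = baseline
    undefined = df_m <= 0
    if undefined:
        rmsea, ci = 0.0, (0.0, 0.0)
    else:
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * n)))
        ci = _rmsea_ci(chi2_m, df_m, n)
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    denom_tli = chi2_b / df_b - 1.0
    tli = 1.0 if denom_tli <= 0 else (chi2_b / df_b - chi2_m / df_m) / denom_tli
    return FitIndices(
        rmsea=rmsea,
        rmsea_ci=ci,
        cfi=float(cfi),
        tli=float(tli),
        chi2=float(chi2_m),
        df=float(df_m),
        rmsea_undefined=bool(undefined),
    )


# ---------------------------------------------------------------------------
# marginal (full-information) likelihood for information criteria


def marginal_loglik(
    items,
    loadings: np.ndarray,
    thresholds: list,
    factor_corr: np.ndarray | None = None,
    n_points: int = 8000,
    seed: int = 0,
    chunk: int = 512,
) -> float:
    """Marginal log-likelihood of the ordinal responses.

    Integrates the graded (normal-ogive) response model over the latent
    factors with scrambled low-discrepancy (Halton) points mapped through
    the factor distribution; respondent-level missingness is marginalised
    by skipping missing items.
    """
    y = as_ordinal_codes(items)
    n, p = y.shape
    lam = np.asarray(loadings, float)
    nf = lam.shape[1]
    psi = np.eye(nf) if factor_corr is None else np.asarray(factor_corr, float)
    if n_points < 500:
        raise ValueError("n_points must be at least 500")
    if n_points < 500 * nf:
        warnings.warn("integration point count is small for the factor count")
    sampler = qmc.Halton(d=nf, scramble=True, seed=seed)
    u = sampler.random(n_points)
    z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    eta = z @ np.linalg.cholesky(psi).T

    resid = np.clip(1.0 - np.einsum("jf,fg,jg->j", lam, psi, lam), 1e-6, None)
    sd = np.sqrt(resid)
    kmax = max(len(t) for t in thresholds) + 1
    # padded category slots stay 0: they are never selected by the one-hot
    # design below, and 0 * 0 keeps the GEMM finite
    logprob = np.zeros((n_points, p, kmax))
    m = eta @ lam.T  # q x p
    for j, tau in enumerate(thresholds):
        bnd = np.concatenate([[-np.inf], tau, [np.inf]])
        cdf = norm.cdf((bnd[None, :] - m[:, j : j + 1]) / sd[j])
        pr = np.maximum(np.diff(cdf, axis=1), 1e-300)
        logprob[:, j, : pr.shape[1]] = np.log(pr)
    lp_flat = np.ascontiguousarray(logprob.reshape(n_points, p * kmax))

    # per-respondent log-likelihood contributions as one BLAS product per
    # chunk: one-hot item-category design (missing -> all-zero row)
    total = 0.0
    logq = np.log(n_points)
    cols_base = np.arange(p) * kmax
    for start in range(0, n, max(chunk, 1)):
        yb = y[start : start + chunk]
        nb = yb.shape[0]
        onehot = np.zeros((nb, p * kmax))
        obs = yb >= 0
        rows, item_idx = np.nonzero(obs)
        onehot[rows, cols_base[item_idx] + yb[obs]] = 1.0
        acc = lp_flat @ onehot.T  # q x nb
        total += float(logsumexp(acc, axis=0).sum()) - logq * nb
    return total


def fit_marginal_ml(
    items,
    fitted: FittedMeasurementModel,
    n_points: int = 8000,
    seed: int = 0,
) -> FitIndices:
    """AIC/BIC/ssaBIC from the marginal likelihood at the DWLS solution.

    The limited-information estimates are consistent for the graded
    response model, so the marginal likelihood evaluated at them supports
    information-criterion comparison across structures without a separate
    full-information optimisation.
    """
    ll = marginal_loglik(
        items,
        fitted.loadings_matrix(),
        fitted.thresholds,
        fitted.factor_corr.to_numpy(),
        n_points=n_points,
        seed=seed,
    )
    y = as_ordinal_codes(items)
    n = int((y >= 0).any(axis=1).sum())
    k = fitted.n_parameters
    aic = -2 * ll + 2 * k
    bic = -2 * ll + k * np.log(n)
    ssa = -2 * ll + k * np.log((n + 2) / 24.0)
    return {"loglik": ll, "aic": aic, "bic": bic, "ssa_bic": ssa,
            "n_parameters": k, "n_obs": n, "n_integration_points": n_points}


def apply_inclusion_filter(
    items: pd.DataFrame, item_blocks: dict, min_per_block: int = 4
):
    """Keep respondents answering >= ``min_per_block`` items in every block."""
    blocks = {}
    for item, b in item_blocks.items():
        blocks.setdefault(b, []).append(item)
    keep = pd.Series(True, index=items.index)
    per_block = {}
    for b, cols in blocks.items():
        answered = items[cols].notna().sum(axis=1)
        per_block[b] = answered
        keep &= answered >= min_per_block
    report = {
        "n_input": int(len(items)),
        "n_kept": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
        "min_per_block": int(min_per_block),
    }
    return items.loc[keep], report


class MeasurementModel(TransformerMixin, BaseEstimator):
    """Scikit-learn style ordinal CFA estimator.

    ``fit`` runs the polychoric + DWLS pipeline for the requested
    structure; ``transform`` returns MAP factor scores.  Fitted attributes
    follow the trailing-underscore convention (``loadings_``,
    ``thresholds_``, ``factor_corr_``, ``chi2_``, ``df_``, ``fit_indices_``).
    """

    def __init__(
        self,
        structure: str = "bifactor",
        item_blocks: dict | None = None,
        compute_stats: bool = True,
        information_criteria: bool = False,
        n_integration_points: int = 8000,
        random_state: int = 0,
    ):
        self.structure = structure
        self.item_blocks = item_blocks
        self.compute_stats = compute_stats
        self.information_criteria = information_criteria
        self.n_integration_points = n_integration_points
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None):
        items = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        spec = build_model(self.structure, self.item_blocks, item_names=list(items.columns))
        poly = polychoric_matrix(
            items, weights=sample_weight, compute_influence=self.compute_stats
        )
        fitted = fit_dwls(poly, spec, compute_stats=self.compute_stats)
        self.spec_ = spec
        self.result_ = fitted
        self.loadings_ = fitted.loadings
        self.thresholds_ = fitted.thresholds
        self.factor_corr_ = fitted.factor_corr
        self.residual_variances_ = fitted.residual_variances
        self.n_obs_ = fitted.n_obs
        self.chi2_ = fitted.chi2
        self.df_ = fitted.df
        if self.compute_stats:
            baseline = fit_baseline(poly)
            self.fit_indices_ = compute_fit_indices(fitted, baseline)
        if self.information_criteria:
            ics = fit_marginal_ml(
                items, fitted, n_points=self.n_integration_points, seed=self.random_state
            )
            self.information_criteria_ = ics
            if self.compute_stats:
                self.fit_indices_.aic = ics["aic"]
                self.fit_indices_.bic = ics["bic"]
                self.fit_indices_.ssa_bic = ics["ssa_bic"]
                self.fit_indices_.n_integration_points = ics["n_integration_points"]
        return self

    def transform(self, X) -> np.ndarray:
        from .association import estimate_factor_scores

        items = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        scores = estimate_factor_scores(self.result_, items)
        return scores.to_numpy()
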