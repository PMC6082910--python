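"""Synthetic cohorts with a bifactor psychopathology truth.

The generator emulates the structure of an adolescent-cohort analysis
linking polygenic risk scores to latent psychopathology: 51 ordinal
questionnaire items in four instrument blocks (10 three-category
psychotic-experience items, 11 four-category negative-dimension items,
13 three-category depression items and 17 anxiety items), a bifactor
truth (one general psychopathology factor plus four orthogonal specific
factors), small standardised PRS effects on the factors, auxiliary
covariates, and covariate-dependent (MAR) missingness so that
inverse-probability weighting is a consistent correction by construction.

Everything is seeded; the same seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .prs import GenotypeMatrix

__all__ = [
    "TrueModel",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_summary_stats",
    "simulate_factors",
    "simulate_item_responses",
    "simulate_covariates",
    "simulate_missingness",
    "simulate_cohort",
    "write_items_csv",
    "write_truth_yaml",
]

BLOCK_NAMES = ("psychotic_experiences", "negative_dimension", "depression", "anxiety")
GENERAL = "GENERAL"
DEFAULT_ITEMS_PER_BLOCK = (10, 11, 13, 17)
DEFAULT_CATEGORIES_PER_BLOCK = (3, 4, 3, 3)

# default single-PRS standardised effects on (general, four specifics):
# magnitudes in the 0.03-0.09 range typical of adolescent-cohort PRS work
DEFAULT_PRS_BETAS = {
    GENERAL: (0.055,),
    "psychotic_experiences": (0.062,),
    "negative_dimension": (0.066,),
    "depression": (-0.013,),
    "anxiety": (0.029,),
}


@dataclass
class TrueModel:
    """Generating bifactor parameters for the ordinal item battery."""

    n_items_per_block: tuple = DEFAULT_ITEMS_PER_BLOCK
    categories_per_block: tuple = DEFAULT_CATEGORIES_PER_BLOCK
    general_loadings: np.ndarray | None = None
    specific_loadings: np.ndarray | None = None
    thresholds: list | None = None
    prs_betas: dict = field(default_factory=lambda: dict(DEFAULT_PRS_BETAS))
    seed: int = 0

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        p = self.n_items
        if self.general_loadings is None:
            # strong general factor, weaker specifics: the loading pattern
            # reported for general-psychopathology batteries
            self.general_loadings = rng.uniform(0.5, 0.8, p)
        if self.specific_loadings is None:
            self.specific_loadings = rng.uniform(0.3, 0.6, p)
        self.general_loadings = np.asarray(self.general_loadings, float)
        self.specific_loadings = np.asarray(self.specific_loadings, float)
        if self.thresholds is None:
            ths = []
            for b, (nb, kb) in enumerate(
                zip(self.n_items_per_block, self.categories_per_block)
            ):
                for _ in range(nb):
                    if kb == 2:
                        base = np.array([0.8])
                    elif kb == 3:
                        base = np.array([0.6, 1.5])  # right-skewed symptom items
                    else:
                        base = np.linspace(0.2, 1.8, kb - 1)
                    ths.append(base + rng.uniform(-0.15, 0.15, kb - 1))
            self.thresholds = ths
        self.thresholds = [np.asarray(t, float) for t in self.thresholds]
        self.prs_betas = {
            k: np.atleast_1d(np.asarray(v, float)) for k, v in self.prs_betas.items()
        }
        self.validate()

    def validate(self) -> None:
        p = self.n_items
        if len(self.general_loadings) != p or len(self.specific_loadings) != p:
            raise ValueError("loading vectors must have one entry per item")
        comm = self.general_loadings**2 + self.specific_loadings**2
        if np.any(comm >= 1.0):
            raise ValueError("general^2 + specific^2 must stay below 1 per item")
        if not np.all((self.general_loadings > 0) & (self.general_loadings < 1)):
            raise ValueError("general loadings must lie in (0, 1)")
        if np.any(self.specific_loadings < 0) or np.any(self.specific_loadings >= 1):
            raise ValueError("specific loadings must lie in [0, 1)")
        if len(self.thresholds) != p:
            raise ValueError("need one threshold vector per item")
        for tau, k in zip(self.thresholds, self.item_categories):
            if len(tau) != k - 1:
                raise ValueError("threshold vector length must equal categories - 1")
            if np.any(np.diff(tau) <= 0):
                raise ValueError("thresholds must be strictly ascending")
        for fac, beta in self.prs_betas.items():
            if fac != GENERAL and fac not in BLOCK_NAMES:
                raise ValueError(f"unknown factor in prs_betas: {fac}")

    # -- layout -----------------------------------------------------------
    @property
    def n_items(self) -> int:
        return int(sum(self.n_items_per_block))

    @property
    def factor_names(self) -> list[str]:
        return [GENERAL, *BLOCK_NAMES]

    @property
    def item_names(self) -> list[str]:
        short = {"psychotic_experiences": "pe", "negative_dimension": "neg",
                 "depression": "dep", "anxiety": "anx"}
        names = []
        for block, nb in zip(BLOCK_NAMES, self.n_items_per_block):
            names += [f"{short[block]}_{i + 1:02d}" for i in range(nb)]
        return names

    @property
    def item_blocks(self) -> dict:
        blocks = {}
        names = self.item_names
        j = 0
        for block, nb in zip(BLOCK_NAMES, self.n_items_per_block):
            for _ in range(nb):
                blocks[names[j]] = block
                j += 1
        return blocks

    @property
    def item_categories(self) -> np.ndarray:
        return np.repeat(self.categories_per_block, self.n_items_per_block)

    @property
    def n_prs(self) -> int:
        return len(next(iter(self.prs_betas.values())))

    def loadings_matrix(self) -> np.ndarray:
        """Item x factor matrix, columns (GENERAL, 4 specifics)."""
        p = self.n_items
        lam = np.zeros((p, 5))
        lam[:, 0] = self.general_loadings
        j = 0
        for b, nb in enumerate(self.n_items_per_block):
            lam[j : j + nb, b + 1] = self.specific_loadings[j : j + nb]
            j += nb
        return lam

    def beta_matrix(self) -> np.ndarray:
        """Factor x PRS matrix of standardised structural effects."""
        return np.vstack(
            [self.prs_betas.get(f, np.zeros(self.n_prs)) for f in self.factor_names]
        )


@dataclass
class SyntheticCohort:
    """All simulation outputs for one seeded cohort."""

    genotypes: GenotypeMatrix
    summary_stats: list  # one validated sumstats DataFrame per PRS trait
    true_prs: pd.DataFrame  # standardised, one column per trait
    factor_scores: pd.DataFrame  # general + 4 specifics
    items_complete: pd.DataFrame
    items: pd.DataFrame  # with missingness applied
    covariates: pd.DataFrame
    inclusion_probability: np.ndarray
    included: np.ndarray
    observed_mask: np.ndarray
    model: TrueModel


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5), seed: int = 0) -> GenotypeMatrix:
    """Hardy-Weinberg allele counts with per-SNP MAF uniform in ``maf_range``."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, m)
    g = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    # unambiguous allele pairs so default harmonisation keeps every SNP
    pairs = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")], dtype=object)
    pick = rng.integers(0, len(pairs), m)
    counted = pairs[pick, 0]
    other = pairs[pick, 1]
    return GenotypeMatrix(
        samples=[f"id_{i + 1:05d}" for i in range(n)],
        snp_ids=[f"rs{j + 1}" for j in range(m)],
        dosages=g,
        counted_allele=counted,
        other_allele=other,
    )


def simulate_summary_stats(
    genotypes: GenotypeMatrix,
    causal_fraction: float = 0.3,
    effect_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Discovery-style summary statistics aligned to a genotype panel.

    Causal SNPs get nonzero weights and small P-values so that P_T
    thresholding retains them preferentially; the remainder get null
    weights and uniform P-values.
    """
    rng = np.random.default_rng(seed)
    m = genotypes.n_snps
    causal = rng.random(m) < causal_fraction
    weight = np.where(causal, rng.normal(0.0, effect_sd, m), rng.normal(0.0, effect_sd / 5, m))
    p = np.where(causal, 10 ** rng.uniform(-8, -2, m), rng.uniform(1e-4, 1.0, m))
    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "effect_allele": genotypes.counted_allele,
            "other_allele": genotypes.other_allele,
            "weight": weight,
            "p_value": np.clip(p, 1e-300, 1.0),
        }
    )


def simulate_factors(
    prs_standardized, betas, n: int | None = None, seed: int = 0
) -> np.ndarray:
    """Latent factor scores with given standardised PRS effects.

    Each factor is ``sum_k beta_k PRS_k + residual`` with the residual
    variance set so the factor has unit total variance; regressing a
    factor on the PRSs therefore recovers ``beta`` in expectation.  The
    residuals are mutually independent, which keeps the bifactor truth
    orthogonal.

    ``betas`` may be a factor-name -> coefficient-vector mapping or a
    (n_factors x n_prs) array.
    """
    rng = np.random.default_rng(seed)
    if prs_standardized is None:
        if n is None:
            raise ValueError("n required when no PRS matrix is given")
        x = np.zeros((n, 1))
        b = np.zeros((np.shape(betas)[0] if not isinstance(betas, dict) else 5, 1))
    else:
        x = np.asarray(prs_standardized, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if isinstance(betas, dict):
            nk = x.shape[1]
            order = [GENERAL, *BLOCK_NAMES]
            b = np.vstack([np.broadcast_to(np.atleast_1d(betas.get(f, 0.0)), (nk,))
                           for f in order])
        else:
            b = np.atleast_2d(np.asarray(betas, dtype=float))
        n = x.shape[0]
    cov = np.cov(x, rowvar=False).reshape(x.shape[1], x.shape[1]) if n > 1 else np.eye(x.shape[1])
    explained = np.einsum("fk,kl,fl->f", b, cov, b)
    if np.any(explained >= 1.0):
        raise ValueError("sum of squared betas implies factor variance >= 1; infeasible")
    resid_sd = np.sqrt(1.0 - explained)
    eta = x @ b.T + rng.standard_normal((n, b.shape[0])) * resid_sd[None, :]
    return eta


def simulate_item_responses(factors, model: TrueModel, seed: int = 0) -> pd.DataFrame:
    """Ordinal responses from the graded (normal-ogive) response model.

    Latent response ``y* = lambda_g g + lambda_s s_block + eps`` with
    ``eps ~ N(0, 1 - lambda_g^2 - lambda_s^2)`` so that y* has unit
    variance; the observed category counts the thresholds below y*.
    """
    eta = np.asarray(factors, dtype=float)
    lam = model.loadings_matrix()
    if eta.shape[1] != lam.shape[1]:
        raise ValueError("factor matrix does not match the model's factor layout")
    rng = np.random.default_rng(seed)
    comm = (lam**2).sum(axis=1)
    ystar = eta @ lam.T + rng.standard_normal((eta.shape[0], lam.shape[0])) * np.sqrt(
        1.0 - comm
    )
    cats = np.empty_like(ystar, dtype=np.int64)
    for j, tau in enumerate(model.thresholds):
        cats[:, j] = np.searchsorted(tau, ystar[:, j])
    return pd.DataFrame(cats, columns=model.item_names)


def simulate_covariates(
    factors, seed: int = 0, advantage_loading: float = -0.5
) -> pd.DataFrame:
    """Auxiliary covariates for the missingness model.

    ``female`` is an independent Bernoulli(0.5) indicator; ``advantage``
    (socio-economic background score) correlates negatively with the
    general factor, so selection on it induces selection on outcome.
    """
    eta = np.asarray(factors, dtype=float)
    rng = np.random.default_rng(seed)
    n = eta.shape[0]
    a = advantage_loading
    advantage = a * eta[:, 0] + np.sqrt(1 - a * a) * rng.standard_normal(n)
    female = rng.random(n) < 0.5
    return pd.DataFrame({"female": female.astype(float), "advantage": advantage})


DEFAULT_MISSINGNESS = {"intercept": 0.4, "female": 0.3, "advantage": 1.2}


def simulate_missingness(
    covariates: pd.DataFrame,
    n_items: int,
    coefficients: dict | None = None,
    item_missing_rate: float = 0.02,
    seed: int = 0,
):
    """MAR inclusion given observed covariates.

    Returns ``(inclusion_probability, included, observed_mask)``.  The
    mask hides all item responses of non-included respondents and a small
    sporadic fraction elsewhere.  Missingness never depends on the latent
    factors directly, only on covariates, so IPW on those covariates is a
    consistent correction.
    """
    coefficients = dict(DEFAULT_MISSINGNESS if coefficients is None else coefficients)
    rng = np.random.default_rng(seed)
    lin = np.full(len(covariates), float(coefficients.pop("intercept", 0.0)))
    for name, coef in coefficients.items():
        lin += float(coef) * covariates[name].to_numpy(dtype=float)
    prob = expit(lin)
    included = rng.random(len(prob)) < prob
    mask = np.ones((len(prob), n_items), dtype=bool)
    if item_missing_rate > 0:
        mask = rng.random(mask.shape) >= item_missing_rate
    mask &= included[:, None]
    return prob, included, mask


def simulate_cohort(
    n: int = 3650,
    model: TrueModel | None = None,
    n_snps: int = 300,
    maf_range=(0.05, 0.5),
    missingness_coefficients: dict | None = None,
    item_missing_rate: float = 0.02,
    seed: int = 0,
) -> SyntheticCohort:
    """End-to-end seeded cohort: genotypes -> PRS -> factors -> items -> mask."""
    model = model if model is not None else TrueModel(seed=seed)
    geno = simulate_genotypes(n, n_snps, maf_range, seed=seed)
    rng_offsets = np.random.SeedSequence(seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in rng_offsets]
    stats = [
        simulate_summary_stats(geno, seed=sub[0] + k) for k in range(model.n_prs)
    ]
    prs_cols = {}
    for k, st in enumerate(stats):
        w = st["weight"].to_numpy()
        raw = np.where(np.isnan(geno.dosages), 2 * geno.allele_frequency()[None, :],
                       geno.dosages) @ w
        prs_cols[f"prs_{k + 1}"] = (raw - raw.mean()) / raw.std()
    true_prs = pd.DataFrame(prs_cols, index=geno.samples)
    eta = simulate_factors(true_prs.to_numpy(), model.prs_betas, seed=sub[1])
    items_complete = simulate_item_responses(eta, model, seed=sub[2])
    items_complete.index = pd.Index(geno.samples)
    covariates = simulate_covariates(eta, seed=sub[3])
    covariates.index = pd.Index(geno.samples)
    prob, included, mask = simulate_missingness(
        covariates,
        model.n_items,
        coefficients=missingness_coefficients,
        item_missing_rate=item_missing_rate,
        seed=sub[4],
    )
    items = items_complete.astype(float).where(mask)
    return SyntheticCohort(
        genotypes=geno,
        summary_stats=stats,
        true_prs=true_prs,
        factor_scores=pd.DataFrame(eta, index=geno.samples, columns=model.factor_names),
        items_complete=items_complete,
        items=items,
        covariates=covariates,
        inclusion_probability=prob,
        included=included,
        observed_mask=mask,
        model=model,
    )


def write_items_csv(items: pd.DataFrame, path) -> None:
    """Respondent id + integer categories; empty cell marks missing."""
    out = items.copy()
    out.index.name = "respondent"
    out.to_csv(path, float_format="%.0f")


def write_truth_yaml(model: TrueModel, path) -> None:
    payload = {
        "n_items_per_block": [int(v) for v in model.n_items_per_block],
        "categories_per_block": [int(v) for v in model.categories_per_block],
        "general_loadings": [float(v) for v in model.general_loadings],
        "specific_loadings": [float(v) for v in model.specific_loadings],
        "thresholds": [[float(x) for x in t] for t in model.thresholds],
        "prs_betas": {k: [float(x) for x in v] for k, v in model.prs_betas.items()},
        "seed": int(model.seed),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
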