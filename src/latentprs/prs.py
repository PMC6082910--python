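"""Polygenic risk scores from GWAS summary statistics and target genotypes.

A polygenic risk score (PRS) for one individual is the sum of their risk
allele counts across SNPs passing a discovery P-value threshold, each
weighted by the discovery effect size.  The module handles the standard
bookkeeping that makes this correct in practice: allele harmonisation
between the summary statistics and the counted allele of the genotype
matrix (including strand flips), dropping of strand-ambiguous A/T and C/G
SNPs, mean imputation of sporadically missing genotypes, and
standardisation of the final scores.

:class:`PolygenicScorer` packages the workflow as a scikit-learn style
transformer so that thresholds and harmonisation fitted on one cohort can
be applied to another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GenotypeMatrix",
    "PrsConfig",
    "PolygenicScore",
    "read_summary_stats",
    "select_snps",
    "harmonize_alleles",
    "compute_prs",
    "prs_correlation_report",
    "PolygenicScorer",
]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_DEFAULT_THRESHOLDS = (0.5, 0.05, 1e-5, 5e-8)


@dataclass
class GenotypeMatrix:
    """Respondent x SNP allele counts (dosages) with allele metadata.

    ``dosages[i, j]`` counts copies of ``counted_allele[j]`` carried by
    sample ``i`` (0..2 for hard calls; fractional dosages allowed; NaN for
    missing).
    """

    samples: list
    snp_ids: list
    dosages: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.snp_ids) != m:
            raise ValueError("dosage shape inconsistent with sample/SNP labels")
        self.counted_allele = np.asarray(self.counted_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Sample frequency of the counted allele (missing ignored)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def to_dosage_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.samples, columns=self.snp_ids)
        meta = pd.DataFrame(
            [self.counted_allele, self.other_allele],
            index=["COUNTED", "OTHER"],
            columns=self.snp_ids,
        )
        pd.concat([meta, df]).to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counted = df.loc["COUNTED"].to_numpy(dtype=object)
        other = df.loc["OTHER"].to_numpy(dtype=object)
        body = df.drop(index=["COUNTED", "OTHER"]).astype(float)
        return cls(
            samples=list(body.index),
            snp_ids=list(body.columns),
            dosages=body.to_numpy(),
            counted_allele=counted,
            other_allele=other,
        )

    def to_vcf(self, path) -> None:
        """Write hard-call genotypes as a minimal single-chromosome VCF."""
        g = self.dosages
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(s) for s in self.samples)
                + "\n"
            )
            gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j, snp in enumerate(self.snp_ids):
                calls = [
                    "./." if not np.isfinite(g[i, j]) else gt_map[int(round(g[i, j]))]
                    for i in range(self.n_samples)
                ]
                # ALT is the counted allele so dosage == ALT allele count
                fh.write(
                    f"1\t{j + 1}\t{snp}\t{self.other_allele[j]}\t"
                    f"{self.counted_allele[j]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read GT fields from a VCF; dosage counts the ALT allele."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        ids, ref, alt, rows = [], [], [], []
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            ref.append(var.REF)
            alt.append(var.ALT[0])
            gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,3 hom-alt,2 unknown
            dos = np.where(gt == 3, 2.0, gt)
            dos[gt == 2] = np.nan
            rows.append(dos)
        return cls(
            samples=samples,
            snp_ids=ids,
            dosages=np.array(rows).T,
            counted_allele=np.array(alt, dtype=object),
            other_allele=np.array(ref, dtype=object),
        )


@dataclass
class PrsConfig:
    """Scoring configuration; ``p_thresholds`` mirrors the usual P_T grid."""

    p_thresholds: tuple = _DEFAULT_THRESHOLDS
    gws_alpha: float = 5e-8
    drop_ambiguous: bool = True
    standardize: bool = True

    def __post_init__(self):
        for t in self.p_thresholds:
            if not 0 < t <= 1:
                raise ValueError(f"P-value threshold {t} outside (0, 1]")


@dataclass
class PolygenicScore:
    """Per-respondent raw and standardised scores at one P_T."""

    samples: list
    raw_score: np.ndarray
    z_score: np.ndarray | None
    n_snps_used: int
    threshold: float
    dropped: list = field(default_factory=list)

    def to_series(self, standardized: bool = True) -> pd.Series:
        vals = self.z_score if (standardized and self.z_score is not None) else self.raw_score
        return pd.Series(vals, index=self.samples, name=f"prs_pt_{self.threshold:g}")


class SummaryStatsError(ValueError):
    """Malformed GWAS summary statistics input."""


_CANONICAL_COLS = ("snp_id", "effect_allele", "other_allele", "weight", "p_value")


def read_summary_stats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a delimited GWAS summary-statistics file.

    The file must name the five canonical fields (snp_id, effect_allele,
    other_allele, weight, p_value), directly or through ``column_map``
    (canonical -> file column).  Rows with non-ACGT alleles are dropped
    with a warning; duplicate SNP ids or out-of-range P-values are errors.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _CANONICAL_COLS if c not in df.columns]
    if missing:
        raise SummaryStatsError(f"summary statistics missing columns: {missing}")
    df = df.loc[:, list(_CANONICAL_COLS)].copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    bad = ~(
        df["effect_allele"].isin(_VALID_BASES) & df["other_allele"].isin(_VALID_BASES)
    )
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} summary-stat records with non-ACGT alleles"
        )
        df = df.loc[~bad]
    dup = df["snp_id"].duplicated()
    if dup.any():
        raise SummaryStatsError(
            "duplicate SNP ids in summary statistics: "
            + ", ".join(map(str, df.loc[dup, "snp_id"].unique()[:5]))
        )
    outside = (df["p_value"] <= 0) | (df["p_value"] > 1)
    if outside.any():
        raise SummaryStatsError(
            f"{int(outside.sum())} records have p_value outside (0, 1]"
        )
    return df.reset_index(drop=True)


def select_snps(stats: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Subset summary statistics to SNPs with p <= P_T."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must lie in (0, 1]")
    kept = stats.loc[stats["p_value"] <= p_threshold].reset_index(drop=True)
    if kept.empty:
        warnings.warn(f"no SNPs pass P_T = {p_threshold:g}")
    return kept


@dataclass
class HarmonizedWeights:
    """Per-SNP scoring weights aligned to the genotype counted allele."""

    snp_index: np.ndarray  # column indices into the genotype matrix
    weight: np.ndarray  # discovery weight (unchanged by orientation)
    flipped: np.ndarray  # True where effect allele is the non-counted allele
    dropped: list  # (snp_id, reason) pairs


def harmonize_alleles(
    stats: pd.DataFrame, genotypes: GenotypeMatrix, drop_ambiguous: bool = True
) -> HarmonizedWeights:
    """Align summary-stat effect alleles with the genotype counted allele.

    Effect allele equal to the counted allele contributes ``g * w``;
    equal to the other allele contributes ``(2 - g) * w`` (handled
    downstream through the ``flipped`` mask).  Strand flips are resolved by
    complementing; A/T and C/G SNPs are strand-ambiguous and dropped when
    ``drop_ambiguous``.
    """
    col = {s: j for j, s in enumerate(genotypes.snp_ids)}
    idx, wts, flips, dropped = [], [], [], []
    for rec in stats.itertuples(index=False):
        j = col.get(rec.snp_id)
        if j is None:
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if drop_ambiguous and ea == _COMPLEMENT[oa]:
            dropped.append((rec.snp_id, "strand-ambiguous"))
            continue
        counted = genotypes.counted_allele[j]
        other = genotypes.other_allele[j]
        pair = (ea, oa)
        if pair == (counted, other):
            flip = False
        elif pair == (other, counted):
            flip = True
        elif (_COMPLEMENT[ea], _COMPLEMENT[oa]) == (counted, other):
            flip = False
        elif (_COMPLEMENT[ea], _COMPLEMENT[oa]) == (other, counted):
            flip = True
        else:
            dropped.append((rec.snp_id, "irreconcilable alleles"))
            continue
        idx.append(j)
        wts.append(rec.weight)
        flips.append(flip)
    return HarmonizedWeights(
        snp_index=np.asarray(idx, dtype=int),
        weight=np.asarray(wts, dtype=float),
        flipped=np.asarray(flips, dtype=bool),
        dropped=dropped,
    )


def compute_prs(
    genotypes: GenotypeMatrix,
    harmonized: HarmonizedWeights,
    threshold: float = np.nan,
    standardize: bool = True,
) -> PolygenicScore:
    """Weighted allele sum over harmonised SNPs.

    Raw score for respondent i: sum_j g*_ij w_j with g* the dosage of the
    effect allele (``2 - g`` where orientation is flipped).  Missing
    dosages are mean-imputed (2 x sample allele frequency), which leaves
    the score mean unchanged.
    """
    if harmonized.snp_index.size == 0:
        raise ValueError("no SNPs survived harmonisation; cannot score")
    g = genotypes.dosages[:, harmonized.snp_index]
    freq_fill = np.nanmean(g, axis=0) if np.isnan(g).any() else None
    if freq_fill is not None:
        g = np.where(np.isnan(g), freq_fill[None, :], g)
    g_eff = np.where(harmonized.flipped[None, :], 2.0 - g, g)
    raw = g_eff @ harmonized.weight
    z = None
    if standardize:
        sd = raw.std()
        if sd < 1e-12:
            raise ValueError("scores are constant; cannot standardise")
        z = (raw - raw.mean()) / sd
    return PolygenicScore(
        samples=list(genotypes.samples),
        raw_score=raw,
        z_score=z,
        n_snps_used=int(harmonized.snp_index.size),
        threshold=threshold,
        dropped=list(harmonized.dropped),
    )


def prs_correlation_report(scores: list[PolygenicScore] | dict) -> pd.DataFrame:
    """Pearson correlations among score sets over their respondent overlap."""
    if isinstance(scores, dict):
        named = scores.items()
    else:
        named = ((f"prs_pt_{s.threshold:g}", s) for s in scores)
    series = {name: s.to_series() for name, s in named}
    if len(series) < 2:
        raise ValueError("need at least two score sets to correlate")
    df = pd.DataFrame(series).dropna()
    if len(df) < 2:
        raise ValueError("fewer than 2 overlapping respondents across score sets")
    return df.corr()


class PolygenicScorer(TransformerMixin, BaseEstimator):
    """Scikit-learn style PRS transformer.

    Parameters
    ----------
    sumstats : DataFrame
        Validated summary statistics (see :func:`read_summary_stats`).
    p_threshold : float
        Discovery P-value threshold P_T for SNP inclusion.
    gws_alpha : float
        Genome-wide significance level (kept overridable because some
        discovery studies use stricter conventions).
    drop_ambiguous, standardize : bool
        Harmonisation / output options as in the functional API.
    """

    def __init__(
        self,
        sumstats=None,
        p_threshold: float = 0.05,
        gws_alpha: float = 5e-8,
        drop_ambiguous: bool = True,
        standardize: bool = True,
    ):
        self.sumstats = sumstats
        self.p_threshold = p_threshold
        self.gws_alpha = gws_alpha
        self.drop_ambiguous = drop_ambiguous
        self.standardize = standardize

    def fit(self, X: GenotypeMatrix, y=None):
        if self.sumstats is None:
            raise ValueError("PolygenicScorer requires sumstats")
        selected = select_snps(self.sumstats, self.p_threshold)
        self.harmonized_ = harmonize_alleles(
            selected, X, drop_ambiguous=self.drop_ambiguous
        )
        score = compute_prs(
            X, self.harmonized_, threshold=self.p_threshold, standardize=False
        )
        self.n_snps_used_ = score.n_snps_used
        self.raw_mean_ = float(score.raw_score.mean())
        self.raw_sd_ = float(score.raw_score.std())
        return self

    def transform(self, X: GenotypeMatrix) -> np.ndarray:
        score = compute_prs(
            X, self.harmonized_, threshold=self.p_threshold, standardize=False
        )
        if not self.standardize:
            return score.raw_score[:, None]
        if self.raw_sd_ < 1e-12:
            raise ValueError("fitted scores are constant; cannot standardise")
        return ((score.raw_score - self.raw_mean_) / self.raw_sd_)[:, None]

    def score_set(self, X: GenotypeMatrix) -> PolygenicScore:
        """Full :class:`PolygenicScore` record for a genotype matrix."""
        return compute_prs(
            X, self.harmonized_, threshold=self.p_threshold, standardize=self.standardize
        )
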