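import io

import numpy as np
import pandas as pd
import pytest

from latentprs.prs import (
    GenotypeMatrix,
    PolygenicScorer,
    PrsConfig,
    compute_prs,
    harmonize_alleles,
    prs_correlation_report,
    read_summary_stats,
    select_snps,
)
from latentprs.simulate import simulate_genotypes, simulate_summary_stats


def make_sumstats(rows):
    cols = ["snp_id", "effect_allele", "other_allele", "weight", "p_value"]
    return pd.DataFrame(rows, columns=cols)


def write_tsv(df, tmp_path, name="ss.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadSummaryStats:
    def test_toy_file(self, tmp_path):
        path = write_tsv(
            make_sumstats(
                [
                    ("rs1", "A", "G", 0.1, 0.01),
                    ("rs2", "C", "T", -0.2, 0.5),
                    ("rs3", "G", "A", 0.05, 1e-6),
                ]
            ),
            tmp_path,
        )
        stats = read_summary_stats(path)
        assert len(stats) == 3

    def test_duplicate_snp_rejected(self, tmp_path):
        path = write_tsv(
            make_sumstats([("rs1", "A", "G", 0.1, 0.1), ("rs1", "C", "T", 0.2, 0.2)]),
            tmp_path,
        )
        with pytest.raises(ValueError, match="rs1"):
            read_summary_stats(path)

    def test_zero_pvalue_rejected(self, tmp_path):
        path = write_tsv(make_sumstats([("rs1", "A", "G", 0.1, 0.0)]), tmp_path)
        with pytest.raises(ValueError, match="p_value"):
            read_summary_stats(path)

    def test_missing_column(self, tmp_path):
        df = make_sumstats([("rs1", "A", "G", 0.1, 0.1)]).drop(columns="weight")
        with pytest.raises(ValueError, match="weight"):
            read_summary_stats(write_tsv(df, tmp_path))

    def test_non_acgt_dropped_with_warning(self, tmp_path):
        path = write_tsv(
            make_sumstats([("rs1", "A", "G", 0.1, 0.1), ("rs2", "I", "D", 0.2, 0.2)]),
            tmp_path,
        )
        with pytest.warns(UserWarning, match="non-ACGT"):
            stats = read_summary_stats(path)
        assert stats["snp_id"].tolist() == ["rs1"]

    def test_column_map(self, tmp_path):
        df = make_sumstats([("rs1", "A", "G", 0.1, 0.1)]).rename(
            columns={"snp_id": "SNP", "p_value": "P"}
        )
        path = write_tsv(df, tmp_path)
        stats = read_summary_stats(path, column_map={"snp_id": "SNP", "p_value": "P"})
        assert stats.loc[0, "snp_id"] == "rs1"


class TestSelectSnps:
    def test_threshold_filters(self):
        stats = make_sumstats(
            [("rs1", "A", "G", 0.1, 0.01), ("rs2", "C", "T", 0.2, 0.2)]
        )
        assert len(select_snps(stats, 0.05)) == 1
        assert len(select_snps(stats, 1.0)) == 2

    def test_empty_result_warns_not_raises(self):
        stats = make_sumstats([("rs1", "A", "G", 0.1, 0.9)])
        with pytest.warns(UserWarning, match="no SNPs"):
            out = select_snps(stats, 1e-8)
        assert out.empty

    def test_gws_default_overridable(self):
        cfg = PrsConfig()
        assert cfg.gws_alpha == 5e-8
        assert PrsConfig(gws_alpha=1e-8).gws_alpha == 1e-8


def toy_genotypes():
    return GenotypeMatrix(
        samples=["s1", "s2", "s3"],
        snp_ids=["rs1", "rs2", "rs3", "rs4"],
        dosages=np.array(
            [[0, 1, 2, 1], [1, 0, 1, 2], [2, 2, 0, 0]], dtype=float
        ),
        counted_allele=np.array(list("AGCA"), dtype=object),
        other_allele=np.array(list("GATT"), dtype=object),
    )


class TestHarmonize:
    def test_direct_and_swapped_orientation(self):
        geno = toy_genotypes()
        stats = make_sumstats(
            [
                ("rs1", "A", "G", 0.1, 0.01),  # effect = counted
                ("rs2", "A", "G", 0.2, 0.01),  # effect = other -> flipped
            ]
        )
        h = harmonize_alleles(stats, geno)
        assert h.flipped.tolist() == [False, True]

    def test_strand_flip_resolved_by_complement(self):
        geno = toy_genotypes()
        stats = make_sumstats([("rs3", "G", "A", 0.3, 0.01)])
        # rs3 is counted C / other T; complement of (G, A) is (C, T)
        h = harmonize_alleles(stats, geno)
        assert h.snp_index.tolist() == [2] and not h.flipped[0]

    def test_ambiguous_snp_dropped_and_logged(self):
        geno = toy_genotypes()
        stats = make_sumstats([("rs4", "A", "T", 0.4, 0.01)])
        h = harmonize_alleles(stats, geno)
        assert h.snp_index.size == 0
        assert h.dropped == [("rs4", "strand-ambiguous")]
        kept = harmonize_alleles(stats, geno, drop_ambiguous=False)
        assert kept.snp_index.tolist() == [3]

    def test_irreconcilable_dropped(self):
        geno = toy_genotypes()
        stats = make_sumstats([("rs1", "A", "C", 0.1, 0.01)])
        h = harmonize_alleles(stats, geno)
        assert h.dropped == [("rs1", "irreconcilable alleles")]


class TestComputePrs:
    def test_hand_summed_raw_score(self):
        geno = GenotypeMatrix(
            samples=["s1"],
            snp_ids=["rs1", "rs2", "rs3"],
            dosages=np.array([[0.0, 1.0, 2.0]]),
            counted_allele=np.array(list("AAA"), dtype=object),
            other_allele=np.array(list("GGG"), dtype=object),
        )
        stats = make_sumstats(
            [
                ("rs1", "A", "G", 0.1, 0.01),
                ("rs2", "A", "G", -0.2, 0.01),
                ("rs3", "A", "G", 0.3, 0.01),
            ]
        )
        score = compute_prs(geno, harmonize_alleles(stats, geno), standardize=False)
        assert score.raw_score[0] == pytest.approx(0.4)

    def test_zero_weights_refuse_standardization(self):
        geno = toy_genotypes()
        stats = make_sumstats([("rs1", "A", "G", 0.0, 0.01)])
        with pytest.raises(ValueError, match="constant"):
            compute_prs(geno, harmonize_alleles(stats, geno))

    def test_brute_force_oracle_equivalence(self):
        """Vectorised scoring equals a per-respondent per-SNP double loop."""
        geno = simulate_genotypes(100, 200, seed=30)
        stats = simulate_summary_stats(geno, seed=31)
        # flip some orientations and inject an ambiguous SNP
        stats.loc[::3, ["effect_allele", "other_allele"]] = stats.loc[
            ::3, ["other_allele", "effect_allele"]
        ].to_numpy()
        stats.loc[5, ["effect_allele", "other_allele"]] = ["A", "T"]
        h = harmonize_alleles(stats, geno)
        score = compute_prs(geno, h, standardize=False)
        expected = np.zeros(geno.n_samples)
        for i in range(geno.n_samples):
            for t, j in enumerate(h.snp_index):
                g = geno.dosages[i, j]
                g = 2 - g if h.flipped[t] else g
                expected[i] += g * h.weight[t]
        assert score.raw_score == pytest.approx(expected.tolist(), abs=1e-10)

    def test_orientation_flip_invariance(self):
        """Recoding a SNP's counted allele leaves every raw score unchanged."""
        geno = simulate_genotypes(50, 20, seed=32)
        stats = simulate_summary_stats(geno, seed=33)
        base = compute_prs(geno, harmonize_alleles(stats, geno), standardize=False)
        flipped = GenotypeMatrix(
            samples=geno.samples,
            snp_ids=geno.snp_ids,
            dosages=2.0 - geno.dosages,
            counted_allele=geno.other_allele,
            other_allele=geno.counted_allele,
        )
        alt = compute_prs(flipped, harmonize_alleles(stats, flipped), standardize=False)
        assert base.raw_score == pytest.approx(alt.raw_score.tolist(), abs=1e-12)

    def test_linearity_in_weights(self):
        geno = simulate_genotypes(40, 15, seed=34)
        stats = simulate_summary_stats(geno, seed=35)
        h = harmonize_alleles(stats, geno)
        import copy

        h1 = copy.deepcopy(h)
        h1.weight = h.weight * 0.25
        h2 = copy.deepcopy(h)
        h2.weight = h.weight * 0.75
        total = compute_prs(geno, h, standardize=False).raw_score
        parts = (
            compute_prs(geno, h1, standardize=False).raw_score
            + compute_prs(geno, h2, standardize=False).raw_score
        )
        assert total == pytest.approx(parts.tolist(), abs=1e-10)

    def test_standardized_moments(self):
        geno = simulate_genotypes(500, 100, seed=36)
        stats = simulate_summary_stats(geno, seed=37)
        score = compute_prs(geno, harmonize_alleles(stats, geno))
        assert abs(score.z_score.mean()) < 1e-10
        assert score.z_score.std() == pytest.approx(1.0, abs=1e-10)

    def test_missing_dosage_mean_imputed(self):
        geno = simulate_genotypes(200, 10, seed=38)
        stats = simulate_summary_stats(geno, seed=39)
        h = harmonize_alleles(stats, geno)
        full = compute_prs(geno, h, standardize=False).raw_score
        geno.dosages[0, 0] = np.nan
        imputed = compute_prs(geno, h, standardize=False).raw_score
        assert imputed[1:] == pytest.approx(full[1:].tolist())


class TestCorrelationReport:
    def test_self_correlation_and_anticorrelation(self):
        geno = simulate_genotypes(300, 50, seed=40)
        stats = simulate_summary_stats(geno, seed=41)
        h = harmonize_alleles(stats, geno)
        s1 = compute_prs(geno, h, threshold=0.5)
        import copy

        h2 = copy.deepcopy(h)
        h2.weight = -h.weight
        s2 = compute_prs(geno, h2, threshold=0.05)
        corr = prs_correlation_report({"a": s1, "b": s1, "c": s2})
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_independent_traits_weakly_correlated(self):
        geno = simulate_genotypes(4000, 150, seed=42)
        scores = {}
        for k in (0, 1):
            stats = simulate_summary_stats(geno, seed=50 + k)
            scores[f"t{k}"] = compute_prs(geno, harmonize_alleles(stats, geno))
        corr = prs_correlation_report(scores)
        assert abs(corr.loc["t0", "t1"]) < 0.1

    def test_requires_two_sets(self):
        geno = simulate_genotypes(30, 10, seed=43)
        stats = simulate_summary_stats(geno, seed=44)
        s = compute_prs(geno, harmonize_alleles(stats, geno))
        with pytest.raises(ValueError, match="two score sets"):
            prs_correlation_report({"only": s})


class TestPolygenicScorer:
    def test_sklearn_roundtrip(self):
        geno = simulate_genotypes(250, 80, seed=45)
        stats = simulate_summary_stats(geno, seed=46)
        scorer = PolygenicScorer(sumstats=stats, p_threshold=0.5)
        z = scorer.fit_transform(geno)
        assert z.shape == (250, 1)
        assert abs(z.mean()) < 1e-10
        params = scorer.get_params()
        assert params["p_threshold"] == 0.5
        clone_z = (
            PolygenicScorer(**params).fit(geno).transform(geno)
        )
        assert np.allclose(z, clone_z)
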