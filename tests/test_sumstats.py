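"""Summary-statistics I/O, harmonization and genomic inflation."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xtrait import (genomic_lambda, harmonize_pair, lambda_1000, ld_matrix,
                    read_sumstats, write_sumstats)
from xtrait.sumstats import COLUMNS, validate_sumstats

from conftest import make_table


class TestReadWrite:
    def test_or_dialect_converts_to_log_scale(self, tmp_path):
        path = tmp_path / "or.tsv"
        pd.DataFrame({
            "SNP": ["rs7960611"], "CHR": ["12"], "BP": [10230416],
            "EA": ["G"], "OA": ["A"], "EAF": [0.3],
            "OR": [1.14], "L95": [1.09], "U95": [1.19], "P": [8.02e-9],
        }).to_csv(path, sep="\t", index=False)
        df = read_sumstats(path, dialect={
            "snp_id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "EA",
            "a2": "OA", "freq_a1": "EAF", "p": "P",
            "or": "OR", "ci_low": "L95", "ci_high": "U95"})
        assert df["beta"].iloc[0] == pytest.approx(np.log(1.14))
        expect_se = (np.log(1.19) - np.log(1.09)) / (2 * 1.959964)
        assert df["se"].iloc[0] == pytest.approx(expect_se)

    def test_round_trip_preserves_table(self, tmp_path, rng):
        df = make_table([{"beta": b} for b in rng.normal(0, 0.1, 10)])
        path = tmp_path / "t.tsv"
        write_sumstats(df, path)
        back = read_sumstats(path)
        pd.testing.assert_frame_equal(back, df, check_dtype=False)
        assert back.attrs["n_dropped"] == 0

    def test_invalid_rows_dropped_and_counted(self):
        df = make_table([
            {}, {"se": 0.0}, {"freq_a1": 1.2}, {"a1": "A", "a2": "A"},
            {"p": 0.0},
        ])
        out, n_dropped = validate_sumstats(df)
        assert len(out) == 1 and n_dropped == 4

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        make_table([{}]).drop(columns=["pos"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="pos"):
            read_sumstats(path)


class TestHarmonize:
    def test_allele_swap_negates_beta_and_flips_freq(self):
        t1 = make_table([{"a1": "G", "a2": "A", "beta": 0.10}])
        t2 = make_table([{"a1": "A", "a2": "G", "beta": -0.10, "freq_a1": 0.7}])
        pair = harmonize_pair(t1, t2)
        assert pair.records_2["beta"].iloc[0] == pytest.approx(0.10)
        assert pair.records_2["freq_a1"].iloc[0] == pytest.approx(0.3)
        assert pair.report.n_flipped == 1
        assert (pair.records_2[["a1", "a2"]].iloc[0] == ["G", "A"]).all()

    def test_strand_complement_preserves_sign(self):
        t1 = make_table([{"a1": "C", "a2": "T", "beta": 0.08}])
        t2 = make_table([{"a1": "G", "a2": "A", "beta": 0.05, "freq_a1": 0.3}])
        pair = harmonize_pair(t1, t2)
        assert pair.records_2["beta"].iloc[0] == pytest.approx(0.05)
        assert pair.report.n_strand_flipped == 1

    def test_palindromic_near_half_dropped_as_ambiguous(self):
        t1 = make_table([{"a1": "A", "a2": "T", "freq_a1": 0.49},
                         {"pos": 99_000}])
        t2 = make_table([{"a1": "A", "a2": "T", "freq_a1": 0.49},
                         {"pos": 99_000}])
        pair = harmonize_pair(t1, t2, ambiguity_maf_bound=0.40)
        assert pair.report.n_ambiguous_dropped == 1
        assert pair.report.n_shared == 1

    def test_palindromic_low_maf_oriented_by_frequency(self):
        t1 = make_table([{"a1": "A", "a2": "T", "freq_a1": 0.1, "beta": 0.2}])
        t2 = make_table([{"a1": "A", "a2": "T", "freq_a1": 0.9, "beta": -0.2}])
        pair = harmonize_pair(t1, t2)
        assert pair.records_2["beta"].iloc[0] == pytest.approx(0.2)
        assert pair.records_2["freq_a1"].iloc[0] == pytest.approx(0.1)

    def test_allele_mismatch_dropped(self):
        t1 = make_table([{"a1": "A", "a2": "G"}, {"pos": 99_000}])
        t2 = make_table([{"a1": "A", "a2": "C"}, {"pos": 99_000}])
        pair = harmonize_pair(t1, t2)
        assert pair.report.n_mismatch_dropped == 1

    def test_empty_intersection_is_hard_error(self):
        t1 = make_table([{"pos": 1000}])
        t2 = make_table([{"pos": 2000, "snp_id": "other"}])
        with pytest.raises(ValueError, match="intersection"):
            harmonize_pair(t1, t2)

    def test_idempotent(self, rng):
        t1 = make_table([{"beta": b, "pos": 1000 * i + 500}
                         for i, b in enumerate(rng.normal(0, 0.1, 8))])
        t2 = make_table([{"a1": "G", "a2": "A", "beta": -b,
                          "freq_a1": 0.7, "pos": 1000 * i + 500}
                         for i, b in enumerate(rng.normal(0, 0.1, 8))])
        once = harmonize_pair(t1, t2)
        twice = harmonize_pair(once.records_1, once.records_2)
        pd.testing.assert_frame_equal(once.records_2, twice.records_2)
        assert twice.report.n_flipped == 0

    def test_sign_equivariance(self):
        t1 = make_table([{"beta": 0.1}, {"pos": 99_000, "beta": -0.2}])
        t2 = make_table([{"a1": "G", "a2": "A", "beta": 0.15, "freq_a1": 0.7},
                         {"pos": 99_000, "beta": 0.05}])
        direct = harmonize_pair(t1, t2).records_2["beta"].to_numpy()
        t2_neg = t2.assign(beta=-t2["beta"])
        negated = harmonize_pair(t1, t2_neg).records_2["beta"].to_numpy()
        np.testing.assert_allclose(direct, -negated)

    def test_snp_id_fallback_matches_relocated_snp(self):
        t1 = make_table([{"snp_id": "rsX", "pos": 1000}])
        t2 = make_table([{"snp_id": "rsX", "pos": 1100}])
        pair = harmonize_pair(t1, t2)
        assert pair.report.n_shared == 1


class TestGenomicLambda:
    def test_null_uniform_p_values(self, rng):
        p = rng.uniform(0, 1, 1_000_000)
        p = p[p > 0]
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.01)

    def test_median_p_gives_unity(self):
        assert genomic_lambda([0.5] * 11) == pytest.approx(1.0)

    def test_inflated_scores_recover_scale(self, rng):
        z = rng.standard_normal(500_000) * np.sqrt(1.1)
        p = 2 * stats.norm.sf(np.abs(z))
        assert genomic_lambda(p) == pytest.approx(1.1, abs=0.02)

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            genomic_lambda([])

    @pytest.mark.parametrize("lam, nca, nco, expect", [
        (1.0, 123, 456, 1.0),
        (1.1, 1000, 1000, 1.1),
        (1.2, 2000, 2000, 1.1),
    ])
    def test_lambda_1000_rescaling(self, lam, nca, nco, expect):
        assert lambda_1000(lam, nca, nco) == pytest.approx(expect)


class TestLdMatrix:
    def test_perfectly_correlated_columns(self):
        x = np.arange(10, dtype=float) % 3
        ref = ld_matrix(np.column_stack([x, x]))
        assert ref.R[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_pearson_bruteforce(self, rng):
        X = rng.integers(0, 3, size=(40, 8)).astype(float)
        ref = ld_matrix(X)
        for i in range(8):
            for j in range(i + 1, 8):
                expect = np.corrcoef(X[:, i], X[:, j])[0, 1]
                assert ref.R[i, j] == pytest.approx(expect, abs=1e-12)

    def test_independent_columns_have_small_r(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.3, size=(500, 6)).astype(float)
        ref = ld_matrix(X)
        off = ref.R[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.15

    def test_zero_variance_column_flagged_and_zeroed(self):
        X = np.column_stack([np.ones(10), np.arange(10) % 3]).astype(float)
        ref = ld_matrix(X)
        assert ref.zero_variance[0]
        assert ref.R[0, 1] == 0.0 and ref.R[0, 0] == 1.0

    def test_sample_duplication_invariance(self, rng):
        X = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
        r1 = ld_matrix(X).R
        r2 = ld_matrix(np.vstack([X, X])).R
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_missing_dosages_mean_imputed(self, rng):
        X = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        Xm = X.copy()
        Xm[0, 0] = np.nan
        ref = ld_matrix(Xm)
        assert np.all(np.isfinite(ref.R))
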