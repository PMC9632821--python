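"""The synthetic two-trait generator: LD blocks, summary-level and
individual-level routes, and their mutual consistency."""

import numpy as np
import pytest
from scipy import stats

from xtrait.simulate import (ArchitectureSpec, assign_architecture,
                             ar1_matrix, make_ld_blocks, simulate_individual,
                             simulate_sumstats, true_effects)


def null_spec(m=20, rho=0.5, seed=0, **kw):
    return ArchitectureSpec(blocks=[(m, rho)],
                            causal_assignments=["none"] * m,
                            effect_scale=(0.1, 0.1), n1=5000, n2=5000,
                            seed=seed, **kw)


class TestLdBlocks:
    def test_ar1_closed_form(self):
        spec = null_spec(m=3, rho=0.5)
        R = make_ld_blocks(spec).blocks[0].R
        np.testing.assert_allclose(R[0], [1.0, 0.5, 0.25])

    def test_zero_rho_gives_identity(self):
        R = make_ld_blocks(null_spec(m=4, rho=0.0)).blocks[0].R
        np.testing.assert_allclose(R, np.eye(4))

    def test_cross_block_entries_absent(self):
        spec = ArchitectureSpec(blocks=[(3, 0.5), (3, 0.8)],
                                causal_assignments=["none"] * 6,
                                effect_scale=(0.1, 0.1), n1=100, n2=100)
        panel = make_ld_blocks(spec)
        assert len(panel.blocks) == 2
        locus = panel.locus("1", 0, 10 ** 9)
        np.testing.assert_allclose(locus.R[:3, 3:], 0.0)

    def test_frequencies_within_range_and_deterministic(self):
        p1 = make_ld_blocks(null_spec(seed=5, maf_range=(0.1, 0.4)))
        p2 = make_ld_blocks(null_spec(seed=5, maf_range=(0.1, 0.4)))
        assert np.all((p1.freqs >= 0.1) & (p1.freqs <= 0.4))
        np.testing.assert_array_equal(p1.freqs, p2.freqs)


class TestArchitecture:
    def test_label_counts(self):
        labels = assign_architecture(100, 10, 5, 3, 2, seed=1)
        counts = {lab: int((labels == lab).sum()) for lab in set(labels)}
        assert counts["shared_aligned"] == 10
        assert counts["shared_opposing"] == 5
        assert counts["none"] == 80

    def test_planted_genetic_correlation_is_exact(self):
        labels = assign_architecture(1000, 56, 0, 44, 44, seed=2)
        spec = ArchitectureSpec(blocks=[(1000, 0.0)], causal_assignments=labels,
                                effect_scale=(0.05, 0.05), n1=100, n2=100, seed=2)
        b1, b2 = true_effects(spec)
        rg = (b1 @ b2) / np.sqrt((b1 @ b1) * (b2 @ b2))
        assert rg == pytest.approx(0.56)

    def test_opposing_labels_reverse_sign(self):
        labels = np.array(["shared_opposing"] * 5 + ["none"] * 5)
        spec = ArchitectureSpec(blocks=[(10, 0.0)], causal_assignments=labels,
                                effect_scale=(0.1, 0.1), n1=100, n2=100)
        b1, b2 = true_effects(spec)
        np.testing.assert_allclose(b2[:5], -b1[:5])

    def test_overlap_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(blocks=[(5, 0.0)], causal_assignments=["none"] * 5,
                             effect_scale=(0.1, 0.1), n1=10, n2=100, n_overlap=50)


class TestSumstatsRoute:
    def test_fixed_seed_reproduces_byte_identical_tables(self):
        a = simulate_sumstats(null_spec(seed=9)).sumstats_1.to_csv()
        b = simulate_sumstats(null_spec(seed=9)).sumstats_1.to_csv()
        assert a == b

    def test_null_calibration_over_replicates(self):
        zs1, zs2 = [], []
        for rep in range(500):
            co = simulate_sumstats(null_spec(seed=rep))
            zs1.append(co.sumstats_1["beta"] / co.sumstats_1["se"])
            zs2.append(co.sumstats_2["beta"] / co.sumstats_2["se"])
        z1 = np.array(zs1)
        z2 = np.array(zs2)
        assert abs(z1.mean()) < 0.02
        assert z1.var() == pytest.approx(1.0, abs=0.05)
        cross = np.mean([np.corrcoef(a, b)[0, 1] for a, b in zip(zs1, zs2)])
        assert abs(cross) < 0.05

    def test_single_causal_mean_matches_mvn_formula(self):
        m = 10
        labels = np.array(["none"] * m, dtype=object)
        labels[4] = "trait1_only"
        acc = np.zeros(m)
        n_rep = 1000
        for rep in range(n_rep):
            spec = ArchitectureSpec(blocks=[(m, 0.6)], causal_assignments=labels,
                                    effect_scale=(0.1, 0.0), n1=2000, n2=100,
                                    seed=rep)
            co = simulate_sumstats(spec)
            sign = np.sign(true_effects(spec)[0][4])
            acc += sign * co.sumstats_1["beta"] / co.sumstats_1["se"]
        mean_z = acc / n_rep
        R = ar1_matrix(m, 0.6)
        expect = np.sqrt(2000) * R[:, 4] * 0.1
        np.testing.assert_allclose(mean_z, expect, atol=4 / np.sqrt(n_rep))

    def test_overlap_induces_cross_trait_noise_correlation(self):
        spec = null_spec(m=200, rho=0.0, n_overlap=2500, pheno_corr=0.8)
        cross = []
        for rep in range(100):
            spec = null_spec(m=200, rho=0.0, seed=rep,
                             n_overlap=2500, pheno_corr=0.8)
            co = simulate_sumstats(spec)
            z1 = co.sumstats_1["beta"] / co.sumstats_1["se"]
            z2 = co.sumstats_2["beta"] / co.sumstats_2["se"]
            cross.append(np.corrcoef(z1, z2)[0, 1])
        # expected correlation: n_overlap * pheno_corr / sqrt(n1 n2) = 0.4
        assert np.mean(cross) == pytest.approx(0.4, abs=0.05)

    def test_impossible_overlap_covariance_rejected(self):
        spec = null_spec(n_overlap=5000, pheno_corr=1.0)
        with pytest.raises(ValueError, match="overlap"):
            simulate_sumstats(spec)


class TestIndividualRoute:
    def test_dosage_correlation_tracks_target(self):
        spec = null_spec(m=20, rho=0.6, seed=3)
        spec = ArchitectureSpec(blocks=[(20, 0.6)],
                                causal_assignments=["none"] * 20,
                                effect_scale=(0.1, 0.1), n1=2000, n2=100, seed=3)
        co = simulate_individual(spec)
        emp = np.corrcoef(co.genotypes["X1"].T)
        target = ar1_matrix(20, 0.6)
        assert np.max(np.abs(emp - target)) < 0.1

    def test_null_p_values_uniform(self):
        passed = 0
        for rep in range(20):
            spec = ArchitectureSpec(blocks=[(30, 0.0)],
                                    causal_assignments=["none"] * 30,
                                    effect_scale=(0.1, 0.1), n1=500, n2=100,
                                    seed=100 + rep)
            co = simulate_individual(spec)
            ks = stats.kstest(co.sumstats_1["p"], "uniform")
            passed += ks.pvalue > 0.01
        assert passed >= 17

    def test_same_seed_same_genotypes(self):
        spec = null_spec(m=5, seed=7)
        a = simulate_individual(spec).genotypes["X1"]
        b = simulate_individual(spec).genotypes["X1"]
        np.testing.assert_array_equal(a, b)

    def test_sample_cap_enforced(self):
        spec = null_spec(seed=0)
        spec.n1 = 10_000
        with pytest.raises(ValueError, match="5,000"):
            simulate_individual(spec)

    def test_routes_agree_on_z_moments(self):
        """Individual-level z-scores have the mean/variance the
        summary-level MVN model draws from (moment matching)."""
        m = 10
        labels = np.array(["none"] * m, dtype=object)
        labels[3] = "trait1_only"
        acc = np.zeros(m)
        acc_var = np.zeros(m)
        n_rep = 500
        for rep in range(n_rep):
            spec = ArchitectureSpec(blocks=[(m, 0.5)], causal_assignments=labels,
                                    effect_scale=(0.1, 0.0), n1=1000, n2=100,
                                    seed=300 + rep)
            co = simulate_individual(spec)
            sign = np.sign(true_effects(spec)[0][3])
            z = (co.sumstats_1["beta"] / co.sumstats_1["se"]).to_numpy()
            acc += sign * z
            acc_var += z ** 2
        mean_z = acc / n_rep
        var_z = acc_var / n_rep - mean_z ** 2
        expect = np.sqrt(1000) * ar1_matrix(m, 0.5)[:, 3] * 0.1
        # copula discretization attenuates LD slightly; allow 10% + MC error
        np.testing.assert_allclose(mean_z, expect,
                                   atol=3.5 / np.sqrt(n_rep) + 0.1 * np.abs(expect).max())
        np.testing.assert_allclose(var_z, 1.0, atol=0.25)


def test_downstream_type_i_error_nominal():
    """Per-SNP two-sided tests on null architecture reject at the nominal
    5% rate (10,000 independent SNP draws)."""
    spec = ArchitectureSpec(blocks=[(100, 0.0)] * 100,
                            causal_assignments=["none"] * 10_000,
                            effect_scale=(0.1, 0.1), n1=5000, n2=5000, seed=11)
    co = simulate_sumstats(spec)
    rate = float((co.sumstats_1["p"] < 0.05).mean())
    assert 0.04 <= rate <= 0.06
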