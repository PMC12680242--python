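import numpy as np
import pytest

from attrbench.errors import SpecError
from attrbench.spikein import (
    SpikeInConstraints,
    build_spikein_set,
    discretize_hwe,
    gen_additive,
    gen_dominant,
    gen_epistatic_pair,
    gen_recessive,
    sample_latent,
)


class TestSampleLatent:
    def test_rho_zero_independence(self, std_phenotype):
        z = sample_latent(std_phenotype, 0.0, seed=1)
        n = len(std_phenotype)
        assert abs(np.corrcoef(z, std_phenotype)[0, 1]) < 3 / np.sqrt(n)

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_boundary_rejected(self, std_phenotype, rho):
        with pytest.raises(ValueError):
            sample_latent(std_phenotype, rho)

    def test_realized_correlation(self):
        # Fisher-z SE oracle: SE(r) ~ 1/sqrt(n) for small rho
        n, rho = 240_000, 0.05
        y = np.random.default_rng(0).standard_normal(n)
        y = (y - y.mean()) / y.std()
        z = sample_latent(y, rho, seed=2)
        assert abs(np.corrcoef(z, y)[0, 1] - rho) < 3 / np.sqrt(n)


class TestDiscretizeHwe:
    def test_hwe_counts(self):
        z = np.random.default_rng(1).standard_normal(10_000)
        g = discretize_hwe(z, 0.1)
        counts = np.bincount(g, minlength=3)
        assert tuple(counts) == (8100, 1800, 100)

    def test_symmetric_at_half(self):
        n = 8000
        z = np.random.default_rng(2).standard_normal(n)
        g = discretize_hwe(z, 0.5)
        counts = np.bincount(g, minlength=3)
        assert tuple(counts) == (n // 4, n // 2, n // 4)

    def test_counts_depend_only_on_ranks(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(5000)
        g1 = np.bincount(discretize_hwe(z, 0.17), minlength=3)
        g2 = np.bincount(discretize_hwe(rng.permutation(z), 0.17), minlength=3)
        assert np.array_equal(g1, g2)

    def test_constant_latent_rejected(self):
        with pytest.raises(ValueError):
            discretize_hwe(np.ones(100), 0.1)

    def test_upper_tail_maps_to_two(self):
        z = np.arange(100, dtype=float)
        g = discretize_hwe(z, 0.2)
        assert g[-1] == 2 and g[0] == 0


class TestAdditive:
    def test_positive_monotone_means(self, std_phenotype):
        g, d = gen_additive(std_phenotype, 0.07, 0.2, seed=1)
        assert d["realized_r"] > 0
        assert d["m0"] < d["m1"] < d["m2"]

    def test_null_rho_equal_means(self, std_phenotype):
        g, d = gen_additive(std_phenotype, 0.0, 0.2, seed=2)
        se = 3 / np.sqrt(len(std_phenotype) * 0.3)
        assert abs(d["m0"] - d["m2"]) < 2 * se

    def test_negative_sign_symmetry(self, std_phenotype):
        g, d = gen_additive(std_phenotype, -0.07, 0.2, seed=3)
        assert d["realized_r"] < 0
        assert d["m0"] > d["m1"] > d["m2"]


class TestDominant:
    def test_carrier_fraction_arithmetic(self, std_phenotype):
        # p(2-p) oracle: p=0.06 -> 0.1164
        assert abs(0.06 * (2 - 0.06) - 0.1164) < 1e-12
        g, d = gen_dominant(std_phenotype, 0.05, 0.06, seed=1)
        assert 0.10 <= d["carrier_fraction"] <= 0.14

    def test_infeasible_maf_rejected(self, std_phenotype):
        with pytest.raises(SpecError):
            gen_dominant(std_phenotype, 0.05, 0.20, seed=2)  # carrier fraction 0.36

    def test_null_rho_equal_means(self, std_phenotype):
        g, d = gen_dominant(std_phenotype, 0.0, 0.06, seed=3)
        assert abs(d["m1"] - d["m0"]) < 0.05

    def test_dominance_pattern(self, std_phenotype):
        # m1 ~= m2 > m0 for positive sign
        g, d = gen_dominant(std_phenotype, 0.30, 0.06, seed=4)
        assert abs(d["m1"] - d["m2"]) < abs(d["m1"] - d["m0"])
        assert d["m1"] > d["m0"]


class TestRecessive:
    def test_boundary_maf_accepted(self, std_phenotype):
        p = np.sqrt(1200.0 / 240_000)  # exact feasibility floor
        g, d = gen_recessive(std_phenotype, 0.05, p, seed=1)
        assert d["homalt_count"] > 0

    def test_low_maf_rejected(self, std_phenotype):
        with pytest.raises(SpecError, match="floor"):
            gen_recessive(std_phenotype, 0.05, 0.05, seed=2)  # 240000*0.05^2 = 600 < 1200

    def test_null_rho_equal_means(self, std_phenotype):
        g, d = gen_recessive(std_phenotype, 0.0, 0.15, seed=3)
        assert abs(d["m0"] - d["m1"]) < 0.05
        assert abs(d["m1"] - d["m2"]) < 0.2

    def test_recessive_pattern(self, std_phenotype):
        g, d = gen_recessive(std_phenotype, 0.06, 0.15, seed=4)
        assert abs(d["m0"] - d["m1"]) < abs(d["m2"] - d["m1"])
        assert d["m2"] > d["m1"]


class TestEpistatic:
    def test_accepted_pair_properties(self, std_phenotype):
        rho = 0.05
        gA, gB, d = gen_epistatic_pair(std_phenotype, rho, 0.1, 0.15, seed=1)
        assert abs(d["h_corr"] - rho) <= 0.005
        n = len(std_phenotype)
        cap = max(0.01, 4 / np.sqrt(n))
        assert max(abs(d["marginal_r_A"]), abs(d["marginal_r_B"])) < cap

    def test_negative_target(self, std_phenotype):
        gA, gB, d = gen_epistatic_pair(std_phenotype, -0.05, 0.1, 0.15, seed=2)
        assert d["h_corr"] < 0

    def test_alpha_zero_is_null(self, std_phenotype):
        # target 0 means alpha ~ 0: interaction and marginals all null
        y = std_phenotype
        rng = np.random.default_rng(3)
        gA = discretize_hwe(rng.standard_normal(len(y)), 0.1)
        gB = discretize_hwe(rng.standard_normal(len(y)), 0.15)
        H = (gA - 0.2) * (gB - 0.3)
        assert abs(np.corrcoef(H, y)[0, 1]) < 4 / np.sqrt(len(y))

    def test_hwe_counts_preserved(self, std_phenotype):
        gA, gB, d = gen_epistatic_pair(std_phenotype, 0.05, 0.1, 0.15, seed=4)
        n = len(std_phenotype)
        assert np.bincount(gA, minlength=3)[0] == round(0.81 * n)
        assert np.bincount(gB, minlength=3)[0] == round(0.85**2 * n)


class TestBuildSpikeInSet:
    def test_counts_and_pairing(self, std_phenotype):
        s = build_spikein_set(std_phenotype, (4, 3, 2, 4), seed=1)
        assert s.genotypes.shape == (len(std_phenotype), 13)
        types = s.effect_types
        assert (types == "additive").sum() == 4
        assert (types == "dominant").sum() == 3
        assert (types == "recessive").sum() == 2
        assert (types == "epistatic").sum() == 4
        epi = [sp for sp in s.specs if sp.effect_type == "epistatic"]
        assert all(sp.partner_id is not None for sp in epi)

    def test_single_additive(self, std_phenotype):
        s = build_spikein_set(std_phenotype, (1, 0, 0, 0), seed=2)
        assert s.genotypes.shape[1] == 1
        assert s.specs[0].effect_type == "additive"

    def test_determinism(self, std_phenotype):
        a = build_spikein_set(std_phenotype, (2, 2, 2, 2), seed=7)
        b = build_spikein_set(std_phenotype, (2, 2, 2, 2), seed=7)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.specs == b.specs

    def test_odd_epistatic_count_rejected(self, std_phenotype):
        with pytest.raises(SpecError):
            build_spikein_set(std_phenotype, (1, 1, 1, 3), seed=0)

    def test_rho_targets_within_range(self, std_phenotype):
        s = build_spikein_set(std_phenotype, (3, 3, 3, 2), seed=8)
        for sp in s.specs:
            assert 0.018 <= abs(sp.target_rho) <= 0.070

    def test_hwe_by_construction(self, std_phenotype):
        s = build_spikein_set(std_phenotype, (2, 0, 0, 0), seed=9)
        n = len(std_phenotype)
        for j, sp in enumerate(s.specs):
            counts = np.bincount(s.genotypes[:, j], minlength=3)
            p = sp.maf
            assert abs(counts[0] - (1 - p) ** 2 * n) <= 1
            assert abs(counts[2] - p * p * n) <= 1


class TestConstraintsScaling:
    def test_recessive_floor_scale_free(self):
        c = SpikeInConstraints()
        assert abs(c.recessive_maf_floor - np.sqrt(0.005)) < 1e-12

    def test_dominant_range(self):
        lo, hi = SpikeInConstraints().dominant_maf_range()
        assert abs(lo * (2 - lo) - 0.10) < 1e-9
        assert abs(hi * (2 - hi) - 0.14) < 1e-9
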