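import numpy as np
import pytest

from dompred.qc import allele_frequencies
from dompred.simulate import (
    SimConfig,
    assign_qtl_effects,
    genotypic_values,
    simulate_crossbred_progeny_means,
    simulate_dataset,
    simulate_genotypes,
    simulate_line_frequencies,
    simulate_phenotypes,
    true_crossbred_value,
    true_purebred_value,
)


def small_config(**kw):
    kw.setdefault("n_snps", 300)
    kw.setdefault("n_qtl", 40)
    kw.setdefault("n_train_sows_per_line", 150)
    kw.setdefault("n_boars_per_line", 40)
    kw.setdefault("n_daughters_per_boar", 10)
    kw.setdefault("seed", 5)
    return SimConfig(**kw)


class TestLineFrequencies:
    def test_no_divergence_shares_ancestral(self):
        f1, f2 = simulate_line_frequencies(small_config(line_divergence=0.0))
        np.testing.assert_array_equal(f1.p, f2.p)

    def test_drift_moment(self):
        cfg = SimConfig(n_snps=10_000, line_divergence=0.2, seed=2)
        rng = np.random.default_rng(2)
        p0 = np.random.default_rng(2).uniform(0.05, 0.95, 10_000)
        f1, f2 = simulate_line_frequencies(cfg)
        msd = np.mean((f1.p - f2.p) ** 2)
        expect = 2 * 0.2 * np.mean(p0 * (1 - p0))
        assert msd == pytest.approx(expect, rel=0.10)

    def test_seeded_repeatability(self):
        cfg = small_config(line_divergence=0.15)
        a = simulate_line_frequencies(cfg)
        b = simulate_line_frequencies(cfg)
        np.testing.assert_array_equal(a[0].p, b[0].p)
        np.testing.assert_array_equal(a[1].p, b[1].p)

    def test_invalid_divergence(self):
        with pytest.raises(ValueError):
            SimConfig(line_divergence=1.0)


class TestGenotypes:
    def test_fixed_allele(self):
        cfg = small_config()
        f1, _ = simulate_line_frequencies(cfg)
        f1.p[:] = 1.0
        t = simulate_genotypes(f1, 20, rng=np.random.default_rng(0))
        assert (t.codes == 2).all()

    def test_binomial_concentration(self):
        cfg = SimConfig(n_snps=2000, seed=3)
        f1, _ = simulate_line_frequencies(cfg)
        t = simulate_genotypes(f1, 2000, rng=np.random.default_rng(3))
        obs = allele_frequencies(t).p
        bound = 4 * np.sqrt(f1.p * (1 - f1.p) / (2 * 2000)) * 1.3
        assert (np.abs(obs - f1.p) < np.maximum(bound, 0.02)).all()

    def test_missing_rate(self):
        cfg = small_config()
        f1, _ = simulate_line_frequencies(cfg)
        t = simulate_genotypes(f1, 500, missing_rate=0.05, rng=np.random.default_rng(4))
        frac = (t.codes == -1).mean()
        assert frac == pytest.approx(0.05, abs=0.01)


class TestQtlEffects:
    def test_no_dominance_degenerate(self):
        cfg = small_config(dominance_ratio=0.0)
        f1, _ = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1)
        assert np.all(eff.d == 0.0)
        assert eff.sigma2_d == 0.0

    def test_variance_targets_hit_exactly(self):
        cfg = small_config(dominance_ratio=0.15, target_h2_a=0.10)
        f1, _ = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1)
        p, q = f1.p, 1 - f1.p
        alpha = eff.a + eff.d * (q - p)
        s2a = (2 * p * q * alpha**2).sum()
        s2d = ((2 * p * q * eff.d) ** 2).sum()
        assert s2a == pytest.approx(eff.sigma2_a, abs=1e-6)
        assert s2d == pytest.approx(0.15 * s2a, abs=1e-6)
        total = eff.sigma2_a + eff.sigma2_d + eff.sigma2_e
        assert eff.sigma2_a / total == pytest.approx(0.10, abs=1e-9)

    def test_seeded_repeatability(self):
        cfg = small_config()
        f1, _ = simulate_line_frequencies(cfg)
        e1 = assign_qtl_effects(cfg, f1)
        e2 = assign_qtl_effects(cfg, f1)
        np.testing.assert_array_equal(e1.a, e2.a)
        np.testing.assert_array_equal(e1.d, e2.d)


class TestPhenotypes:
    def test_noise_free_constant(self):
        cfg = small_config(dominance_ratio=0.0)
        f1, _ = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1)
        eff.a[:] = 0.0
        eff.sigma2_e = 0.0
        t = simulate_genotypes(f1, 30, rng=np.random.default_rng(1))
        ph = simulate_phenotypes(t, eff, cfg, rng=np.random.default_rng(1))
        np.testing.assert_allclose(ph.values, cfg.mu)

    def test_variance_decomposition(self):
        cfg = SimConfig(n_snps=1000, n_qtl=150, seed=6)
        f1, _ = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1, rng=np.random.default_rng(6))
        t = simulate_genotypes(f1, 2000, rng=np.random.default_rng(7))
        ph = simulate_phenotypes(t, eff, cfg, rng=np.random.default_rng(8))
        total = eff.sigma2_a + eff.sigma2_d + eff.sigma2_e
        assert np.var(ph.values) == pytest.approx(total, rel=0.10)

    def test_single_qtl_regression_recovers_substitution_effect(self):
        cfg = SimConfig(n_snps=50, n_qtl=1, target_h2_a=0.5, dominance_ratio=0.1, seed=9)
        f1, _ = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1, rng=np.random.default_rng(9))
        j = int(eff.qtl_idx[0])
        t = simulate_genotypes(f1, 4000, rng=np.random.default_rng(10))
        ph = simulate_phenotypes(t, eff, cfg, rng=np.random.default_rng(11))
        x = t.codes[:, j].astype(float)
        xc = x - x.mean()
        slope = xc @ (ph.values - ph.values.mean()) / (xc @ xc)
        p = x.mean() / 2  # realised frequency
        alpha = eff.a[j] + eff.d[j] * (1 - 2 * p)
        se = np.sqrt(eff.sigma2_e / (xc @ xc))
        assert slope == pytest.approx(alpha, abs=4 * se + 0.02)


class TestProgenyMeans:
    def test_fixed_parents_fixed_daughters(self):
        cfg = small_config()
        f1, f2 = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1)
        boars = simulate_genotypes(f1, 3, rng=np.random.default_rng(2))
        boars.codes[:] = 2
        f2.p[:] = 1.0
        eff.sigma2_e = 0.0
        pm = simulate_crossbred_progeny_means(
            boars, f2, eff, 5, cfg, rng=np.random.default_rng(3)
        )
        # all daughters are homozygous carriers at every SNP
        expect = cfg.mu + 2 * eff.a.sum()
        np.testing.assert_allclose(pm.values, expect)
        assert (pm.n_daughters == 5).all()

    def test_large_family_mean_approaches_true_crossbred_value(self):
        """E[daughter phenotype] = mu + sum(a) + crossbred breeding value."""
        cfg = small_config(seed=13)
        f1, f2 = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1)
        boars = simulate_genotypes(f1, 4, rng=np.random.default_rng(4))
        pm = simulate_crossbred_progeny_means(
            boars, f2, eff, 40_000, cfg, rng=np.random.default_rng(5)
        )
        tbv = true_crossbred_value(boars, f2, eff)
        offset = cfg.mu + eff.a.sum()
        np.testing.assert_allclose(pm.values, tbv + offset, atol=0.15)

    def test_seeded_repeatability(self):
        cfg = small_config()
        f1, f2 = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1)
        boars = simulate_genotypes(f1, 5, rng=np.random.default_rng(6))
        a = simulate_crossbred_progeny_means(boars, f2, eff, 10, cfg, rng=np.random.default_rng(7))
        b = simulate_crossbred_progeny_means(boars, f2, eff, 10, cfg, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.values, b.values)


class TestTrueValues:
    def test_no_dominance_same_frequencies_purebred_equals_crossbred(self):
        cfg = small_config(dominance_ratio=0.0)
        f1, _ = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1)
        boars = simulate_genotypes(f1, 10, rng=np.random.default_rng(8))
        np.testing.assert_allclose(
            true_purebred_value(boars, f1, eff),
            true_crossbred_value(boars, f1, eff),
            atol=1e-12,
        )

    def test_linear_in_effects(self):
        cfg = small_config()
        f1, f2 = simulate_line_frequencies(cfg)
        eff = assign_qtl_effects(cfg, f1)
        boars = simulate_genotypes(f1, 6, rng=np.random.default_rng(9))
        base = true_crossbred_value(boars, f2, eff)
        eff.a *= 2
        eff.d *= 2
        doubled = true_crossbred_value(boars, f2, eff)
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-10)

    def test_purebred_crossbred_correlation_below_one_with_dominance(self):
        cfg = small_config(
            n_boars_per_line=200, dominance_ratio=0.15, line_divergence=0.15, seed=21
        )
        ds = simulate_dataset(cfg)
        r = np.corrcoef(ds.true_bv_purebred["line1"], ds.true_bv_crossbred["line1"])[0, 1]
        assert r < 0.995


class TestDataset:
    def test_structure_and_determinism(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        assert ds.lines == ["line1", "line2"]
        for ln in ds.lines:
            assert ds.sows[ln].n_animals == cfg.n_train_sows_per_line
            assert ds.boars[ln].n_animals == cfg.n_boars_per_line
            assert len(ds.progeny_means[ln]) == cfg.n_boars_per_line
            assert (ds.progeny_means[ln].n_daughters == cfg.n_daughters_per_boar).all()
            assert ds.true_bv_purebred[ln].size == cfg.n_boars_per_line
        ds2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(ds.sows["line1"].codes, ds2.sows["line1"].codes)
        np.testing.assert_array_equal(
            ds.progeny_means["line2"].values, ds2.progeny_means["line2"].values
        )
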