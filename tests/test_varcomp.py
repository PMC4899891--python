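import numpy as np
import pytest

from dompred.io_genotypes import GenotypeTable, SnpMeta
from dompred.qc import AlleleFrequencySet, allele_frequencies
from dompred.varcomp import (
    VarianceComponents,
    backsolve_snp_effects,
    build_mme,
    center_additive,
    center_dominance,
    gblup_solve,
    genomic_relationships,
    make_D,
    make_G,
    relationship_diagnostics,
    reml_ad,
)

from conftest import make_table


def freqset(p, snp_ids=None, line="L"):
    p = np.atleast_1d(np.asarray(p, dtype=float))
    ids = snp_ids or [f"s{j}" for j in range(p.size)]
    return AlleleFrequencySet(line, ids, p)


def one_snp_table(codes, line="L"):
    codes = np.asarray(codes, dtype=np.int8).reshape(-1, 1)
    return GenotypeTable(
        [f"a{i}" for i in range(codes.shape[0])],
        [line] * codes.shape[0],
        [SnpMeta("s0", "1", 1, "A", "G")],
        codes,
    )


class TestCenterings:
    def test_additive_elements(self):
        t = one_snp_table([2, 1, 0])
        W = center_additive(t, freqset(0.5))
        np.testing.assert_allclose(W[:, 0], [1.0, 0.0, -1.0])

    def test_additive_monomorphic_p_zero(self):
        t = one_snp_table([2, 1, 0])
        W = center_additive(t, freqset(0.0))
        np.testing.assert_allclose(W[:, 0], [2.0, 1.0, 0.0])

    def test_additive_columns_centered_at_observed_frequency(self, rng):
        t = make_table(rng, 100, 20)
        W = center_additive(t, allele_frequencies(t))
        np.testing.assert_allclose(W.mean(axis=0), 0.0, atol=1e-12)

    def test_dominance_elements(self):
        t = one_snp_table([2, 1, 0])
        W = center_dominance(t, freqset(0.5))
        np.testing.assert_allclose(W[:, 0], [-0.5, 0.5, -0.5])

    def test_dominance_monomorphic_column_zero(self):
        t = one_snp_table([2, 2, 2])
        W = center_dominance(t, freqset(1.0))
        np.testing.assert_allclose(W[:, 0], 0.0)

    def test_dominance_expected_mean_zero_under_hwe(self, rng):
        # exact HWE counts: -2q^2 p^2 + 2pq 2pq - 2p^2 q^2 = 0
        p = rng.uniform(0.05, 0.95, 50)
        q = 1 - p
        expected = p**2 * (-2 * q**2) + 2 * p * q * (2 * p * q) + q**2 * (-2 * p**2)
        np.testing.assert_allclose(expected, 0.0, atol=1e-12)


class TestRelationshipMatrices:
    def test_single_heterozygote(self):
        t = one_snp_table([1])
        f = freqset(0.5)
        G = make_G(center_additive(t, f), f)
        assert G[0, 0] == pytest.approx(0.0)

    def test_mean_diagonal_near_one(self, rng):
        t = make_table(rng, 500, 2000)
        rel = genomic_relationships(t)
        assert np.diag(rel.G).mean() == pytest.approx(1.0, abs=0.05)
        assert np.allclose(rel.G, rel.G.T)
        assert np.allclose(rel.D, rel.D.T)

    def test_permutation_equivariance(self, rng):
        t = make_table(rng, 20, 50)
        rel = genomic_relationships(t)
        perm = rng.permutation(20)
        rel2 = genomic_relationships(t.subset_animals(perm))
        np.testing.assert_allclose(rel2.G, rel.G[np.ix_(perm, perm)], atol=1e-12)

    def test_monomorphic_panel_rejected(self):
        t = one_snp_table([2, 2])
        f = freqset(1.0)
        with pytest.raises(ValueError, match="monomorphic"):
            make_G(center_additive(t, f), f)

    def test_psd_up_to_tolerance(self, rng):
        t = make_table(rng, 60, 120)
        rel = genomic_relationships(t)
        assert np.linalg.eigvalsh(rel.G).min() > -1e-8


class TestReml:
    def test_recovery_in_informative_design(self, rng):
        """Strong-signal configuration: estimates land near the truth."""
        n, m = 400, 150
        t = make_table(rng, n, m)
        rel = genomic_relationships(t)
        sa, sd, se = 1.0, 0.5, 1.0
        L = np.linalg.cholesky(rel.G + 1e-6 * np.eye(n))
        Ld = np.linalg.cholesky(rel.D + 1e-6 * np.eye(n))
        est = []
        for _ in range(5):
            y = (
                L @ rng.normal(size=n) * np.sqrt(sa)
                + Ld @ rng.normal(size=n) * np.sqrt(sd)
                + rng.normal(size=n) * np.sqrt(se)
            )
            vc = reml_ad(y, rel.G, rel.D)
            est.append([vc.sigma2_a, vc.sigma2_d, vc.sigma2_e])
        mean = np.array(est).mean(axis=0)
        np.testing.assert_allclose(mean, [sa, sd, se], rtol=0.35)

    def test_null_dominance_not_inflated(self, rng):
        n, m = 300, 120
        t = make_table(rng, n, m)
        rel = genomic_relationships(t)
        L = np.linalg.cholesky(rel.G + 1e-6 * np.eye(n))
        ests = []
        for _ in range(6):
            y = L @ rng.normal(size=n) * 1.0 + rng.normal(size=n) * 1.0
            vc = reml_ad(y, rel.G, rel.D)
            ests.append(vc.sigma2_d)
        assert np.mean(ests) < 0.15  # truth sigma2_a = 1

    def test_matches_independent_em_reml(self, rng):
        """Additive-only model agrees with a plain EM-REML iteration."""
        n, m = 120, 60
        t = make_table(rng, n, m)
        rel = genomic_relationships(t)
        L = np.linalg.cholesky(rel.G + 1e-6 * np.eye(n))
        y = L @ rng.normal(size=n) + rng.normal(size=n)
        vc = reml_ad(y, rel.G, tol=1e-12)

        # independent EM-REML on (G, I)
        X = np.ones((n, 1))
        K = [rel.G + 1e-6 * np.eye(n), np.eye(n)]
        theta = np.array([np.var(y) / 2, np.var(y) / 2])
        for _ in range(5000):
            V = theta[0] * K[0] + theta[1] * K[1]
            Vi = np.linalg.inv(V)
            P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
            Py = P @ y
            new = theta + theta**2 * np.array(
                [(Py @ (Kk @ Py) - np.trace(P @ Kk)) / n for Kk in K]
            )
            if np.max(np.abs(new - theta)) < 1e-12:
                theta = new
                break
            theta = new
        assert vc.sigma2_a == pytest.approx(theta[0], abs=1e-4)
        assert vc.sigma2_e == pytest.approx(theta[1], abs=1e-4)

    def test_shift_invariance(self, rng):
        n = 150
        t = make_table(rng, n, 80)
        rel = genomic_relationships(t)
        y = rng.normal(size=n)
        vc1 = reml_ad(y, rel.G, rel.D)
        vc2 = reml_ad(y + 100.0, rel.G, rel.D)
        assert vc1.sigma2_a == pytest.approx(vc2.sigma2_a, abs=1e-6)
        assert vc1.sigma2_e == pytest.approx(vc2.sigma2_e, abs=1e-6)


class TestGblup:
    @pytest.fixture()
    def system(self, rng):
        n = 80
        t = make_table(rng, n, 200)
        rel = genomic_relationships(t)
        L = np.linalg.cholesky(rel.G + 1e-6 * np.eye(n))
        y = 12.0 + L @ rng.normal(size=n) + rng.normal(size=n)
        vc = VarianceComponents(
            sigma2_a=1.0, sigma2_d=0.2, sigma2_e=1.0, h2_a=0.45, h2_d=0.09
        )
        return t, rel, y, vc

    def test_solutions_satisfy_mme(self, system):
        _, rel, y, vc = system
        u, v, mu = gblup_solve(y, rel.G, rel.D, vc)
        lhs, rhs = build_mme(y, rel.G, rel.D, vc)
        sol = np.concatenate([[mu], u, v])
        assert np.abs(lhs @ sol - rhs).max() < 1e-8

    def test_shrinkage_limit(self, system):
        _, rel, y, _ = system
        vc_small = VarianceComponents(
            sigma2_a=1e-8, sigma2_d=1e-8, sigma2_e=1.0, h2_a=0.0, h2_d=0.0
        )
        u, v, _ = gblup_solve(y, rel.G, rel.D, vc_small)
        assert np.abs(u).max() < 1e-4
        assert np.abs(v).max() < 1e-4

    def test_nonpositive_variance_rejected(self, system):
        _, rel, y, _ = system
        vc_bad = VarianceComponents(sigma2_a=0.0, sigma2_d=0.1, sigma2_e=1.0, h2_a=0, h2_d=0)
        with pytest.raises(ValueError):
            gblup_solve(y, rel.G, rel.D, vc_bad)


class TestBacksolve:
    def test_projection_identity_full_row_rank(self, rng):
        n, m = 30, 100
        W = rng.normal(size=(n, m))
        u = rng.normal(size=n)
        a_hat, _ = backsolve_snp_effects(u, W)
        np.testing.assert_allclose(W @ a_hat, u, atol=1e-6)

    def test_zero_solutions_give_zero_effects(self, rng):
        W = rng.normal(size=(10, 40))
        a_hat, _ = backsolve_snp_effects(np.zeros(10), W)
        np.testing.assert_allclose(a_hat, 0.0, atol=1e-12)

    def test_gebv_from_backsolved_effects_matches_u(self, rng):
        """Training-animal breeding values are reproduced by W_a a_hat."""
        n = 60
        t = make_table(rng, n, 300)
        rel = genomic_relationships(t)
        L = np.linalg.cholesky(rel.G + 1e-6 * np.eye(n))
        y = L @ rng.normal(size=n) + rng.normal(size=n)
        vc = reml_ad(y, rel.G)
        vc2 = VarianceComponents(
            sigma2_a=max(vc.sigma2_a, 0.05), sigma2_d=0.0,
            sigma2_e=vc.sigma2_e, h2_a=vc.h2_a, h2_d=0.0,
        )
        u, _, _ = gblup_solve(y, rel.G, None, vc2)
        W = center_additive(t, allele_frequencies(t))
        with pytest.warns(RuntimeWarning):
            a_hat, _ = backsolve_snp_effects(u, W)  # centred W is rank n-1
        pred = W @ a_hat
        assert np.corrcoef(pred, u)[0, 1] > 0.9999


class TestDiagnostics:
    def test_identity_matrix_has_zero_offdiag_variance(self):
        out = relationship_diagnostics(np.eye(6), ["A"] * 3 + ["B"] * 3)
        assert out["offdiag_variance"] == pytest.approx(0.0)
        assert out["mean_cross_group"]["A|B"] == pytest.approx(0.0)

    def test_family_structure_detected(self, rng):
        # two families: high within-block relationship
        block = 0.5 * np.ones((4, 4))
        G = np.block(
            [[block, np.zeros((4, 4))], [np.zeros((4, 4)), block]]
        ) + 0.5 * np.eye(8)
        out = relationship_diagnostics(G, ["f1"] * 4 + ["f2"] * 4)
        within = np.mean([0.5, 0.5])
        assert out["mean_cross_group"]["f1|f2"] < within

    def test_matches_brute_force_pairs(self, rng):
        n = 12
        G = rng.normal(size=(n, n))
        G = (G + G.T) / 2
        groups = ["x"] * 6 + ["y"] * 6
        out = relationship_diagnostics(G, groups)
        pairs = [G[i, j] for i in range(n) for j in range(n) if i != j]
        assert out["offdiag_variance"] == pytest.approx(np.var(pairs))
        cross = [G[i, j] for i in range(6) for j in range(6, 12)]
        assert out["mean_cross_group"]["x|y"] == pytest.approx(np.mean(cross))


def test_additive_dominance_codings_orthogonal_under_hwe(rng):
    """Sample covariance between W_a and W_d columns shrinks as n grows."""
    p = 0.3
    for n, bound in ((200, 0.25), (5000, 0.06)):
        codes = rng.binomial(2, p, size=(n, 1)).astype(np.int8)
        t = one_snp_table(codes.ravel())
        f = freqset(p, snp_ids=["s0"])
        wa = center_additive(t, f)[:, 0]
        wd = center_dominance(t, f)[:, 0]
        cov = np.cov(wa, wd)[0, 1]
        assert abs(cov) < bound
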