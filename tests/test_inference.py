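import numpy as np
import pandas as pd
import pytest

from rrgp.basis import TimeGrid, legendre_basis
from rrgp.geno import GRM
from rrgp.inference import (GibbsConfig, effective_sample_size, gibbs_sample,
                            predict_unphenotyped, solve_mme,
                            _invwishart_draw, _scaled_invchi2_draw)
from rrgp.model import (CovarianceComponents, PhenotypeTable, RRMSpec,
                        build_design)
from rrgp.summaries import genomic_correlation
from rrgp.synthdata import SyntheticConfig, simulate_dataset


def toy_grm(n, rho=0.25, seed=None):
    acc = tuple(f"a{i}" for i in range(n))
    if seed is None:
        return GRM(acc, np.eye(n) * (1 - rho) + rho)
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(n, 3 * n))
    G = W @ W.T / (3 * n)
    d = np.sqrt(np.diag(G))
    return GRM(acc, G / np.outer(d, d))


def records(entries):
    return PhenotypeTable(pd.DataFrame(
        entries, columns=["accession", "trait", "day", "value"]))


def st_comps(n_days, s2u=1.0, s2p=0.5, s2e=0.8, order=2):
    K = order + 1
    return CovarianceComponents(
        s2u * np.eye(K), s2p * np.eye(K),
        np.full((n_days, 1, 1), s2e), tuple(range(1, n_days + 1)))


class TestSolveMme:
    def test_zero_phenotypes_give_zero_solutions(self, basis20, st_spec):
        ph = records([(f"a{i}", "WU", d, 0.0)
                      for i in range(5) for d in range(1, 21)])
        m = build_design(ph, basis20, st_spec, toy_grm(5))
        sols = solve_mme(m, st_comps(20))
        assert np.allclose(sols.b, 0.0, atol=1e-12)
        assert np.allclose(sols.u, 0.0, atol=1e-12)
        assert np.allclose(sols.p, 0.0, atol=1e-12)

    def test_order0_single_day_equals_closed_form_gblup(self):
        # RRM with one day and constant basis is GBLUP; compare to the dense
        # closed form u = (inv(G) lambda + I)^-1 (y - X bhat)
        n = 20
        grm = toy_grm(n, seed=11)
        rng = np.random.default_rng(1)
        y = rng.normal(size=n)
        basis = legendre_basis(TimeGrid((10,), 1, 20), 0)
        spec = RRMSpec(traits=("WU",), fixed_order=0, genetic_order=0,
                       pe_order=0)
        ph = records([(f"a{i}", "WU", 10, y[i]) for i in range(n)])
        m = build_design(ph, basis, spec, grm)
        s2u, s2p, s2e = 1.3, 0.4, 0.7
        comps = CovarianceComponents(np.array([[s2u]]), np.array([[s2p]]),
                                     np.full((1, 1, 1), s2e), (10,))
        ridge = 1e-8
        sols = solve_mme(m, comps, ridge=ridge)
        Gr = grm.matrix + ridge * np.eye(n)
        lam = (s2p + s2e) / s2u
        V = s2u * Gr + (s2p + s2e) * np.eye(n)
        Vinv = np.linalg.inv(V)
        X = np.ones((n, 1))
        bhat = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y).item()
        uhat = np.linalg.solve(np.linalg.inv(Gr) * lam + np.eye(n), y - bhat)
        assert sols.b[0] == pytest.approx(bhat, rel=1e-8)
        np.testing.assert_allclose(sols.u[:, 0], uhat, rtol=1e-8, atol=1e-10)

    def test_mme_residual_identity(self, basis20, mt_spec, small_dataset):
        _, _, grm, phenos, truth = small_dataset
        m = build_design(phenos, basis20, mt_spec, grm)
        sols, lhs, rhs = solve_mme(m, truth.components, return_lhs=True)
        sol = np.concatenate([sols.b, sols.u.ravel(), sols.p.ravel()])
        rel = np.linalg.norm(lhs @ sol - rhs) / np.linalg.norm(rhs)
        assert rel < 1e-8

    def test_duplicate_accessions_get_equal_solutions(self, basis20, st_spec):
        # identical genotype rows and identical records are exchangeable
        n = 6
        rng = np.random.default_rng(3)
        G = toy_grm(n, seed=5).matrix.copy()
        G[1] = G[0]
        G[:, 1] = G[:, 0]
        G[1, 1] = G[0, 0]
        grm = GRM(tuple(f"a{i}" for i in range(n)), G)
        vals = rng.normal(size=20)
        entries = []
        for i in range(n):
            for d in range(1, 21):
                v = vals[d - 1] if i in (0, 1) else rng.normal()
                entries.append((f"a{i}", "WU", d, v))
        m = build_design(records(entries), basis20, st_spec, grm)
        sols = solve_mme(m, st_comps(20))
        np.testing.assert_allclose(sols.u[0], sols.u[1], atol=1e-8)

    def test_invariant_to_record_order(self, basis20, st_spec):
        rng = np.random.default_rng(4)
        entries = [(f"a{i}", "WU", d, rng.normal())
                   for i in range(5) for d in range(1, 21)]
        ph1 = records(entries)
        shuffled = list(entries)
        rng.shuffle(shuffled)
        ph2 = records(shuffled)
        grm = toy_grm(5, seed=9)
        comps = st_comps(20)
        s1 = solve_mme(build_design(ph1, basis20, st_spec, grm), comps)
        s2 = solve_mme(build_design(ph2, basis20, st_spec, grm), comps)
        # accession order may differ; compare by id
        o1 = {a: i for i, a in enumerate(s1.accession_ids)}
        o2 = {a: i for i, a in enumerate(s2.accession_ids)}
        for a in o1:
            np.testing.assert_allclose(s1.u[o1[a]], s2.u[o2[a]], atol=1e-9)
        np.testing.assert_allclose(s1.b, s2.b, atol=1e-9)

    def test_non_pd_components_rejected(self, basis20, st_spec):
        ph = records([(f"a{i}", "WU", d, 0.1)
                      for i in range(4) for d in range(1, 21)])
        m = build_design(ph, basis20, st_spec, toy_grm(4))
        comps = CovarianceComponents(np.zeros((3, 3)), np.eye(3),
                                     np.full((20, 1, 1), 0.5),
                                     tuple(range(1, 21)))
        with pytest.raises(ValueError):
            solve_mme(m, comps)


class TestPredictUnphenotyped:
    def make_sols(self, grm, basis, u):
        from rrgp.inference import RRMSolutions
        n = u.shape[0]
        return RRMSolutions(b=np.zeros(3), u=u, p=np.zeros_like(u),
                            accession_ids=grm.accession_ids[:n],
                            basis=basis, traits=("WU",))

    def test_identical_genotype_copies_prediction(self, basis20):
        n = 6
        G = toy_grm(n, seed=2).matrix.copy()
        # test accession a5 genotypically identical to training a0
        G[5] = G[0]
        G[:, 5] = G[:, 0]
        G[5, 5] = G[0, 0]
        grm = GRM(tuple(f"a{i}" for i in range(n)), G)
        rng = np.random.default_rng(0)
        u = rng.normal(size=(5, 3))
        sols = self.make_sols(grm, basis20, u)
        pred = predict_unphenotyped(grm, [f"a{i}" for i in range(5)], ["a5"],
                                    sols, ridge=1e-10)
        train_traj = u[0] @ basis20.phi.T
        np.testing.assert_allclose(pred[0], train_traj, rtol=1e-6, atol=1e-8)

    def test_unrelated_test_accessions_predict_zero(self, basis20):
        G = np.eye(5)
        grm = GRM(tuple(f"a{i}" for i in range(5)), G)
        u = np.random.default_rng(1).normal(size=(4, 3))
        sols = self.make_sols(grm, basis20, u)
        pred = predict_unphenotyped(grm, [f"a{i}" for i in range(4)], ["a4"],
                                    sols)
        np.testing.assert_allclose(pred, 0.0, atol=1e-9)

    def test_hand_built_matrix_product(self, basis20):
        grm = toy_grm(5, seed=7)
        rng = np.random.default_rng(2)
        u = rng.normal(size=(3, 3))
        sols = self.make_sols(grm, basis20, u)
        train = ["a0", "a1", "a2"]
        test = ["a3", "a4"]
        ridge = 1e-6
        pred = predict_unphenotyped(grm, train, test, sols, ridge=ridge)
        a_trn = u @ basis20.phi.T
        Gtt = grm.matrix[:3, :3] + ridge * np.eye(3)
        Gst = grm.matrix[3:, :3]
        expected = Gst @ np.linalg.solve(Gtt, a_trn)
        np.testing.assert_allclose(pred, expected, atol=1e-10)

    def test_overlapping_sets_rejected(self, basis20):
        grm = toy_grm(4)
        u = np.zeros((3, 3))
        sols = self.make_sols(grm, basis20, u)
        with pytest.raises(ValueError, match="disjoint"):
            predict_unphenotyped(grm, ["a0", "a1"], ["a1", "a3"], sols)

    def test_matches_joint_mme_blup_of_zero_record_accessions(
            self, basis20, st_spec):
        # including unphenotyped accessions in the MME equals the two-step
        # genomic projection at fixed variances
        n, n_test = 24, 6
        grm = toy_grm(n, seed=13)
        rng = np.random.default_rng(5)
        train = [f"a{i}" for i in range(n - n_test)]
        test = [f"a{i}" for i in range(n - n_test, n)]
        ph = records([(a, "WU", d, rng.normal())
                      for a in train for d in range(1, 21)])
        comps = st_comps(20)
        ridge = 1e-6
        m_joint = build_design(ph, basis20, st_spec, grm,
                               accessions=train + test)
        sols_joint = solve_mme(m_joint, comps, ridge=ridge)
        order = {a: i for i, a in enumerate(sols_joint.accession_ids)}
        gv_joint = sols_joint.genetic_values(trait=0)[[order[a] for a in test]]
        m_trn = build_design(ph, basis20, st_spec, grm)
        sols_trn = solve_mme(m_trn, comps, ridge=ridge)
        pred = predict_unphenotyped(grm, train, test, sols_trn, ridge=ridge)
        np.testing.assert_allclose(gv_joint, pred, rtol=1e-6, atol=1e-9)


class TestGibbs:
    def test_fixed_variances_contract(self, basis20, st_spec):
        rng = np.random.default_rng(6)
        ph = records([(f"a{i}", "WU", d, rng.normal())
                      for i in range(8) for d in range(1, 21)])
        m = build_design(ph, basis20, st_spec, toy_grm(8, seed=3))
        comps = st_comps(20)
        cfg = GibbsConfig(n_iter=60, burn_in=20, thin=2, seed=1,
                          fixed_variances=comps)
        draws = gibbs_sample(m, cfg)
        for k in range(draws.n_kept):
            np.testing.assert_array_equal(draws.C_draws[k], comps.C)
            np.testing.assert_array_equal(draws.D_draws[k], comps.D)
            np.testing.assert_array_equal(draws.R_draws[k], comps.R)
        # locations are actually sampled
        assert np.abs(draws.location_mean.u).max() > 0

    def test_fixed_variance_posterior_mean_matches_mme(self, basis20,
                                                       st_spec):
        rng = np.random.default_rng(7)
        ph = records([(f"a{i}", "WU", d, rng.normal())
                      for i in range(10) for d in range(1, 21)])
        m = build_design(ph, basis20, st_spec, toy_grm(10, seed=4))
        comps = st_comps(20)
        sols = solve_mme(m, comps)
        cfg = GibbsConfig(n_iter=20000, burn_in=2000, thin=1, seed=2,
                          fixed_variances=comps, save_draws=False)
        draws = gibbs_sample(m, cfg)
        loc = draws.location_mean
        assert np.corrcoef(loc.u.ravel(), sols.u.ravel())[0, 1] > 0.995
        np.testing.assert_allclose(loc.b, sols.b, atol=0.05)

    def test_reproducible_under_seed(self, basis20, st_spec):
        rng = np.random.default_rng(8)
        ph = records([(f"a{i}", "WU", d, rng.normal())
                      for i in range(6) for d in range(1, 21)])
        m = build_design(ph, basis20, st_spec, toy_grm(6, seed=5))
        cfg = GibbsConfig(n_iter=120, burn_in=40, thin=2, seed=11)
        d1 = gibbs_sample(m, cfg)
        d2 = gibbs_sample(m, cfg)
        np.testing.assert_array_equal(d1.C_draws, d2.C_draws)
        np.testing.assert_array_equal(d1.R_draws, d2.R_draws)
        np.testing.assert_array_equal(d1.location_mean.u, d2.location_mean.u)

    def test_conjugate_variance_draw_matches_analytic_posterior(self):
        # known-mean one-variance toy model: scaled-inverse-chi-square
        # posterior mean (s0 + sum y^2) / (nu0 + n - 2)
        rng = np.random.default_rng(9)
        n = 50
        y = rng.normal(0, 1.4, size=n)
        nu0, s0 = 3.0, 0.01
        ss = s0 + y @ y
        analytic = ss / (nu0 + n - 2)
        draws = np.array([_scaled_invchi2_draw(rng, nu0 + n, ss)
                          for _ in range(4000)])
        mc_se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - analytic) < 3 * mc_se

    def test_invwishart_draw_matches_analytic_mean(self):
        rng = np.random.default_rng(10)
        p = 3
        scale = np.array([[2.0, 0.3, 0.0], [0.3, 1.5, 0.2], [0.0, 0.2, 1.0]])
        df = 12.0
        analytic = scale / (df - p - 1)
        draws = np.stack([_invwishart_draw(rng, df, scale)
                          for _ in range(6000)])
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - analytic) < 4 * se)

    def test_parameter_recovery_bivariate(self, basis20, mt_spec):
        # simulate from the generative model with known C, D, R and recover
        # the genomic-correlation trajectory
        cfg = SyntheticConfig(n_accessions=200, n_markers=1200,
                              n_founders=32, seed=21)
        _, grm, phenos, truth = simulate_dataset(cfg)
        m = build_design(phenos, basis20, mt_spec, grm)
        draws = gibbs_sample(m, GibbsConfig(n_iter=6000, burn_in=2000,
                                            thin=5, seed=3, save_draws=False))
        pm = draws.posterior_mean()
        rg_est = genomic_correlation(pm, basis20)
        rg_true = genomic_correlation(truth.components, basis20)
        assert np.abs(rg_est - rg_true).mean() <= 0.1

    def test_invalid_chain_controls_rejected(self):
        with pytest.raises(ValueError):
            GibbsConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            GibbsConfig(thin=0)


class TestEffectiveSampleSize:
    def test_iid_series_ess_near_n(self):
        x = np.random.default_rng(0).normal(size=2000)
        assert effective_sample_size(x) > 1200

    def test_correlated_series_ess_smaller(self):
        rng = np.random.default_rng(1)
        x = np.zeros(2000)
        for i in range(1, 2000):
            x[i] = 0.95 * x[i - 1] + rng.normal()
        assert effective_sample_size(x) < 300
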