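import numpy as np
import pandas as pd
import pytest

from rrgp.basis import TimeGrid, legendre_basis
from rrgp.geno import GRM
from rrgp.model import (CovarianceComponents, PhenotypeTable, RRMSpec,
                        build_design, realized_covariance)


def toy_grm(n, rho=0.2):
    acc = tuple(f"a{i}" for i in range(n))
    return GRM(acc, np.eye(n) * (1 - rho) + rho)


def records(entries):
    return PhenotypeTable(pd.DataFrame(
        entries, columns=["accession", "trait", "day", "value"]))


class TestPhenotypeTable:
    def test_duplicate_records_rejected(self):
        with pytest.raises(ValueError):
            records([("a0", "WU", 1, 0.5), ("a0", "WU", 1, 0.6)])

    def test_subset_filters(self):
        ph = records([("a0", "WU", 1, 0.1), ("a0", "PSA", 1, 1.0),
                      ("a1", "WU", 2, 0.2)])
        assert len(ph.subset(traits=["WU"]).records) == 2
        assert len(ph.subset(accessions=["a1"]).records) == 1
        assert len(ph.subset(days=[1]).records) == 2

    def test_csv_roundtrip(self, tmp_path):
        ph = records([("a0", "WU", 1, 0.1), ("a1", "PSA", 2, 3.0)])
        path = tmp_path / "phenos.tsv"
        ph.to_csv(path)
        ph2 = PhenotypeTable.read_csv(path)
        pd.testing.assert_frame_equal(ph.records, ph2.records)


class TestBuildDesign:
    def test_single_record_design_row_is_phi(self, basis20, st_spec):
        ph = records([("a0", "WU", 1, 0.5)])
        m = build_design(ph, basis20, st_spec, toy_grm(1))
        assert m.design.shape == (1, 3)
        np.testing.assert_allclose(m.design[0], basis20.phi[0], atol=1e-12)

    def test_complete_bivariate_dimensions(self, basis20, mt_spec):
        entries = [(f"a{i}", t, d, 0.0)
                   for i in range(2) for t in ("WU", "PSA")
                   for d in range(1, 21)]
        m = build_design(records(entries), basis20, mt_spec, toy_grm(2))
        assert m.y.shape == (80,)
        assert m.coef_dim == 6              # Z has 2 traits x 3 coefs x 2 acc
        assert m.design.shape == (80, 6)

    def test_removing_a_record_removes_one_row(self, basis20, mt_spec):
        entries = [(f"a{i}", t, d, 0.1)
                   for i in range(3) for t in ("WU", "PSA")
                   for d in range(1, 21)]
        full = build_design(records(entries), basis20, mt_spec, toy_grm(3))
        partial = build_design(records(entries[1:]), basis20, mt_spec,
                               toy_grm(3))
        assert partial.n_records == full.n_records - 1
        assert partial.coef_dim == full.coef_dim
        assert partial.n_accessions == full.n_accessions

    def test_accession_absent_from_grm_raises(self, basis20, st_spec):
        ph = records([("ghost", "WU", 1, 0.5)])
        with pytest.raises(KeyError):
            build_design(ph, basis20, st_spec, toy_grm(2))

    def test_day_off_grid_needs_flag(self, st_spec):
        basis = legendre_basis(TimeGrid((1, 2, 3)), 2)
        ph = records([("a0", "WU", 5, 0.5)])
        with pytest.raises(ValueError, match="outside the basis grid"):
            build_design(ph, basis, st_spec, toy_grm(1))
        m = build_design(ph, basis, st_spec, toy_grm(1),
                         allow_extrapolation=True)
        assert m.n_records == 1

    def test_trait_block_placement(self, basis20, mt_spec):
        ph = records([("a0", "PSA", 4, 1.0)])
        m = build_design(ph, basis20, mt_spec, toy_grm(1))
        np.testing.assert_allclose(m.design[0, :3], 0.0)
        np.testing.assert_allclose(m.design[0, 3:], basis20.phi[3], atol=1e-12)


def bivariate_comps(M=6, n_days=2, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(M, M))
    C = scale * (A @ A.T + np.eye(M))
    B = rng.normal(size=(M, M))
    D = 0.5 * (B @ B.T) + np.eye(M)
    R = np.zeros((n_days, 2, 2))
    for t in range(n_days):
        R[t] = [[0.8 + 0.1 * t, 0.2], [0.2, 1.1]]
    return CovarianceComponents(C, D, R, tuple(range(1, n_days + 1)))


class TestRealizedCovariance:
    def setup_method(self):
        self.basis = legendre_basis(TimeGrid((1, 2), 1, 2), 2)
        self.spec = RRMSpec(traits=("WU", "PSA"))
        self.grm = toy_grm(3, rho=0.4)
        entries = [(f"a{i}", t, d, 0.0)
                   for i in range(3) for d in (1, 2) for t in ("WU", "PSA")]
        self.model = build_design(records(entries), self.basis, self.spec,
                                  self.grm)

    def test_residual_only_model_is_block_diagonal(self):
        comps = bivariate_comps()
        zero = CovarianceComponents(np.zeros((6, 6)), np.zeros((6, 6)),
                                    comps.R, comps.r_days)
        V = realized_covariance(self.model, zero)
        # nonzero only within (accession, day) 2x2 blocks
        for r1 in range(12):
            for r2 in range(12):
                same = (self.model.rec_acc[r1] == self.model.rec_acc[r2]
                        and self.model.rec_day[r1] == self.model.rec_day[r2])
                if not same:
                    assert V[r1, r2] == 0.0
        day_idx = {d: i for i, d in enumerate(comps.r_days)}
        for r in range(12):
            t = day_idx[self.model.rec_day[r]]
            q = self.model.rec_trait[r]
            assert V[r, r] == pytest.approx(comps.R[t, q, q])

    def test_single_day_order0_reduces_to_gblup_covariance(self):
        # degenerate random regression = GBLUP: V = s2u G + s2p I + s2e I
        basis = legendre_basis(TimeGrid((5,), 1, 20), 0)
        spec = RRMSpec(traits=("WU",), fixed_order=0, genetic_order=0,
                       pe_order=0)
        grm = toy_grm(4, rho=0.3)
        ph = records([(f"a{i}", "WU", 5, 0.0) for i in range(4)])
        model = build_design(ph, basis, spec, grm)
        s2u, s2p, s2e = 1.7, 0.6, 0.9
        comps = CovarianceComponents(np.array([[s2u]]), np.array([[s2p]]),
                                     np.full((1, 1, 1), s2e), (5,))
        V = realized_covariance(model, comps)
        expected = s2u * grm.matrix + (s2p + s2e) * np.eye(4)
        np.testing.assert_allclose(V, expected, atol=1e-12)

    def test_monte_carlo_covariance_oracle(self):
        # brute-force draws of u, p, e on the 3-accession x 2-day instance
        comps = bivariate_comps(scale=0.5)
        V = realized_covariance(self.model, comps)
        rng = np.random.default_rng(42)
        n_draw = 100_000
        G = self.model.G
        Lg = np.linalg.cholesky(G + 1e-10 * np.eye(3))
        Lc = np.linalg.cholesky(comps.C)
        Ld = np.linalg.cholesky(comps.D)
        Lr = np.linalg.cholesky(comps.R)
        A = self.model.design
        j = self.model.rec_acc
        day_idx = {d: i for i, d in enumerate(comps.r_days)}
        t_of = np.array([day_idx[d] for d in self.model.rec_day])
        q_of = self.model.rec_trait
        u = np.einsum("ij,njm,km->nik", Lg,
                      rng.standard_normal((n_draw, 3, 6)), Lc)
        p = np.einsum("njm,km->njk", rng.standard_normal((n_draw, 3, 6)), Ld)
        z = rng.standard_normal((n_draw, 3, 2, 2))
        e = np.einsum("tqr,njtr->njtq", Lr, z)
        y = (np.einsum("ri,nri->nr", A, (u + p)[:, j, :])
             + e[:, j, t_of, q_of])
        emp = np.cov(y.T)
        se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V ** 2) / n_draw)
        assert np.all(np.abs(emp - V) < 5 * se + 1e-12)

    def test_genetic_variance_at_day_formula(self):
        # Var(genetic value at day t) = phi C1 phi' * G, checked by simulation
        comps = bivariate_comps(scale=0.3)
        rng = np.random.default_rng(9)
        G = self.grm.matrix
        Lg = np.linalg.cholesky(G + 1e-10 * np.eye(3))
        Lc = np.linalg.cholesky(comps.C)
        u = np.einsum("ij,njm,km->nik", Lg,
                      rng.standard_normal((60_000, 3, 6)), Lc)
        phi = self.basis.phi[0]
        gv = np.einsum("k,nik->ni", phi, u[:, :, :3])
        emp = np.cov(gv.T)
        expected = float(phi @ comps.C[:3, :3] @ phi) * G
        assert np.abs(emp - expected).max() < 0.05 * expected.max()

    def test_trait_swap_conjugates_components(self, basis20):
        comps = bivariate_comps(n_days=20, seed=3)
        K = 3
        perm = np.r_[K:2 * K, 0:K]
        swapped = CovarianceComponents(comps.C[np.ix_(perm, perm)],
                                       comps.D[np.ix_(perm, perm)],
                                       comps.R[:, ::-1, ::-1],
                                       comps.r_days)
        from rrgp.summaries import genomic_correlation, heritability
        np.testing.assert_allclose(
            genomic_correlation(comps, basis20),
            genomic_correlation(swapped, basis20), atol=1e-12)
        np.testing.assert_allclose(heritability(comps, basis20, 0),
                                   heritability(swapped, basis20, 1),
                                   atol=1e-12)
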