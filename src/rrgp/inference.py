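"""Variance-component estimation and BLUP/BLUE solving for random regression models.

Two complementary routes:

* :func:`solve_mme` — the deterministic solve of Henderson's mixed model
  equations at fixed covariance components (used for all cross-validation
  predictions, mirroring a "fixed variance" run of a Bayesian MME solver);
* :func:`gibbs_sample` — a blocked Gibbs sampler over location effects and
  covariance components with conjugate updates: multivariate-normal full
  conditionals per accession for the coefficient vectors, inverse-Wishart for
  the genetic (C) and permanent-environment (D) coefficient covariances, and
  per-day inverse-Wishart / scaled-inverse-chi-square updates for the
  heterogeneous residual blocks R(t).

Genetic values of accessions without any phenotype records are obtained from
:func:`predict_unphenotyped`, which projects training genetic-value
trajectories through the genomic relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from ._kernels import gibbs_location_sweep
from .basis import BasisMatrix
from .geno import GRM
from .model import AssembledModel, CovarianceComponents

__all__ = [
    "GibbsConfig",
    "RRMSolutions",
    "PosteriorDraws",
    "solve_mme",
    "gibbs_sample",
    "predict_unphenotyped",
    "effective_sample_size",
]

DEFAULT_RIDGE = 1e-6


@dataclass(frozen=True)
class GibbsConfig:
    """Chain controls and priors for the Gibbs sampler.

    Priors: flat on fixed effects; inverse-Wishart(df = M + 2) on C and D and
    inverse-Wishart(df = n_traits + 2) per residual day block (a scaled
    inverse chi-square for one trait). With the default
    ``prior_scale_cd=None`` the scale matrices are centered on the
    method-of-moments starting estimates at the minimal proper degrees of
    freedom — a weakly informative, data-scaled prior. A scalar sets
    scale * I instead; beware that a very small scalar concentrates
    substantial prior mass at zero variance (the inverse-Wishart with a tiny
    scale is a spike at the origin, which can absorb a weakly identified
    component). When ``fixed_variances`` is set, variance sampling is
    disabled and only the location effects are drawn.
    """

    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    prior_scale_cd: float | None = None
    prior_scale_r: float | None = None
    fixed_variances: CovarianceComponents | None = None
    save_draws: bool = True
    ridge: float = DEFAULT_RIDGE

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be below n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class RRMSolutions:
    """Fixed coefficients plus per-accession random regression coefficients.

    ``u`` and ``p`` are accession-major (n x M) with M = n_traits * (order+1);
    the genetic trajectory of accession j for trait q at day t is
    phi(t) . u[j, q-block].
    """

    b: np.ndarray
    u: np.ndarray
    p: np.ndarray
    accession_ids: tuple
    basis: BasisMatrix
    traits: tuple

    @property
    def n_coef(self) -> int:
        return self.b.shape[0] // len(self.traits)

    def _trait_index(self, trait) -> int:
        if isinstance(trait, (int, np.integer)):
            return int(trait)
        return self.traits.index(trait)

    def coef_block(self, which: str, trait=0) -> np.ndarray:
        q = self._trait_index(trait)
        K = self.n_coef
        mat = {"b": self.b[None, :], "u": self.u, "p": self.p}[which]
        return mat[:, q * K:(q + 1) * K]

    def genetic_values(self, trait=0, days=None) -> np.ndarray:
        """n_accessions x n_days matrix of genetic values phi(t) u."""
        days = self.basis.grid.days if days is None else days
        phi = self.basis.evaluate(np.asarray(days))
        return self.coef_block("u", trait) @ phi.T

    def mean_trajectory(self, trait=0, days=None) -> np.ndarray:
        days = self.basis.grid.days if days is None else days
        phi = self.basis.evaluate(np.asarray(days))
        return phi @ self.coef_block("b", trait)[0]


# ---------------------------------------------------------------------------
# residual precision helpers

def _residual_precisions(comps: CovarianceComponents):
    """Per-day full inverse blocks and marginal per-trait precisions."""
    n_days, T, _ = comps.R.shape
    rinv_full = np.zeros_like(comps.R)
    for t in range(n_days):
        rinv_full[t] = np.linalg.inv(comps.R[t])
    diag = np.einsum("tqq->tq", comps.R)
    rinv_marg = 1.0 / diag
    return rinv_full, rinv_marg


def _day_positions(model: AssembledModel, comps: CovarianceComponents) -> np.ndarray:
    idx = comps.r_day_index()
    missing = set(model.observed_days()) - set(comps.r_days)
    if missing:
        raise ValueError(f"no residual block for observed days {sorted(missing)}")
    return np.asarray([idx[d] for d in model.rec_day], dtype=np.int64)


def _group_structure(model: AssembledModel):
    """Group pointers by (accession, day) and per-accession group pointers."""
    grp_ptr = model.day_groups().astype(np.int64)
    acc_of_group = model.rec_acc[grp_ptr[:-1]]
    n = model.n_accessions
    acc_grp_ptr = np.searchsorted(acc_of_group, np.arange(n + 1)).astype(np.int64)
    return grp_ptr, acc_grp_ptr


def _apply_rinv(model, comps, day_pos, vec_or_rows):
    """Apply the block-diagonal residual precision to a record-indexed array."""
    rinv_full, rinv_marg = _residual_precisions(comps)
    grp_ptr, _ = _group_structure(model)
    sizes = np.diff(grp_ptr)
    out = np.array(vec_or_rows, dtype=float)
    x = vec_or_rows
    # singles: marginal precision
    single_idx = grp_ptr[:-1][sizes == 1]
    w = rinv_marg[day_pos[single_idx], model.rec_trait[single_idx]]
    out[single_idx] = (x[single_idx].T * w).T
    # pairs: 2x2 block
    pair_i0 = grp_ptr[:-1][sizes == 2]
    if pair_i0.size:
        t = day_pos[pair_i0]
        r00 = rinv_full[t, 0, 0]
        r01 = rinv_full[t, 0, 1]
        r11 = rinv_full[t, 1, 1]
        x0, x1 = x[pair_i0], x[pair_i0 + 1]
        out[pair_i0] = (x0.T * r00 + x1.T * r01).T
        out[pair_i0 + 1] = (x0.T * r01 + x1.T * r11).T
    return out


def _weighted_products(model: AssembledModel, comps: CovarianceComponents):
    """Per-accession normal-equation blocks W_j = A_j' Rinv A_j and A_j' Rinv y_j."""
    day_pos = _day_positions(model, comps)
    A = model.design
    RA = _apply_rinv(model, comps, day_pos, A)
    Ry = _apply_rinv(model, comps, day_pos, model.y)
    n, M = model.n_accessions, model.coef_dim
    Wj = np.zeros((n, M, M))
    rhs_j = np.zeros((n, M))
    # records are sorted by accession: segment boundaries
    bounds = np.searchsorted(model.rec_acc, np.arange(n + 1))
    for j in range(n):
        a0, a1 = bounds[j], bounds[j + 1]
        if a1 > a0:
            Aj = A[a0:a1]
            Wj[j] = Aj.T @ RA[a0:a1]
            rhs_j[j] = Aj.T @ Ry[a0:a1]
    return Wj, rhs_j


def solve_mme(model: AssembledModel, comps: CovarianceComponents,
              ridge: float = DEFAULT_RIDGE, return_lhs: bool = False):
    """Solve Henderson's mixed model equations at fixed covariance components.

    The joint system over [b, u, p] uses Var(u) = C (x) G (with G ridged
    before inversion), Var(p) = D (x) I and the per-day residual blocks.
    Returns :class:`RRMSolutions`; with ``return_lhs`` the (dense, symmetric
    positive-definite) coefficient matrix and right-hand side are also
    returned for verification.
    """
    n, M = model.n_accessions, model.coef_dim
    if comps.C.shape[0] != M:
        raise ValueError("component dimension does not match model")
    Wj, rhs_j = _weighted_products(model, comps)

    Ginv = np.linalg.inv(model.G + ridge * np.eye(n))
    try:
        Cinv = np.linalg.inv(comps.C)
        Dinv = np.linalg.inv(comps.D)
    except np.linalg.LinAlgError as err:
        raise ValueError("C and D must be invertible (positive definite)") from err

    size = M + 2 * n * M
    lhs = np.zeros((size, size))
    rhs = np.zeros(size)
    sl_b = slice(0, M)
    sl_u = slice(M, M + n * M)
    sl_p = slice(M + n * M, size)

    lhs[sl_b, sl_b] = Wj.sum(axis=0)
    rhs[sl_b] = rhs_j.sum(axis=0)
    # horizontal stacks of W_j couple b with each accession's u_j and p_j
    Wrow = Wj.transpose(1, 0, 2).reshape(M, n * M)
    lhs[sl_b, sl_u] = Wrow
    lhs[sl_u, sl_b] = Wrow.T
    lhs[sl_b, sl_p] = Wrow
    lhs[sl_p, sl_b] = Wrow.T

    bd = np.zeros((n * M, n * M))
    for j in range(n):
        bd[j * M:(j + 1) * M, j * M:(j + 1) * M] = Wj[j]
    lhs[sl_u, sl_u] = bd + np.kron(Ginv, Cinv)
    lhs[sl_u, sl_p] = bd
    lhs[sl_p, sl_u] = bd
    lhs[sl_p, sl_p] = bd + np.kron(np.eye(n), Dinv)
    rhs[sl_u] = rhs_j.reshape(-1)
    rhs[sl_p] = rhs_j.reshape(-1)

    try:
        cf = sla.cho_factor(lhs, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular mixed-model equations; check component "
                         "positive-definiteness and data support") from err
    sol = sla.cho_solve(cf, rhs, check_finite=False)
    sols = RRMSolutions(b=sol[sl_b], u=sol[sl_u].reshape(n, M),
                        p=sol[sl_p].reshape(n, M),
                        accession_ids=model.accession_ids,
                        basis=model.basis, traits=model.spec.traits)
    if return_lhs:
        return sols, lhs, rhs
    return sols


# ---------------------------------------------------------------------------
# Gibbs sampling

def _invwishart_draw(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition.

    X ~ IW(df, scale): draw W ~ Wishart(df, scale^{-1}) and invert.
    """
    p = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    LA = L @ A
    W = LA @ LA.T
    X = np.linalg.inv(W)
    return (X + X.T) / 2


def _scaled_invchi2_draw(rng, df: float, sum_sq: float) -> float:
    return sum_sq / rng.chisquare(df)


# -- partially collapsed scale move ----------------------------------------
# The conjugate updates of C and D condition on the current split of each
# accession's total effect t_j = u_j + p_j, but the data identify that split
# only weakly per accession, so the (C, D) partition mixes extremely slowly
# and can stall in a degenerate basin (all variance genetic or all permanent
# environment). The fix: in the eigenbasis of G the totals are independent,
# t_k ~ N(0, lambda_k C + D), so p(C, D | t) is available with the split
# integrated out. A Metropolis step rescales the per-trait blocks of C and D
# against that collapsed density, after which the split is redrawn exactly
# from its Gaussian conditional. This leaves the posterior invariant and
# traverses the genetic/permanent-environment trade-off in a few moves.

def _collapsed_loglik(t: np.ndarray, lam: np.ndarray, C: np.ndarray,
                      D: np.ndarray) -> float:
    S = lam[:, None, None] * C + D
    L = np.linalg.cholesky(S)
    logdet = 2.0 * np.sum(np.log(np.einsum("kii->ki", L)))
    sol = np.linalg.solve(S, t[..., None])[..., 0]
    quad = np.einsum("ki,ki->", t, sol)
    return -0.5 * (logdet + quad)


def _iw_logpdf_unnorm(X: np.ndarray, df: float, scale: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(X)
    if sign <= 0:
        return -np.inf
    p = X.shape[0]
    return -0.5 * (df + p + 1) * ld - 0.5 * np.trace(scale @ np.linalg.inv(X))


def _block_scale_move(rng, t, lam, C, D, n_traits, n_coef, df0, S0_C, S0_D,
                      step=0.2, n_steps=3):
    """Metropolis rescaling of per-trait blocks of C and D given totals t."""
    M = C.shape[0]
    ll = _collapsed_loglik(t, lam, C, D)
    lp = (_iw_logpdf_unnorm(C, df0, S0_C) + _iw_logpdf_unnorm(D, df0, S0_D))
    for _ in range(n_steps):
        z = step * rng.standard_normal(2 * n_traits)
        sC = np.exp(np.repeat(z[:n_traits], n_coef))
        sD = np.exp(np.repeat(z[n_traits:], n_coef))
        C2 = C * np.outer(sC, sC)
        D2 = D * np.outer(sD, sD)
        ll2 = _collapsed_loglik(t, lam, C2, D2)
        lp2 = (_iw_logpdf_unnorm(C2, df0, S0_C) + _iw_logpdf_unnorm(D2, df0, S0_D))
        log_jac = (M + 1) * n_coef * float(np.sum(z))
        if np.log(rng.uniform()) < (ll2 + lp2 + log_jac) - (ll + lp):
            C, D, ll, lp = C2, D2, ll2, lp2
    return C, D


def _resample_split(rng, t, lam, C, D):
    """Draw u | t exactly: u_k ~ N(Su S^-1 t_k, Su - Su S^-1 Su), Su = lam_k C."""
    n, M = t.shape
    Su = lam[:, None, None] * C
    S = Su + D
    Sinv_t = np.linalg.solve(S, t[..., None])
    mean = (Su @ Sinv_t)[..., 0]
    cov = Su - Su @ np.linalg.solve(S, Su)
    cov = 0.5 * (cov + np.swapaxes(cov, 1, 2)) + 1e-12 * np.eye(M)
    L = np.linalg.cholesky(cov)
    U = mean + (L @ rng.standard_normal((n, M, 1)))[..., 0]
    return U, t - U


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained covariance draws plus posterior-mean location solutions."""

    C_draws: np.ndarray          # n_kept x M x M
    D_draws: np.ndarray
    R_draws: np.ndarray          # n_kept x n_days x T x T
    r_days: tuple
    location_mean: RRMSolutions
    config: GibbsConfig

    @property
    def n_kept(self) -> int:
        return self.C_draws.shape[0]

    def posterior_mean(self) -> CovarianceComponents:
        return CovarianceComponents(C=self.C_draws.mean(axis=0),
                                    D=self.D_draws.mean(axis=0),
                                    R=self.R_draws.mean(axis=0),
                                    r_days=self.r_days)

    def ess(self) -> dict:
        """Effective sample sizes of the retained C/D diagonal traces."""
        out = {}
        for name, draws in (("C", self.C_draws), ("D", self.D_draws)):
            for k in range(draws.shape[1]):
                out[f"{name}[{k},{k}]"] = effective_sample_size(draws[:, k, k])
        return out


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial positive sequence of autocorrelations (Geyer)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    # sum consecutive pairs until a pair sum goes non-positive
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / tau))


def _initial_components(model: AssembledModel, r_days: tuple) -> CovarianceComponents:
    """Starting values: split the day-detrended phenotypic variance.

    The mean trajectory is removed per (trait, day) before taking the
    variance across accessions, so the start is on the scale of the random
    effects rather than of the raw records.
    """
    T, K = model.spec.n_traits, model.spec.n_coef
    var_q = np.ones(T)
    for q in range(T):
        mask = model.rec_trait == q
        vals = model.y[mask]
        days = model.rec_day[mask]
        if vals.size > 1:
            uniq, inv = np.unique(days, return_inverse=True)
            means = np.bincount(inv, weights=vals) / np.bincount(inv)
            var_q[q] = max(np.var(vals - means[inv]), 1e-8)
    diag = np.repeat(var_q, K)
    C0 = np.diag(0.4 * diag)
    D0 = np.diag(0.2 * diag)
    R0 = np.zeros((len(r_days), T, T))
    for q in range(T):
        R0[:, q, q] = 0.4 * var_q[q]
    return CovarianceComponents(C=C0, D=D0, R=R0, r_days=r_days)


def _moment_init(model: AssembledModel, r_days: tuple, lam: np.ndarray,
                 V: np.ndarray) -> CovarianceComponents | None:
    """Method-of-moments starting values for accession-balanced data.

    Per-accession least squares on the shared design estimates the total
    coefficient vectors t_j = u_j + p_j. Two noise-robust moment equations
    then separate the components:

    * cross-accession products are free of estimation noise and of the
      permanent-environment term, E[t_i t_j'] = G_ij C for i != j, giving C
      by a scalar regression on the off-diagonal G;
    * the mean self product corrects for estimation noise,
      E[t_i t_i'] = G_ii C + D + E with E the (known-form) least-squares
      sampling covariance built from the per-day residual blocks, giving D
      once C is known.

    Results are clipped to positive definiteness. A start in the right basin
    matters because the genetic/permanent-environment partition of the
    posterior can be multimodal, and directions the data window constrains
    weakly stay anchored to these estimates through the prior.
    """
    n = model.n_accessions
    Mdim = model.coef_dim
    bounds = np.searchsorted(model.rec_acc, np.arange(n + 1))
    cells = bounds[1] - bounds[0]
    if cells <= Mdim:
        return None
    A = model.design[:cells]
    Y = model.y.reshape(n, cells)
    Yt = Y - Y.mean(axis=0)

    def ls_fit(cols):
        Asub = A[cols]
        AtA = Asub.T @ Asub
        if np.linalg.cond(AtA) > 1e8:
            return None
        return Yt[:, cols] @ Asub @ np.linalg.inv(AtA)

    T_hat = ls_fit(np.arange(cells))
    if T_hat is None:
        return None

    # residual blocks per day (df-corrected for the per-accession fit)
    T_tr = model.spec.n_traits
    day_of_cell = model.rec_day[:cells]
    trait_of_cell = model.rec_trait[:cells]
    n_days = len(r_days)
    day_idx = {d: i for i, d in enumerate(r_days)}
    resid = Yt - T_hat @ A.T
    resid = resid * np.sqrt(cells / max(cells - Mdim, 1))
    R0 = np.zeros((n_days, T_tr, T_tr))
    for c1 in range(cells):
        t1 = day_idx[day_of_cell[c1]]
        for c2 in range(cells):
            if day_of_cell[c2] == day_of_cell[c1]:
                R0[t1, trait_of_cell[c1], trait_of_cell[c2]] += \
                    resid[:, c1] @ resid[:, c2] / n
    for t in range(n_days):
        for q in range(T_tr):
            if R0[t, q, q] <= 0:
                R0[t, q, q] = 1e-6
        if T_tr == 2:
            cap = 0.9 * np.sqrt(R0[t, 0, 0] * R0[t, 1, 1])
            R0[t, 0, 1] = R0[t, 1, 0] = np.clip(R0[t, 0, 1], -cap, cap)

    # C from cross-accession products
    G = model.G
    g_diag = np.diag(G)
    num = T_hat.T @ G @ T_hat - (T_hat * g_diag[:, None]).T @ T_hat
    den = float((G ** 2).sum() - (g_diag ** 2).sum())
    if den <= 0:
        return None
    C0 = (num + num.T) / (2 * den)

    # D from noise-corrected self products: mean_i t_i t_i' = mean(G_ii) C
    # + D + E, with E the least-squares sampling covariance of t_hat
    Rrec = np.zeros((cells, cells))
    for c1 in range(cells):
        for c2 in range(cells):
            if day_of_cell[c1] == day_of_cell[c2]:
                Rrec[c1, c2] = R0[day_idx[day_of_cell[c1]],
                                  trait_of_cell[c1], trait_of_cell[c2]]
    AtA_inv = np.linalg.inv(A.T @ A + 1e-10 * np.eye(Mdim))
    E = AtA_inv @ (A.T @ Rrec @ A) @ AtA_inv
    M2 = (T_hat[:, :, None] * T_hat[:, None, :]).mean(axis=0)
    D0 = (M2 + M2.T) / 2 - g_diag.mean() * C0 - E

    # clip to PSD on the correlation scale: the traits (and polynomial
    # orders) live on very different scales, and flooring eigenvalues of the
    # raw matrix would inflate the small-scale coefficients' variances. The
    # per-coefficient scale comes from the (noisy but strictly positive)
    # self-moment diagonal.
    M2d = np.einsum("ni,ni->i", T_hat, T_hat) / n
    scale = np.sqrt(np.maximum(M2d, 1e-12))

    def psd_clip(X, floor_frac=1e-3):
        Xn = (X + X.T) / 2 / np.outer(scale, scale)
        w, Q = np.linalg.eigh(Xn)
        floor = max(w.max(), 1e-8) * floor_frac
        Xn = (Q * np.maximum(w, floor)) @ Q.T
        return Xn * np.outer(scale, scale)

    return CovarianceComponents(C=psd_clip(C0), D=psd_clip(D0), R=R0,
                                r_days=r_days)


def gibbs_sample(model: AssembledModel, cfg: GibbsConfig) -> PosteriorDraws:
    """Run the blocked Gibbs sampler and return retained draws.

    Sweep per iteration: (1) every accession's genetic and permanent-
    environment coefficient vectors and the fixed coefficients from their
    normal full conditionals; (2) C from IW(nu0 + n, S0 + U' Ginv U);
    (3) D from IW(nu0 + n, S0 + P' P); (4) each day's residual block from its
    conjugate conditional — full 2x2 inverse-Wishart where both traits are
    recorded that day, per-trait scaled inverse chi-square otherwise.
    Reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, M = model.n_accessions, model.coef_dim
    T, K = model.spec.n_traits, model.spec.n_coef
    n_rec = model.n_records

    fixed = cfg.fixed_variances
    if fixed is not None:
        r_days = fixed.r_days
        comps = fixed
        if comps.C.shape[0] != M:
            raise ValueError("fixed_variances dimension mismatch")
    else:
        r_days = tuple(int(d) for d in model.observed_days())
        comps = None
    day_pos = _day_positions(
        model, comps if comps is not None
        else CovarianceComponents(np.eye(M), np.eye(M),
                                  np.tile(np.eye(T), (len(r_days), 1, 1)),
                                  r_days))
    grp_ptr, acc_grp_ptr = _group_structure(model)
    sizes = np.diff(grp_ptr)

    # per-day residual index sets for the variance updates
    n_days = len(r_days)
    pair_idx: list[np.ndarray] = []
    single_idx: list[list[np.ndarray]] = []
    g_start = grp_ptr[:-1]
    g_day = day_pos[g_start]
    for t in range(n_days):
        here = g_day == t
        pair_idx.append(g_start[here & (sizes == 2)])
        per_trait = []
        for q in range(T):
            s = g_start[here & (sizes == 1)]
            per_trait.append(s[model.rec_trait[s] == q])
        single_idx.append(per_trait)

    # Accession-balanced data (every accession carries the same (day, trait)
    # pattern) are rotated into the eigenbasis of G: the prior on the rotated
    # genetic coefficients is diagonal across eigen-accessions, which removes
    # the near-degenerate sum constraint a centered (singular) G imposes and
    # restores fast mixing. The rotated model has identical structure except
    # that the overall-mean covariates are scaled by (V' 1)_k per eigen-row.
    bounds = np.searchsorted(model.rec_acc, np.arange(n + 1))
    cells = np.diff(bounds)
    balanced = bool(cells.size and np.all(cells == cells[0]))
    if balanced and n > 1:
        pat = (day_pos * 4 + model.rec_trait).reshape(n, cells[0])
        balanced = bool(np.all(pat == pat[0]))
    y_obs = model.y
    if balanced:
        lam, V = np.linalg.eigh(model.G + cfg.ridge * np.eye(n))
        Ginv = np.diag(1.0 / lam)
        fixw = V.T @ np.ones(n)
        y_obs = (V.T @ model.y.reshape(n, cells[0])).ravel()
    else:
        lam = V = None
        Ginv = np.linalg.inv(model.G + cfg.ridge * np.eye(n))
        fixw = np.ones(n)

    if comps is None:
        if balanced:
            comps = _moment_init(model, r_days, lam, V)
        if comps is None:
            comps = _initial_components(model, r_days)

    C = np.array(comps.C)
    D = np.array(comps.D)
    R = np.array(comps.R)
    Cinv, Dinv = np.linalg.inv(C), np.linalg.inv(D)
    rinv_full, rinv_marg = _residual_precisions(comps)

    b = np.zeros(M)
    U = np.zeros((n, M))
    P = np.zeros((n, M))
    S = Ginv @ U
    e = y_obs.copy()
    radd = np.empty(n_rec)
    cols = model.rec_trait[:, None] * K + np.arange(K)[None, :]
    phi_rec = np.ascontiguousarray(np.take_along_axis(model.design, cols, axis=1))

    nu0_cd = M + 2.0
    nu0_r = T + 2.0
    if cfg.prior_scale_cd is None:
        # prior mean at the starting estimates, minimal proper df
        S0_C = np.array(comps.C) * (nu0_cd - M - 1)
        S0_D = np.array(comps.D) * (nu0_cd - M - 1)
    else:
        S0_C = S0_D = cfg.prior_scale_cd * np.eye(M)
    if cfg.prior_scale_r is None:
        S0_R = np.array(comps.R) * (nu0_r - T - 1)
        for t in range(len(r_days)):           # diagonal scale only
            S0_R[t] = np.diag(np.diag(S0_R[t]))
    else:
        S0_R = np.tile(cfg.prior_scale_r * np.eye(T), (len(r_days), 1, 1))

    n_kept = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
    C_draws = np.empty((n_kept, M, M)) if cfg.save_draws else np.empty((0, M, M))
    D_draws = np.empty_like(C_draws)
    R_draws = (np.empty((n_kept, n_days, T, T)) if cfg.save_draws
               else np.empty((0, n_days, T, T)))
    C_sum = np.zeros((M, M))
    D_sum = np.zeros((M, M))
    R_sum = np.zeros((n_days, T, T))
    b_sum = np.zeros(M)
    U_sum = np.zeros((n, M))
    P_sum = np.zeros((n, M))
    kept = 0

    rec_day_idx = day_pos  # kernel indexes Rinv arrays by this
    recq = model.rec_trait.astype(np.int64)
    rec_acc = model.rec_acc.astype(np.int64)

    for it in range(cfg.n_iter):
        z_u = rng.standard_normal((n, M))
        z_p = rng.standard_normal((n, M))
        z_b = rng.standard_normal(M)
        gibbs_location_sweep(e, b, U, P, S, phi_rec, recq, rec_day_idx,
                             rec_acc, grp_ptr, acc_grp_ptr, Ginv, Cinv, Dinv,
                             rinv_full, rinv_marg, fixw, z_u, z_p, z_b, radd)

        if fixed is None:
            C = _invwishart_draw(rng, nu0_cd + n, S0_C + U.T @ S)
            D = _invwishart_draw(rng, nu0_cd + n, S0_D + P.T @ P)
            for t in range(n_days):
                pi = pair_idx[t]
                if pi.size and T == 2:
                    e1, e2 = e[pi], e[pi + 1]
                    scale = np.array([[e1 @ e1, e1 @ e2],
                                      [e1 @ e2, e2 @ e2]]) + S0_R[t]
                    R[t] = _invwishart_draw(rng, nu0_r + pi.size, scale)
                else:
                    for q in range(T):
                        si = single_idx[t][q]
                        if si.size:
                            ee = e[si]
                            R[t, q, q] = _scaled_invchi2_draw(
                                rng, nu0_r + si.size, S0_R[t, q, q] + ee @ ee)
                            if T == 2:
                                R[t, 0, 1] = R[t, 1, 0] = 0.0
            if balanced:
                # partially collapsed move on the C/D partition (see above)
                tot = U + P
                C, D = _block_scale_move(rng, tot, lam, C, D, T, K,
                                         nu0_cd, S0_C, S0_D)
                U, P = _resample_split(rng, tot, lam, C, D)
                S = U / lam[:, None]
            Cinv, Dinv = np.linalg.inv(C), np.linalg.inv(D)
            diag = np.einsum("tqq->tq", R)
            rinv_marg = 1.0 / diag
            for t in range(n_days):
                rinv_full[t] = np.linalg.inv(R[t])

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            if cfg.save_draws:
                C_draws[kept] = C
                D_draws[kept] = D
                R_draws[kept] = R
            C_sum += C
            D_sum += D
            R_sum += R
            b_sum += b
            U_sum += U
            P_sum += P
            kept += 1

    if kept == 0:
        raise RuntimeError("no draws retained; check n_iter/burn_in/thin")
    if balanced:
        # rotate posterior-mean coefficients back to accession space
        U_sum = V @ U_sum
        P_sum = V @ P_sum
    if not cfg.save_draws:
        C_draws = (C_sum / kept)[None, ...]
        D_draws = (D_sum / kept)[None, ...]
        R_draws = (R_sum / kept)[None, ...]
    loc = RRMSolutions(b=b_sum / kept, u=U_sum / kept, p=P_sum / kept,
                       accession_ids=model.accession_ids, basis=model.basis,
                       traits=model.spec.traits)
    return PosteriorDraws(C_draws=C_draws[:kept] if cfg.save_draws else C_draws,
                          D_draws=D_draws[:kept] if cfg.save_draws else D_draws,
                          R_draws=R_draws[:kept] if cfg.save_draws else R_draws,
                          r_days=r_days, location_mean=loc, config=cfg)


# ---------------------------------------------------------------------------
# prediction for unphenotyped accessions

def predict_unphenotyped(grm: GRM, train_ids, test_ids, sols: RRMSolutions,
                         basis: BasisMatrix | None = None, trait=0,
                         days=None, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Genetic values of test accessions by genomic projection.

    a_test(t) = G[test, train] G[train, train]^{-1} a_train(t), with
    a_train(t) = phi(t) . u_train evaluated at every requested day. Returns a
    (n_test x n_days) array.
    """
    train_ids = [str(a) for a in train_ids]
    test_ids = [str(a) for a in test_ids]
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test accessions must be disjoint")
    basis = sols.basis if basis is None else basis
    days = basis.grid.days if days is None else days
    order = {a: i for i, a in enumerate(sols.accession_ids)}
    rows = [order[a] for a in train_ids]
    phi = basis.evaluate(np.asarray(days))
    a_trn = sols.coef_block("u", trait)[rows] @ phi.T
    G_tt = grm.block(train_ids, train_ids) + ridge * np.eye(len(train_ids))
    G_st = grm.block(test_ids, train_ids)
    return G_st @ np.linalg.solve(G_tt, a_trn)
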