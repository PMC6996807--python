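"""Synthetic genotypes and bivariate longitudinal phenotypes.

The generator mirrors the generative assumptions of the random regression
model so that every downstream stage (GRM, design assembly, Gibbs sampling,
cross-validation) can be exercised without external data:

* genotypes — independent biallelic markers, dosage ~ Binomial(2, p) with the
  allele frequency drawn per marker from ``maf_range``;
* phenotypes — y = Phi b + Phi u + Phi p + e with u ~ N(0, C (x) G) (drawn via
  Cholesky factors of C and G), p ~ N(0, D (x) I) and per-day residual pairs
  e ~ N(0, R(t)).

The default covariance components emulate a two-trait greenhouse study of
daily water use (trait 1, "WU") and projected shoot area (trait 2, "PSA") in
a rice diversity panel: 357 accessions, 20 daily records, exponential-shaped
mean trajectories, WU heritability rising from about 0.28 to 0.69, PSA
heritability from about 0.48 to 0.80, and a genomic correlation rising from
weak (~0.38) to strong (~0.8). They are built from a documented low-rank
recipe: both traits load on a shared genetic factor whose variance grows over
time plus a trait-specific factor of constant variance, the permanent-
environment covariance is a scaled copy of the genetic one, and the per-day
residual variances are solved so the formula-implied heritability equals the
target curve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BasisMatrix, TimeGrid, legendre_basis
from .geno import GRM, GenotypeMatrix, compute_grm
from .model import CovarianceComponents, PhenotypeTable

__all__ = [
    "SyntheticConfig",
    "default_components",
    "default_mean_coefs",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_dataset",
    "SimulatedTruth",
]

TRAITS = ("WU", "PSA")

# --- default generator regime -------------------------------------------------
# shared genetic factor: concave quadratic in f = (1+x)/2 rising 0.35 -> 1.0
# (fast early growth, plateau late); trait-specific factors constant with
# variance ratio gamma2 relative to the shared one
_SHARED_CURVE = (0.35, 1.10, -0.45)   # coefficients on 1, f, f^2
_GAMMA2 = (0.20, 0.30)                # specific/shared variance ratio per trait
_SIGMA2_SHARED = (0.05, 13.0)     # shared-factor variance scale per trait
_PE_FRACTION = 0.15               # D = 0.15 * C
_RESID_CORR = 0.30                # residual correlation between traits
# target heritability trajectories (as functions of (1+x)/2 in [0, 1])
_H2_WU = (0.28, 0.69)             # linear rise
_H2_PSA = (0.48, 0.80, 2.0)      # 0.80 - 0.32*(1-s)^2: fast early rise, plateau


def _project_curve(basis: BasisMatrix, values: np.ndarray) -> np.ndarray:
    """Exact basis coefficients of a curve that is polynomial of degree <= order."""
    coefs, *_ = np.linalg.lstsq(basis.phi, values, rcond=None)
    return coefs


def _h2_targets(frac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo1, hi1 = _H2_WU
    h1 = lo1 + (hi1 - lo1) * frac
    lo2, hi2, power = _H2_PSA
    h2 = hi2 - (hi2 - lo2) * (1.0 - frac) ** power
    return h1, h2


def default_components(basis: BasisMatrix) -> CovarianceComponents:
    """Build the default bivariate C, D and per-day R on a basis grid."""
    K = basis.n_coef
    if K != 3:
        raise ValueError("default components are defined for the quadratic basis")
    x = np.asarray([basis.standardize(d) for d in basis.grid.days])
    frac = (1.0 + x) / 2.0
    c0, c1, c2 = _SHARED_CURVE
    shared = c0 + c1 * frac + c2 * frac ** 2
    ws = _project_curve(basis, shared)
    we = np.array([1.0, 0.0, 0.0])  # constant specific curve (phi_0 == 1)

    s1, s2 = _SIGMA2_SHARED
    g1sq, g2sq = _GAMMA2
    C = np.zeros((2 * K, 2 * K))
    # the 1e-3 identity keeps C full rank (invertible at the truth) while
    # perturbing the implied trajectories by well under a percent
    C[:K, :K] = s1 * (np.outer(ws, ws) + g1sq * np.outer(we, we) + 1e-3 * np.eye(K))
    C[K:, K:] = s2 * (np.outer(ws, ws) + g2sq * np.outer(we, we) + 1e-3 * np.eye(K))
    cross = np.sqrt(s1 * s2) * np.outer(ws, ws)
    C[:K, K:] = cross
    C[K:, :K] = cross.T
    D = _PE_FRACTION * C

    phi = basis.phi
    g = np.stack([np.einsum("ij,jk,ik->i", phi, C[:K, :K], phi),
                  np.einsum("ij,jk,ik->i", phi, C[K:, K:], phi)])
    pe = _PE_FRACTION * g
    h_t = np.stack(_h2_targets(frac))
    ve = g * (1.0 - h_t) / h_t - pe
    if np.any(ve <= 0):
        raise ValueError("target heritabilities incompatible with pe fraction")
    n_days = len(basis.grid.days)
    R = np.zeros((n_days, 2, 2))
    R[:, 0, 0] = ve[0]
    R[:, 1, 1] = ve[1]
    R[:, 0, 1] = R[:, 1, 0] = _RESID_CORR * np.sqrt(ve[0] * ve[1])
    return CovarianceComponents(C=C, D=D, R=R, r_days=basis.grid.days)


def default_mean_coefs(basis: BasisMatrix) -> np.ndarray:
    """Basis-projected exponential-shaped mean trajectories (2 x n_coef).

    WU climbs from ~0.2 to ~1.5 (kg water/day), PSA from ~2.5 to ~33
    (scaled pixel counts); both are quadratic-basis projections of
    exponential curves, so the fitted fixed regression is well specified.
    """
    days = np.asarray(basis.grid.days, dtype=float)
    span = days[-1] - days[0]
    wu = 0.15 * np.exp(np.log(10.0) * (days - days[0]) / span)
    psa = 2.0 * np.exp(np.log(16.5) * (days - days[0]) / span)
    return np.stack([_project_curve(basis, wu), _project_curve(basis, psa)])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: 357 accessions x 20 days x 2 traits.

    ``n_markers`` defaults to 2,000 independent markers — GRM-level behavior
    is insensitive to marker count beyond a few hundred. ``components`` and
    ``mean_coefs`` default to the documented regime (built lazily on the
    config's time grid).
    """

    n_accessions: int = 357
    n_markers: int = 2_000
    n_days: int = 20
    maf_range: tuple = (0.05, 0.5)
    n_founders: int | None = 40
    order: int = 2
    components: CovarianceComponents | None = None
    mean_coefs: np.ndarray | None = None
    misspecified_mean: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    def basis(self) -> BasisMatrix:
        return legendre_basis(TimeGrid(tuple(range(1, self.n_days + 1))), self.order)

    def resolved_components(self, basis=None) -> CovarianceComponents:
        return self.components if self.components is not None else \
            default_components(basis or self.basis())

    def resolved_mean_coefs(self, basis=None) -> np.ndarray:
        return self.mean_coefs if self.mean_coefs is not None else \
            default_mean_coefs(basis or self.basis())

    def with_zero_genetic_cross(self) -> "SyntheticConfig":
        """Same regime but no shared genetic architecture (C12 = D12 = 0)."""
        basis = self.basis()
        comps = self.resolved_components(basis)
        K = comps.n_coef
        C = comps.C.copy()
        D = comps.D.copy()
        C[:K, K:] = C[K:, :K] = 0.0
        D[:K, K:] = D[K:, :K] = 0.0
        zero = CovarianceComponents(C=C, D=D, R=comps.R, r_days=comps.r_days)
        return SyntheticConfig(**{**self.__dict__, "components": zero})


@dataclass(frozen=True)
class SimulatedTruth:
    """Generative ground truth kept for diagnostics and recovery tests."""

    components: CovarianceComponents
    mean_coefs: np.ndarray
    u: np.ndarray                 # n x 2K genetic coefficients
    p: np.ndarray
    genetic_values: dict          # trait index -> n x n_days Phi u
    basis: BasisMatrix


def simulate_genotypes(cfg: SyntheticConfig, rng=None) -> GenotypeMatrix:
    """Biallelic markers with family relatedness among accessions.

    Per marker the allele frequency is drawn from ``maf_range``. A founder set
    of ``n_founders`` accessions gets independent Binomial(2, p) dosages; every
    remaining accession descends from two random founders, receiving one
    gamete from each (an allele drawn per marker with probability dosage/2).
    The resulting panel carries half/full-sib-like blocks in the genomic
    relationship matrix — the relatedness structure that makes genetic and
    permanent-environment variance separable, standing in for the strong
    population structure of a real diversity panel. ``n_founders=None``
    produces plain independent accessions instead.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    n = cfg.n_accessions
    if cfg.n_founders is None or cfg.n_founders >= n:
        dosages = rng.binomial(2, p[None, :], size=(n, cfg.n_markers))
    else:
        nf = cfg.n_founders
        founders = rng.binomial(2, p[None, :], size=(nf, cfg.n_markers))
        parents = rng.integers(0, nf, size=(n - nf, 2))
        g1 = rng.binomial(1, founders[parents[:, 0]] / 2.0)
        g2 = rng.binomial(1, founders[parents[:, 1]] / 2.0)
        dosages = np.vstack([founders, g1 + g2])
    acc = tuple(f"acc{i:04d}" for i in range(n))
    markers = tuple(f"snp{i:05d}" for i in range(cfg.n_markers))
    return GenotypeMatrix(acc, markers, dosages)


def simulate_traits(geno: GenotypeMatrix, cfg: SyntheticConfig,
                    basis: BasisMatrix | None = None, rng=None,
                    grm: GRM | None = None) -> tuple[PhenotypeTable, SimulatedTruth]:
    """Draw coefficients and residuals from the generative model.

    Returns complete bivariate records for every accession and day plus the
    ground truth (true coefficients and per-day genetic values).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    basis = cfg.basis() if basis is None else basis
    comps = cfg.resolved_components(basis)
    mean_coefs = cfg.resolved_mean_coefs(basis)
    K = basis.n_coef
    n = geno.n_accessions
    if grm is None:
        variable = geno.dosages.std(axis=0) > 0
        grm = compute_grm(geno if variable.all()
                          else geno.subset_markers(variable))

    # u accession-major: Cov(vec rows) = G (x) C  ->  u = Lg Z Lc'
    # (eigen square roots tolerate PSD-singular C or D, e.g. D = 0)
    def psd_sqrt(mat):
        w, Q = np.linalg.eigh(mat)
        return Q * np.sqrt(np.maximum(w, 0.0))

    Lc = psd_sqrt(comps.C)
    Ld = psd_sqrt(comps.D)
    Lg = np.linalg.cholesky(grm.matrix + 1e-6 * np.eye(n))
    u = Lg @ rng.standard_normal((n, 2 * K)) @ Lc.T
    p = rng.standard_normal((n, 2 * K)) @ Ld.T

    phi = basis.phi
    days = np.asarray(basis.grid.days)
    n_days = len(days)
    traj = {q: u[:, q * K:(q + 1) * K] @ phi.T for q in range(2)}
    pe_traj = {q: p[:, q * K:(q + 1) * K] @ phi.T for q in range(2)}

    if cfg.misspecified_mean:
        span = days[-1] - days[0]
        mean = np.stack([0.15 * np.exp(np.log(10.0) * (days - days[0]) / span),
                         2.0 * np.exp(np.log(16.5) * (days - days[0]) / span)])
    else:
        mean = np.stack([phi @ mean_coefs[0], phi @ mean_coefs[1]])

    # residual pairs per (accession, day); eigen square root tolerates the
    # noise-free limit R(t) = 0
    w, Q = np.linalg.eigh(comps.R)            # n_days x 2 / x 2 x 2
    Lr = Q * np.sqrt(np.maximum(w, 0.0))[:, None, :]
    z = rng.standard_normal((n, n_days, 2))
    e = np.einsum("tqr,ntr->ntq", Lr, z)

    frames = []
    for q, trait in enumerate(TRAITS):
        vals = mean[q][None, :] + traj[q] + pe_traj[q] + e[:, :, q]
        frames.append(pd.DataFrame({
            "accession": np.repeat(list(geno.accession_ids), n_days),
            "trait": trait,
            "day": np.tile(days, n),
            "value": vals.ravel(),
        }))
    phenos = PhenotypeTable(pd.concat(frames, ignore_index=True))
    truth = SimulatedTruth(components=comps, mean_coefs=mean_coefs, u=u, p=p,
                           genetic_values=traj, basis=basis)
    return phenos, truth


def simulate_dataset(cfg: SyntheticConfig):
    """Genotypes, GRM, phenotypes and truth from one master seed.

    Markers that drift to monomorphic during family sampling are dropped
    before the GRM (they carry no relationship information and would make
    column scaling degenerate).
    """
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg, rng)
    variable = geno.dosages.std(axis=0) > 0
    if not variable.all():
        geno = geno.subset_markers(variable)
    grm = compute_grm(geno)
    phenos, truth = simulate_traits(geno, cfg, rng=rng, grm=grm)
    return geno, grm, phenos, truth
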