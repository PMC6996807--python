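"""Design assembly for single- and multi-trait random regression models.

The observation model is y = X b + Z u + Q p + e with

* b  — fixed regression coefficients (one mean trajectory per trait),
* u  — additive genetic regression coefficients, Var(u) = C (x) G,
* p  — permanent-environment coefficients, Var(p) = D (x) I,
* e  — residuals with one (co)variance block R(t) per day of measurement.

(x) denotes the Kronecker product with the coefficient index outer and the
accession index inner, i.e. the vector u stacks, for each (trait, polynomial
order) pair, the coefficients of all accessions. Internally coefficients are
held accession-major (an n x M matrix, M = n_traits * (order+1)); in that
layout the same covariance is G (x) C. One ordering is fixed globally and
verified against a brute-force realized covariance in the tests, because a
silent Kronecker-ordering mismatch is the classic random-regression bug.

Every observation row for (accession j, trait q, day t) carries the basis row
phi(t) in trait q's coefficient block of X, Z and Q; missing (accession, day)
combinations simply contribute no row, so unbalanced data are supported
without imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BasisMatrix
from .geno import GRM

__all__ = [
    "PhenotypeTable",
    "RRMSpec",
    "CovarianceComponents",
    "AssembledModel",
    "build_design",
    "realized_covariance",
]


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format phenotype records: (accession, trait, day, value).

    Values are first-stage adjusted means (BLUEs) of the trait on a given day.
    At most one record per (accession, trait, day).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"accession", "trait", "day", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        df = df.copy()
        df["accession"] = df["accession"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["day"] = df["day"].astype(int)
        df["value"] = df["value"].astype(float)
        if df.duplicated(["accession", "trait", "day"]).any():
            raise ValueError("duplicate (accession, trait, day) records")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @classmethod
    def from_arrays(cls, accession, trait, day, value) -> "PhenotypeTable":
        return cls(pd.DataFrame({"accession": accession, "trait": trait,
                                 "day": day, "value": value}))

    def traits(self) -> tuple:
        return tuple(pd.unique(self.records["trait"]))

    def days(self) -> tuple:
        return tuple(sorted(self.records["day"].unique()))

    def accessions(self) -> tuple:
        return tuple(pd.unique(self.records["accession"]))

    def subset(self, accessions=None, traits=None, days=None) -> "PhenotypeTable":
        df = self.records
        mask = np.ones(len(df), dtype=bool)
        if accessions is not None:
            mask &= df["accession"].isin([str(a) for a in accessions]).to_numpy()
        if traits is not None:
            mask &= df["trait"].isin(list(traits)).to_numpy()
        if days is not None:
            mask &= df["day"].isin(list(days)).to_numpy()
        return PhenotypeTable(df.loc[mask])

    def to_csv(self, path, sep="\t") -> None:
        self.records.to_csv(path, sep=sep, index=False)

    @classmethod
    def read_csv(cls, path, sep=None) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep=sep, engine="python"))


@dataclass(frozen=True)
class RRMSpec:
    """Model structure: traits and polynomial orders of each regression."""

    traits: tuple = ("WU",)
    fixed_order: int = 2
    genetic_order: int = 2
    pe_order: int = 2
    heterogeneous_residual: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", tuple(self.traits))
        if len(self.traits) not in (1, 2):
            raise ValueError("1 or 2 traits supported")
        if min(self.fixed_order, self.genetic_order, self.pe_order) < 0:
            raise ValueError("orders must be >= 0")
        if not (self.fixed_order == self.genetic_order == self.pe_order):
            # one basis serves all three regressions; heterogeneous orders are
            # possible in principle but deliberately unsupported
            raise ValueError("all regression orders must match")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_coef(self) -> int:
        return self.genetic_order + 1

    @property
    def coef_dim(self) -> int:
        """M = n_traits * (order + 1), the per-accession coefficient count."""
        return self.n_traits * self.n_coef


@dataclass(frozen=True)
class CovarianceComponents:
    """C (genetic), D (permanent environment) and per-day residual blocks R(t).

    ``R`` has shape (n_days, n_traits, n_traits), aligned with ``r_days``.
    For two traits C and D carry the block structure [[C1, C12], [C12', C2]]
    with 3x3 sub-blocks at the default quadratic order.
    """

    C: np.ndarray
    D: np.ndarray
    R: np.ndarray
    r_days: tuple

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        D = np.asarray(self.D, dtype=float)
        R = np.asarray(self.R, dtype=float)
        days = tuple(int(d) for d in self.r_days)
        if C.shape != D.shape or C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C and D must be square and of equal size")
        if R.ndim != 3 or R.shape[0] != len(days) or R.shape[1] != R.shape[2]:
            raise ValueError("R must be (n_days, n_traits, n_traits)")
        for name, mat in (("C", C), ("D", D)):
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        if not np.allclose(R, np.swapaxes(R, 1, 2), atol=1e-10):
            raise ValueError("every R(t) must be symmetric")
        object.__setattr__(self, "C", (C + C.T) / 2)
        object.__setattr__(self, "D", (D + D.T) / 2)
        object.__setattr__(self, "R", (R + np.swapaxes(R, 1, 2)) / 2)
        object.__setattr__(self, "r_days", days)

    @property
    def n_traits(self) -> int:
        return self.R.shape[1]

    @property
    def n_coef(self) -> int:
        return self.C.shape[0] // self.n_traits

    def trait_block(self, which: str, q1: int, q2: int) -> np.ndarray:
        """Sub-block of C or D for trait pair (q1, q2)."""
        mat = self.C if which == "C" else self.D
        k = self.n_coef
        return mat[q1 * k:(q1 + 1) * k, q2 * k:(q2 + 1) * k]

    def r_day_index(self) -> dict:
        return {d: i for i, d in enumerate(self.r_days)}

    def to_dict(self) -> dict:
        return {"C": self.C.tolist(), "D": self.D.tolist(),
                "R": self.R.tolist(), "r_days": list(self.r_days)}

    @classmethod
    def from_dict(cls, payload: dict) -> "CovarianceComponents":
        return cls(C=np.asarray(payload["C"]), D=np.asarray(payload["D"]),
                   R=np.asarray(payload["R"]),
                   r_days=tuple(payload["r_days"]))


@dataclass(frozen=True)
class AssembledModel:
    """Observation vector plus implicit sparse design and index maps.

    ``design`` holds, for each record, the M-vector that multiplies either the
    fixed coefficients (X row), the accession's genetic coefficients (the only
    nonzero block of the Z row) or its permanent-environment coefficients (Q
    row) — the three designs share the same per-trait basis covariates.
    Records are sorted by (accession, day, trait) so that residual-covariance
    blocks (both traits of one accession on one day) occupy consecutive rows.
    """

    y: np.ndarray
    design: np.ndarray        # n_records x M
    rec_acc: np.ndarray       # accession index per record
    rec_trait: np.ndarray     # trait index per record
    rec_day: np.ndarray       # calendar day per record
    accession_ids: tuple
    spec: RRMSpec
    basis: BasisMatrix
    grm: GRM
    G: np.ndarray = field(repr=False)   # GRM restricted to model accessions

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def coef_dim(self) -> int:
        return self.spec.coef_dim

    def observed_days(self) -> tuple:
        return tuple(np.unique(self.rec_day))

    def day_groups(self):
        """Start pointers of runs of records sharing (accession, day).

        Returns (ptr,) with ptr of length n_groups+1; records within a group
        are the (at most n_traits) traits of one accession measured that day,
        which share one residual covariance block.
        """
        key = self.rec_acc.astype(np.int64) * 10_000 + self.rec_day.astype(np.int64)
        change = np.flatnonzero(np.diff(key)) + 1
        return np.concatenate([[0], change, [self.n_records]])


def build_design(phenos: PhenotypeTable, basis: BasisMatrix, spec: RRMSpec,
                 grm: GRM, accessions=None,
                 allow_extrapolation: bool = False) -> AssembledModel:
    """Assemble the random regression design from long-format records.

    Every phenotype accession must be present in the GRM; days must lie on the
    basis grid unless ``allow_extrapolation`` permits evaluating phi off-grid.
    ``accessions`` optionally fixes the accession set and order of the random
    effects (a superset of the observed accessions is allowed — accessions
    without records contribute no rows but still receive BLUP solutions).
    """
    df = phenos.records
    trait_index = {t: i for i, t in enumerate(spec.traits)}
    unknown = set(df["trait"]) - set(spec.traits)
    if unknown:
        raise ValueError(f"records carry traits {sorted(unknown)} not in spec {spec.traits}")

    if accessions is None:
        accessions = tuple(pd.unique(df["accession"]))
    else:
        accessions = tuple(str(a) for a in accessions)
        observed = set(df["accession"])
        if not observed.issubset(accessions):
            raise ValueError("accessions= must cover every observed accession")
    acc_index = {a: i for i, a in enumerate(accessions)}
    grm_rows = grm.index_of(accessions)  # raises if absent

    grid_days = set(basis.grid.days)
    obs_days = set(df["day"].unique())
    off_grid = obs_days - grid_days
    if off_grid and not allow_extrapolation:
        raise ValueError(f"days {sorted(off_grid)} outside the basis grid; "
                         "pass allow_extrapolation=True to evaluate phi off-grid")

    rec_acc = df["accession"].map(acc_index).to_numpy(dtype=np.int64)
    rec_trait = df["trait"].map(trait_index).to_numpy(dtype=np.int64)
    rec_day = df["day"].to_numpy(dtype=np.int64)
    y = df["value"].to_numpy(dtype=float)

    order = np.lexsort((rec_trait, rec_day, rec_acc))
    rec_acc, rec_trait, rec_day, y = (a[order] for a in (rec_acc, rec_trait, rec_day, y))

    all_days = np.array(sorted(obs_days | grid_days))
    phi_all = basis.evaluate(all_days)
    day_pos = {d: i for i, d in enumerate(all_days)}
    phi_rec = phi_all[[day_pos[d] for d in rec_day]]

    K = spec.n_coef
    M = spec.coef_dim
    design = np.zeros((len(y), M))
    for q in range(spec.n_traits):
        rows = rec_trait == q
        design[np.ix_(rows, range(q * K, (q + 1) * K))] = phi_rec[rows]

    G = grm.matrix[np.ix_(grm_rows, grm_rows)]
    return AssembledModel(y=y, design=design, rec_acc=rec_acc, rec_trait=rec_trait,
                          rec_day=rec_day, accession_ids=accessions, spec=spec,
                          basis=basis, grm=grm, G=G)


def realized_covariance(model: AssembledModel, comps: CovarianceComponents) -> np.ndarray:
    """Dense phenotypic covariance Z(C x G)Z' + Q(D x I)Q' + residual expansion.

    Verification helper only (O(n_records^2) memory): the covariance between
    two observation rows r, r' is

        A_r C A_r'' * G[j, j']  +  A_r D A_r'' * 1[j = j']  +  R(t)[q, q'] * 1[j = j', t = t']
    """
    M = model.coef_dim
    if comps.C.shape[0] != M:
        raise ValueError(f"components sized {comps.C.shape[0]}, model needs {M}")
    day_idx = comps.r_day_index()
    missing = set(model.observed_days()) - set(comps.r_days)
    if missing:
        raise ValueError(f"no residual block for days {sorted(missing)}")
    A = model.design
    j = model.rec_acc
    same_acc = j[:, None] == j[None, :]
    Vu = (A @ comps.C @ A.T) * model.G[np.ix_(j, j)]
    Vp = (A @ comps.D @ A.T) * same_acc
    same_day = model.rec_day[:, None] == model.rec_day[None, :]
    t_pos = np.asarray([day_idx[d] for d in model.rec_day])
    Ve = comps.R[t_pos[:, None], model.rec_trait[:, None], model.rec_trait[None, :]]
    Ve = np.where(same_acc & same_day, Ve, 0.0)
    return Vu + Vp + Ve
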