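"""Genotype ingestion, marker QC, and the genomic relationship matrix.

Dosages are biallelic SNP codes in {0, 1, 2} (copies of the minor or alternate
allele) per accession, with -1 as the missing sentinel. The genomic
relationship matrix is G = W W' / m from the centered, column-scaled dosage
matrix W; with population-variance scaling of the columns the mean of diag(G)
is exactly 1 on complete data. The classical alternative denominator
2 * sum(p * (1 - p)) is available via ``scaling="allele_freq"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "NoMarkersSurviveQC",
    "filter_snps",
    "compute_grm",
    "read_dosage_table",
    "write_dosage_table",
    "write_grm",
    "read_grm",
]

MISSING = -1


class NoMarkersSurviveQC(ValueError):
    """Raised when QC filtering removes every marker."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Accessions x markers integer dosage codes with -1 marking missing calls."""

    accession_ids: tuple
    marker_ids: tuple
    dosages: np.ndarray

    def __post_init__(self) -> None:
        acc = tuple(str(a) for a in self.accession_ids)
        mk = tuple(str(m) for m in self.marker_ids)
        if len(set(acc)) != len(acc):
            raise ValueError("duplicate accession identifiers")
        if len(set(mk)) != len(mk):
            raise ValueError("duplicate marker identifiers")
        dos = np.asarray(self.dosages)
        if dos.shape != (len(acc), len(mk)):
            raise ValueError(f"dosage shape {dos.shape} does not match ids "
                             f"({len(acc)} x {len(mk)})")
        ok = np.isin(dos, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(dos[~ok])
            raise ValueError(f"invalid dosage codes {bad}; expected 0/1/2 or {MISSING}")
        object.__setattr__(self, "accession_ids", acc)
        object.__setattr__(self, "marker_ids", mk)
        object.__setattr__(self, "dosages", np.ascontiguousarray(dos, dtype=np.int8))

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def is_missing(self) -> np.ndarray:
        return self.dosages == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - self.is_missing().mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency from non-missing calls only."""
        obs = ~self.is_missing()
        n_called = obs.sum(axis=0)
        alt = np.where(obs, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.accession_ids,
            tuple(self.marker_ids[i] for i in keep),
            self.dosages[:, keep],
        )

    def subset_accessions(self, ids) -> "GenotypeMatrix":
        idx = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [idx[str(a)] for a in ids]
        return GenotypeMatrix(tuple(str(a) for a in ids), self.marker_ids,
                              self.dosages[rows, :])


def filter_snps(geno: GenotypeMatrix, maf_min: float = 0.05,
                callrate_min: float = 0.95) -> GenotypeMatrix:
    """Remove markers with call rate <= callrate_min or MAF <= maf_min.

    Removal is on <= (markers strictly above both thresholds are kept); MAF is
    computed from non-missing calls. Accessions and marker order are preserved.
    Raises :class:`NoMarkersSurviveQC` when nothing survives.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= callrate_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    cr = geno.call_rate()
    maf = geno.maf()
    keep = (cr > callrate_min) & (np.nan_to_num(maf, nan=-1.0) > maf_min)
    if not keep.any():
        raise NoMarkersSurviveQC(
            f"no markers survive QC (maf > {maf_min}, call rate > {callrate_min})")
    return geno.subset_markers(keep)


@dataclass(frozen=True)
class GRM:
    """Genomic relationship matrix with its accession ordering."""

    accession_ids: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        acc = tuple(str(a) for a in self.accession_ids)
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(acc), len(acc)):
            raise ValueError("GRM must be square and match accession ids")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        object.__setattr__(self, "accession_ids", acc)
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.asarray([lookup[str(a)] for a in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"accession {err} not present in the GRM") from None

    def block(self, row_ids, col_ids) -> np.ndarray:
        r = self.index_of(row_ids)
        c = self.index_of(col_ids)
        return self.matrix[np.ix_(r, c)]

    def regularized(self, ridge: float = 1e-6) -> np.ndarray:
        """Copy of the matrix with ``ridge`` added to the diagonal.

        G from a finite marker panel is typically singular (rank at most
        m, minus one for centering); every inversion in the package goes
        through this ridge.
        """
        return self.matrix + ridge * np.eye(self.n)


def compute_grm(geno: GenotypeMatrix, scaling: str = "unit_variance",
                impute_missing: bool = False) -> GRM:
    """G = W W' / m from centered, scaled dosages.

    scaling="unit_variance" divides each centered column by its population
    standard deviation (divide by n), which makes mean(diag(G)) exactly 1;
    scaling="allele_freq" centers by 2p and divides W W' by 2*sum(p(1-p)),
    the familiar frequency-based denominator. Missing dosages are rejected
    unless ``impute_missing`` mean-imputes them (testing convenience only —
    proper imputation is out of scope).
    """
    if geno.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    if geno.n_markers < 1:
        raise ValueError("need at least 1 marker")
    X = geno.dosages.astype(float)
    miss = geno.is_missing()
    if miss.any():
        if not impute_missing:
            raise ValueError("missing genotypes present; impute first or pass "
                             "impute_missing=True for naive mean imputation")
        X = np.where(miss, np.nan, X)
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    mean = X.mean(axis=0)
    Wc = X - mean[None, :]
    if scaling == "unit_variance":
        sd = X.std(axis=0)  # population variance: ddof=0
        if np.any(sd == 0):
            mono = [geno.marker_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
            raise ValueError(f"monomorphic markers (zero variance), e.g. {mono}; "
                             "run filter_snps first")
        W = Wc / sd[None, :]
        G = (W @ W.T) / geno.n_markers
    elif scaling == "allele_freq":
        p = mean / 2.0
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom == 0:
            raise ValueError("all markers monomorphic; run filter_snps first")
        G = (Wc @ Wc.T) / denom
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    G = (G + G.T) / 2.0
    return GRM(geno.accession_ids, G)


# ---------------------------------------------------------------------------
# plain-text IO

def read_dosage_table(path, sep=None) -> GenotypeMatrix:
    """Read a delimited dosage table: header = marker ids, first col = accession."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    dos = df.to_numpy()
    dos = np.where(pd.isna(dos), MISSING, dos).astype(int)
    return GenotypeMatrix(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), dos)


def write_dosage_table(geno: GenotypeMatrix, path, sep="\t") -> None:
    df = pd.DataFrame(geno.dosages, index=list(geno.accession_ids),
                      columns=list(geno.marker_ids))
    df.index.name = "accession"
    df.to_csv(path, sep=sep)


def write_grm(grm: GRM, path, sep="\t") -> None:
    df = pd.DataFrame(grm.matrix, index=list(grm.accession_ids),
                      columns=list(grm.accession_ids))
    df.index.name = "accession"
    df.to_csv(path, sep=sep, float_format="%.10g")


def read_grm(path, sep="\t") -> GRM:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return GRM(tuple(df.index.astype(str)), df.to_numpy())
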