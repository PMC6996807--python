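"""Per-day genetic summaries from coefficient covariance functions.

With a quadratic Legendre basis row t_i = phi(t) (1 x 3), the additive genetic
variance of a trait at day t is the quadratic form t_i C_q t_i', and the
genomic correlation between two traits is

    rg(t) = t_i C12 t_i' / sqrt(t_i C1 t_i' * t_i C2 t_i').

Narrow-sense heritability at day t is defined here as

    h2(t) = g(t) / (g(t) + pe(t) + ve(t))

with g(t) and pe(t) the genetic and permanent-environment quadratic forms and
ve(t) the day's residual variance. Whether the permanent-environment variance
belongs in the denominator is a modeling convention; excluding it
(``include_pe=False``) raises the level of every h2(t) but not the shape of
the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisMatrix
from .model import CovarianceComponents

__all__ = ["TrajectorySummary", "genomic_correlation", "heritability",
           "summarize_trajectories"]

_OVERSHOOT_TOL = 1e-10


@dataclass(frozen=True)
class TrajectorySummary:
    """Per-day heritability per trait and genomic correlation."""

    days: tuple
    h2: dict          # trait index -> per-day array
    rg: np.ndarray | None

    def to_frame(self, trait_names=None) -> pd.DataFrame:
        cols = {"day": list(self.days)}
        for q, vals in self.h2.items():
            name = trait_names[q] if trait_names else f"trait{q + 1}"
            cols[f"h2_{name}"] = vals
        if self.rg is not None:
            cols["rg"] = self.rg
        return pd.DataFrame(cols)


def _quadratic_forms(mat: np.ndarray, phi: np.ndarray) -> np.ndarray:
    return np.einsum("ij,jk,ik->i", phi, mat, phi)


def genomic_correlation(comps: CovarianceComponents, basis: BasisMatrix) -> np.ndarray:
    """Per-day genomic correlation between the two traits of a bivariate fit.

    Days where either trait has zero genetic variance yield NaN; values beyond
    [-1, 1] by more than a numerical whisker raise (a PSD C cannot produce
    them), otherwise they are clipped.
    """
    if comps.n_traits != 2:
        raise ValueError("genomic correlation needs a bivariate fit")
    phi = basis.phi
    g1 = _quadratic_forms(comps.trait_block("C", 0, 0), phi)
    g2 = _quadratic_forms(comps.trait_block("C", 1, 1), phi)
    g12 = _quadratic_forms(comps.trait_block("C", 0, 1), phi)
    denom_sq = g1 * g2
    rg = np.full(phi.shape[0], np.nan)
    ok = denom_sq > 0
    rg[ok] = g12[ok] / np.sqrt(denom_sq[ok])
    over = np.nanmax(np.abs(rg), initial=0.0) - 1.0
    if over > _OVERSHOOT_TOL:
        raise ValueError(f"|rg| exceeds 1 by {over:.3g}; C is not PSD")
    return np.clip(rg, -1.0, 1.0, out=rg)


def heritability(comps: CovarianceComponents, basis: BasisMatrix, trait: int = 0,
                 include_pe: bool = True) -> np.ndarray:
    """Per-day narrow-sense heritability of one trait.

    Requires a residual block for every basis day. ``include_pe`` keeps the
    permanent-environment variance in the denominator (the default).
    """
    phi = basis.phi
    g = _quadratic_forms(comps.trait_block("C", trait, trait), phi)
    pe = _quadratic_forms(comps.trait_block("D", trait, trait), phi)
    idx = comps.r_day_index()
    missing = set(basis.grid.days) - set(comps.r_days)
    if missing:
        raise ValueError(f"no residual variance for days {sorted(missing)}")
    ve = np.asarray([comps.R[idx[d], trait, trait] for d in basis.grid.days])
    denom = g + ve + (pe if include_pe else 0.0)
    if np.all(denom == 0):
        raise ValueError("zero phenotypic variance at every day")
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(denom > 0, g / denom, np.nan)
    return h2


def summarize_trajectories(comps: CovarianceComponents, basis: BasisMatrix,
                           include_pe: bool = True) -> TrajectorySummary:
    h2 = {q: heritability(comps, basis, q, include_pe)
          for q in range(comps.n_traits)}
    rg = genomic_correlation(comps, basis) if comps.n_traits == 2 else None
    return TrajectorySummary(days=basis.grid.days, h2=h2, rg=rg)
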