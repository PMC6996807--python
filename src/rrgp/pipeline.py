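"""The study workflow: water-use derivation, first-stage adjusted means, and
the two cross-validation scenarios.

The analysis is two-stage. Stage one collapses raw greenhouse records to one
adjusted mean (BLUE) per accession and day by fitting, separately per day,

    y = mu + accession (fixed) + experiment + smarthouse block
        + accession x experiment + error   (all but accession random).

Stage two fits random regression models to the per-day BLUEs.

Two cross-validation scenarios probe genomic prediction of daily water use:

* CV1 — predict WU trajectories of accessions with no WU records: random
  train/test split (default 245/112), variance components estimated on the
  training set, then fixed-variance BLUP. ST-RRM and MT-RRM1 project training
  genetic values through the genomic relationship matrix; MT-RRM2 includes
  the test accessions' PSA records in the MME and reads their WU genetic
  values directly from the BLUP solutions.
* CV2 — forecast future WU of known accessions: train on the first
  ``train_days`` days (WU; PSA per model), evaluate the basis at the held-out
  days and correlate forecast genetic values with the observed later BLUEs.

Accuracy is the per-day Pearson correlation between predicted genetic values
and the phenotypic BLUEs; when simulated truth is supplied, the correlation
with the true genetic values is reported alongside as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisMatrix, TimeGrid, legendre_basis
from .geno import GRM
from .inference import (DEFAULT_RIDGE, GibbsConfig, RRMSolutions, gibbs_sample,
                        predict_unphenotyped, solve_mme)
from .model import PhenotypeTable, RRMSpec, build_design

__all__ = [
    "compute_wu",
    "stage1_blue",
    "accuracy",
    "CVConfig",
    "CVResult",
    "run_cv1",
    "run_cv2",
]

MODELS = ("ST-RRM", "MT-RRM1", "MT-RRM2")


# ---------------------------------------------------------------------------
# water use from pot weights

def compute_wu(weights: pd.DataFrame) -> pd.DataFrame:
    """Daily water use from pot-weight records: WU_t = Potwt_{t-1} - Potwt_t.

    ``weights`` needs columns ``accession, day, potwt, potwt_pre`` (``potwt``
    is the weight after watering, ``potwt_pre`` the weight before watering on
    the current day) plus any grouping columns such as experiment/replicate/
    smarthouse. Water use on day t is the previous day's after-watering
    weight minus the current day's pre-watering weight; the first day of a
    series (or a day with no previous-day record) has missing WU.
    """
    required = {"accession", "day", "potwt", "potwt_pre"}
    if not required.issubset(weights.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if (weights["potwt"] <= 0).any() or (weights["potwt_pre"] <= 0).any():
        raise ValueError("pot weights must be positive")
    group_cols = [c for c in weights.columns
                  if c not in ("day", "potwt", "potwt_pre")]
    out = weights.sort_values(group_cols + ["day"]).reset_index(drop=True)
    prev = out[group_cols + ["day", "potwt"]].copy()
    prev["day"] = prev["day"] + 1
    prev = prev.rename(columns={"potwt": "_potwt_prev"})
    out = out.merge(prev, on=group_cols + ["day"], how="left")
    out["wu"] = out["_potwt_prev"] - out["potwt_pre"]
    return out.drop(columns="_potwt_prev")


# ---------------------------------------------------------------------------
# first-stage adjusted means (per-day BLUEs)

def _design_matrices(raw: pd.DataFrame):
    """Fixed design (intercept + sum-to-zero accession contrasts) and the
    random-term incidence matrices for the per-day stage-one model."""
    acc = pd.Categorical(raw["accession"].astype(str))
    levels = list(acc.categories)
    n_acc = len(levels)
    n = len(raw)
    if n_acc < 2:
        raise ValueError("need at least 2 accessions")
    # sum-to-zero contrasts: last level = -sum(others)
    Xa = np.zeros((n, n_acc - 1))
    codes = acc.codes
    last = n_acc - 1
    for i in range(n):
        if codes[i] == last:
            Xa[i, :] = -1.0
        else:
            Xa[i, codes[i]] = 1.0
    X = np.column_stack([np.ones(n), Xa])

    def incidence(keys) -> np.ndarray:
        cat = pd.Categorical(keys)
        Z = np.zeros((n, len(cat.categories)))
        Z[np.arange(n), cat.codes] = 1.0
        return Z

    exp_rep = raw["experiment"].astype(str) + "/" + raw["replicate"].astype(str)
    block = exp_rep + "/" + raw["smarthouse"].astype(str)
    acc_exp = raw["accession"].astype(str) + "/" + exp_rep
    Zs = [incidence(exp_rep), incidence(block), incidence(acc_exp)]
    return X, Zs, levels, codes


def _mme_general(y, X, Zs, sig2, sig2_e):
    """Henderson MME for y = Xb + sum_k Z_k a_k with iid random terms."""
    blocks = [X] + list(Zs)
    W = np.hstack(blocks)
    lhs = W.T @ W / sig2_e
    rhs = W.T @ y / sig2_e
    off = X.shape[1]
    for Z, s2 in zip(Zs, sig2):
        q = Z.shape[1]
        lhs[off:off + q, off:off + q] += np.eye(q) / max(s2, 1e-12)
        off += q
    sol = np.linalg.solve(lhs + 1e-10 * np.eye(lhs.shape[0]), rhs)
    return sol


def _stage1_variance_gibbs(y, X, Zs, n_iter=2000, burn_in=None, seed=0):
    """Scalar-variance Gibbs for the stage-one model (conjugate updates)."""
    if burn_in is None:
        burn_in = min(500, n_iter // 3)
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    p = X.shape[1]
    qs = [Z.shape[1] for Z in Zs]
    v_y = max(np.var(y), 1e-10)
    sig2 = [0.1 * v_y for _ in Zs]
    sig2_e = 0.5 * v_y
    s0 = 1e-2 * v_y
    nu0 = 3.0
    keep_s = np.zeros(len(Zs))
    keep_e = 0.0
    kept = 0
    for it in range(n_iter):
        sol = _mme_general(y, X, Zs, sig2, sig2_e)
        # sample locations around the MME solution
        blocks = [X] + list(Zs)
        W = np.hstack(blocks)
        lhs = W.T @ W / sig2_e
        off = p
        for Z, s2 in zip(Zs, sig2):
            q = Z.shape[1]
            lhs[off:off + q, off:off + q] += np.eye(q) / max(s2, 1e-12)
            off += q
        L = np.linalg.cholesky(lhs + 1e-10 * np.eye(lhs.shape[0]))
        theta = sol + np.linalg.solve(L.T, rng.standard_normal(lhs.shape[0]))
        off = p
        for k, q in enumerate(qs):
            a = theta[off:off + q]
            sig2[k] = (s0 + a @ a) / rng.chisquare(nu0 + q)
            off += q
        resid = y - W @ theta
        sig2_e = (s0 + resid @ resid) / rng.chisquare(nu0 + n)
        if it >= burn_in:
            keep_s += sig2
            keep_e += sig2_e
            kept += 1
    return list(keep_s / kept), keep_e / kept


def stage1_blue(raw: pd.DataFrame, day=None, variance_components=None,
                n_iter: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per-accession adjusted means (BLUEs) for one day of records.

    ``raw`` needs columns ``accession, experiment, replicate, smarthouse,
    day, value``. Accession is fixed under a sum-to-zero constraint;
    experiment/replicate, smarthouse block and accession-by-experiment are
    random with scalar variances, estimated by a conjugate Gibbs sampler
    unless ``variance_components=(sig2_list, sig2_e)`` is supplied. Returns a
    frame with columns ``accession, blue`` where blue = mu + accession
    effect.
    """
    required = {"accession", "experiment", "replicate", "smarthouse", "day",
                "value"}
    if not required.issubset(raw.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if day is not None:
        raw = raw[raw["day"] == day]
    if raw["day"].nunique() != 1:
        raise ValueError("stage1_blue fits one day at a time; pass day=")
    raw = raw.reset_index(drop=True)
    y = raw["value"].to_numpy(dtype=float)
    exp_per_acc = raw.groupby("accession")["experiment"].nunique()
    acc_per_exp = raw.groupby("experiment")["accession"].nunique()
    if (raw["experiment"].nunique() > 1 and (exp_per_acc == 1).all()
            and (acc_per_exp == 1).all()):
        raise ValueError("confounded design: accession aliased with experiment")
    X, Zs, levels, _ = _design_matrices(raw)
    if variance_components is None:
        sig2, sig2_e = _stage1_variance_gibbs(y, X, Zs, n_iter=n_iter, seed=seed)
    else:
        sig2, sig2_e = variance_components
    sol = _mme_general(y, X, Zs, sig2, sig2_e)
    mu = sol[0]
    eff = np.concatenate([sol[1:X.shape[1]], [-np.sum(sol[1:X.shape[1]])]])
    return pd.DataFrame({"accession": levels, "blue": mu + eff})


# ---------------------------------------------------------------------------
# accuracy

def accuracy(pred, obs) -> float:
    """Pearson correlation between predictions and observed values.

    Pairs with a missing observation are dropped; fewer than 3 pairs or zero
    variance on either side yields NaN.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ok = ~(np.isnan(pred) | np.isnan(obs))
    pred, obs = pred[ok], obs[ok]
    if pred.size < 3 or np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


# ---------------------------------------------------------------------------
# cross-validation scenarios

@dataclass(frozen=True)
class CVConfig:
    """Split sizes, repeats, chain lengths and the master seed."""

    n_train: int = 245
    n_test: int = 112
    n_repeats: int = 10
    train_days: int = 10          # CV2: days used for training
    seed: int = 0
    n_iter: int = 4_000
    burn_in: int = 1_500
    thin: int = 5
    ridge: float = DEFAULT_RIDGE
    wu_trait: str = "WU"
    psa_trait: str = "PSA"

    def gibbs(self, seed: int) -> GibbsConfig:
        return GibbsConfig(n_iter=self.n_iter, burn_in=self.burn_in,
                           thin=self.thin, seed=seed, ridge=self.ridge,
                           save_draws=False)


@dataclass(frozen=True)
class CVResult:
    """Per-repeat, per-day accuracies for the three models of one scenario."""

    scenario: str
    table: pd.DataFrame          # columns: model, repeat, day, accuracy[, accuracy_true]
    seeds: tuple

    def per_day(self, against: str = "accuracy") -> pd.DataFrame:
        """Mean accuracy per model and day, averaged across repeats."""
        return (self.table.pivot_table(index="day", columns="model",
                                       values=against, aggfunc="mean")
                .reindex(columns=list(MODELS)))

    def mean_accuracy(self, against: str = "accuracy") -> pd.Series:
        return self.table.groupby("model")[against].mean().reindex(list(MODELS))


def _blue_matrix(phenos: PhenotypeTable, trait: str, accessions, days):
    """accessions x days matrix of BLUEs (NaN where missing)."""
    df = phenos.records
    sub = df[df["trait"] == trait]
    piv = sub.pivot(index="accession", columns="day", values="value")
    piv = piv.reindex(index=[str(a) for a in accessions], columns=list(days))
    return piv.to_numpy()


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _estimate_components(phenos, basis, spec, grm, gcfg):
    model = build_design(phenos, basis, spec, grm)
    draws = gibbs_sample(model, gcfg)
    return draws.posterior_mean()


def run_cv1(phenos: PhenotypeTable, grm: GRM, cfg: CVConfig = CVConfig(),
            basis: BasisMatrix | None = None, truth=None) -> CVResult:
    """Prediction of water use for accessions with no WU records.

    Per repeat: a random disjoint train/test split; variance components
    estimated on the training set per model family; then fixed-variance BLUP
    predictions for the test set and per-day Pearson accuracies against the
    test WU BLUEs.
    """
    wu, psa = cfg.wu_trait, cfg.psa_trait
    accessions = np.asarray(phenos.accessions())
    if cfg.n_train + cfg.n_test > accessions.size:
        raise ValueError("split sizes exceed the number of accessions")
    days = phenos.days()
    if basis is None:
        basis = legendre_basis(TimeGrid(days), 2)
    st_spec = RRMSpec(traits=(wu,))
    mt_spec = RRMSpec(traits=(wu, psa))
    seeds = _child_seeds(cfg.seed, cfg.n_repeats)
    rows = []
    for rep, rep_seed in enumerate(seeds):
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(accessions.size)
        train = list(accessions[perm[:cfg.n_train]])
        test = list(accessions[perm[cfg.n_train:cfg.n_train + cfg.n_test]])
        train_ph = phenos.subset(accessions=train)
        gcfg_st = cfg.gibbs(rep_seed + 1)
        gcfg_mt = cfg.gibbs(rep_seed + 2)

        comps_st = _estimate_components(train_ph.subset(traits=[wu]), basis,
                                        st_spec, grm, gcfg_st)
        comps_mt = _estimate_components(train_ph, basis, mt_spec, grm, gcfg_mt)

        preds = {}
        # ST-RRM: train on WU only, project through G
        m_st = build_design(train_ph.subset(traits=[wu]), basis, st_spec, grm)
        sols = solve_mme(m_st, comps_st, ridge=cfg.ridge)
        preds["ST-RRM"] = predict_unphenotyped(grm, train, test, sols,
                                               trait=0, ridge=cfg.ridge)
        # MT-RRM1: train bivariate, project WU coefficients through G
        m_mt = build_design(train_ph, basis, mt_spec, grm)
        sols = solve_mme(m_mt, comps_mt, ridge=cfg.ridge)
        preds["MT-RRM1"] = predict_unphenotyped(grm, train, test, sols,
                                                trait=0, ridge=cfg.ridge)
        # MT-RRM2: joint MME with the test accessions' PSA records
        joint_ph = phenos.subset(accessions=train + test)
        keep = (joint_ph.records["accession"].isin(train)
                | (joint_ph.records["trait"] == psa))
        joint_ph = PhenotypeTable(joint_ph.records.loc[keep])
        m_j = build_design(joint_ph, basis, mt_spec, grm,
                           accessions=train + test)
        sols = solve_mme(m_j, comps_mt, ridge=cfg.ridge)
        gv = sols.genetic_values(trait=0)
        order = {a: i for i, a in enumerate(sols.accession_ids)}
        preds["MT-RRM2"] = gv[[order[a] for a in test]]

        obs = _blue_matrix(phenos, wu, test, days)
        obs_true = (truth_matrix(truth, test, grm) if truth is not None else None)
        for name in MODELS:
            for di, day in enumerate(days):
                row = {"model": name, "repeat": rep, "day": day,
                       "accuracy": accuracy(preds[name][:, di], obs[:, di])}
                if obs_true is not None:
                    row["accuracy_true"] = accuracy(preds[name][:, di],
                                                    obs_true[:, di])
                rows.append(row)
    return CVResult("CV1", pd.DataFrame(rows), tuple(seeds))


def truth_matrix(truth, accessions, grm) -> np.ndarray:
    """True WU genetic values (accessions x days) from a SimulatedTruth."""
    order = {a: i for i, a in enumerate(grm.accession_ids)}
    rows = [order[str(a)] for a in accessions]
    return truth.genetic_values[0][rows]


def run_cv2(phenos: PhenotypeTable, grm: GRM, cfg: CVConfig = CVConfig(),
            basis: BasisMatrix | None = None, truth=None) -> CVResult:
    """Forecasting future water-use genetic values for known accessions.

    Per repeat: select ``n_train`` accessions; train ST-RRM on their WU over
    the first ``train_days`` days, MT-RRM1 additionally on PSA over the same
    window, MT-RRM2 on PSA over all days; evaluate the basis at the held-out
    later days (same standardization as the full design) and correlate the
    forecast genetic values with the later WU BLUEs of the same accessions.
    """
    wu, psa = cfg.wu_trait, cfg.psa_trait
    accessions = np.asarray(phenos.accessions())
    if cfg.n_train > accessions.size:
        raise ValueError("training size exceeds the number of accessions")
    days = phenos.days()
    early = [d for d in days[:cfg.train_days]]
    late = [d for d in days[cfg.train_days:]]
    if not late:
        raise ValueError("no held-out days to forecast")
    if basis is None:
        basis = legendre_basis(TimeGrid(days), 2)
    st_spec = RRMSpec(traits=(wu,))
    mt_spec = RRMSpec(traits=(wu, psa))
    seeds = _child_seeds(cfg.seed, cfg.n_repeats)
    rows = []
    for rep, rep_seed in enumerate(seeds):
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(accessions.size)
        train = list(accessions[perm[:cfg.n_train]])
        train_ph = phenos.subset(accessions=train)

        training_sets = {
            "ST-RRM": (train_ph.subset(traits=[wu], days=early), st_spec),
            "MT-RRM1": (train_ph.subset(days=early), mt_spec),
            "MT-RRM2": (PhenotypeTable(pd.concat([
                train_ph.subset(traits=[wu], days=early).records,
                train_ph.subset(traits=[psa]).records])), mt_spec),
        }
        obs = _blue_matrix(phenos, wu, train, late)
        obs_true = (truth_matrix(truth, train, grm)[:, [days.index(d) for d in late]]
                    if truth is not None else None)
        for mi, (name, (ph, spec)) in enumerate(training_sets.items()):
            gcfg = cfg.gibbs(rep_seed + 1 + mi)
            comps = _estimate_components(ph, basis, spec, grm, gcfg)
            m = build_design(ph, basis, spec, grm)
            sols = solve_mme(m, comps, ridge=cfg.ridge)
            order = {a: i for i, a in enumerate(sols.accession_ids)}
            fc = sols.genetic_values(trait=0, days=late)
            fc = fc[[order[a] for a in train]]
            for di, day in enumerate(late):
                row = {"model": name, "repeat": rep, "day": day,
                       "accuracy": accuracy(fc[:, di], obs[:, di])}
                if obs_true is not None:
                    row["accuracy_true"] = accuracy(fc[:, di], obs_true[:, di])
                rows.append(row)
    return CVResult("CV2", pd.DataFrame(rows), tuple(seeds))
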