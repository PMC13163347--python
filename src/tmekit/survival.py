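"""Survival analytics and the regulon-composite prognostic risk model.

Kaplan-Meier estimation, log-rank tests and Cox regression are delegated to
lifelines (Efron tie handling); the maximally selected log-rank cutpoint,
IPCW time-dependent ROC, and the two-stage (univariate filter + L1-penalized
Cox) risk model are implemented here, the penalized path via scikit-survival
with a hand-rolled held-out partial-likelihood cross-validation.

The risk score of a fitted model is the plain coefficient-weighted sum of
regulon activity scores, ``RS = sum_i coef_i * score_i``; patients are
stratified at the median RS (ties to low risk).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "RiskModel",
    "km_estimate",
    "logrank",
    "optimal_cutpoint",
    "cox_hr",
    "split_cohort",
    "fit_risk_model",
    "risk_score",
    "stratify_median",
    "time_roc",
    "module_survival",
    "infiltration_correlation",
]


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if records.index.duplicated().any():
        raise ValueError("duplicate patients")
    if (records["time"] <= 0).any():
        raise ValueError("non-positive survival times")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return records


@dataclass
class RiskModel:
    """Coefficient vector over selected regulons defining RS = sum coef*score."""

    regulons: list[str]
    coefficients: list[float]
    alpha: float = float("nan")
    folds: int = 10
    seed: int = 0
    status: str = "ok"

    def __post_init__(self) -> None:
        if len(self.regulons) != len(set(self.regulons)):
            raise ValueError("duplicate regulon names")
        if len(self.regulons) != len(self.coefficients):
            raise ValueError("names and coefficients differ in length")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        return cls(**json.loads(Path(path).read_text()))


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve: columns (time, survival)."""
    records = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank(labels: pd.Series | np.ndarray, records: pd.DataFrame) -> tuple[float, int, float]:
    """Log-rank test across groups: (chi-square statistic, df, p)."""
    records = _check_records(records)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(records["time"], labels, records["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def _logrank_z_per_cut(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray, cuts: np.ndarray
) -> np.ndarray:
    """Standardized log-rank statistic for every candidate cutoff.

    Maximally-selected-rank-statistic form: each subject carries the log-rank
    score ``a_i = event_i - NelsonAalen(t_i)``; for a cut, the statistic is
    the sum of scores in the high group standardized by its
    permutation mean ``n1 * mean(a)`` and variance
    ``n1 n2 / (n (n-1)) * sum((a - mean(a))^2)``. Vectorized over cutoffs.
    """
    n = len(time)
    taus = np.unique(time[event == 1])
    at_risk = time[:, None] >= taus[None, :]  # subjects x event times
    n_tot = at_risk.sum(axis=0).astype(float)
    d_tot = ((time[:, None] == taus[None, :]) & (event[:, None] == 1)).sum(axis=0).astype(float)
    haz = d_tot / n_tot
    cum_haz_at = at_risk @ haz  # Nelson-Aalen cumulative hazard at each t_i
    a = event - cum_haz_at
    abar = a.mean()
    ss = float(((a - abar) ** 2).sum())
    G = (scores[None, :] > cuts[:, None]).astype(float)  # cuts x subjects
    n1 = G.sum(axis=1)
    n2 = n - n1
    s1 = G @ a
    var = n1 * n2 / (n * (n - 1.0)) * ss
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(var > 0, (s1 - n1 * abar) / np.sqrt(var), 0.0)


def optimal_cutpoint(
    scores: pd.Series, records: pd.DataFrame, minprop: float = 0.1
) -> tuple[float, float]:
    """Maximally selected log-rank cutpoint of a continuous score.

    Every candidate cutoff (midpoints of consecutive sorted unique scores
    leaving at least ``minprop`` of patients on each side) is evaluated by the
    standardized two-group log-rank statistic; the cutoff maximizing |z| is
    returned together with that maximum.
    """
    records = _check_records(records)
    s = scores.reindex(records.index).to_numpy(dtype=float)
    if np.nanstd(s) == 0:
        raise ValueError("score has zero variance")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(s)
    low = np.array([(s <= c).sum() for c in mids])
    ok = (low >= minprop * n) & ((n - low) >= minprop * n)
    cuts = mids[ok]
    if len(cuts) == 0:
        raise ValueError("no candidate cutoff satisfies minprop")
    z = _logrank_z_per_cut(s, records["time"].to_numpy(), records["event"].to_numpy(dtype=int), cuts)
    best = int(np.argmax(np.abs(z)))
    return float(cuts[best]), float(np.abs(z[best]))


def cox_hr(
    x: pd.Series,
    records: pd.DataFrame,
    covariates: list[str] = ("age",),
) -> dict:
    """Cox proportional-hazards effect of a score or group indicator.

    Fits a Cox model (Efron tie handling) of ``x`` plus the requested
    covariate columns of ``records``; returns HR = exp(beta), Wald 95% CI and
    p for ``x``, and the direction label "Worse survival" (HR > 1) or
    "Better survival" (HR < 1).
    """
    records = _check_records(records)
    if records["event"].sum() < 5:
        raise ValueError("need at least 5 events")
    df = records[["time", "event", *covariates]].copy()
    df["x"] = pd.Series(x).reindex(records.index).astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["x"]
    hr = float(s["exp(coef)"])
    return {
        "hr": hr,
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "pvalue": float(s["p"]),
        "direction": "Worse survival" if hr > 1 else "Better survival",
    }


def split_cohort(n: int, train_frac: float = 0.7, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test index split with |train| = floor(frac * n)."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_frac * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    order = np.argsort(-time, kind="mergesort")
    eta, time, event = eta[order], time[order], event[order]
    log_cumsum = np.logaddexp.accumulate(eta)
    # handle ties in time: risk set includes all with time >= t
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        denom = log_cumsum[j - 1]
        ll += float(np.sum(eta[i:j][event[i:j] == 1])) - float(event[i:j].sum()) * denom
        i = j
    return ll


def fit_risk_model(
    scores: pd.DataFrame,
    records: pd.DataFrame,
    p_uni: float = 0.05,
    folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
) -> RiskModel:
    """Two-stage regulon risk model: univariate Cox filter + L1-penalized Cox.

    Stage 1 keeps regulons with univariate Cox Wald p < ``p_uni``. Stage 2
    fits an L1-penalized Cox path over the survivors (standardized
    internally; returned coefficients are on the raw score scale) and selects
    the penalty maximizing the summed held-out Breslow partial log-likelihood
    over ``folds`` folds (equivalently minimizing CV deviance); pass
    ``alpha`` to skip the CV. Regulons with nonzero coefficients at the
    selected penalty define the model. An empty stage-1 survivor set returns
    an empty model with status "no_univariate_survivor".
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    records = _check_records(records)
    scores = scores.loc[records.index]
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 candidate regulons")
    if records["event"].sum() < 30:
        raise ValueError("need at least 30 events")

    survivors = []
    for reg in scores.columns:
        df = pd.DataFrame(
            {"time": records["time"], "event": records["event"], "x": scores[reg]}
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        if float(cph.summary.loc["x", "p"]) < p_uni:
            survivors.append(reg)
    if not survivors:
        return RiskModel([], [], folds=folds, seed=seed, status="no_univariate_survivor")

    X = scores[survivors].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    y = Surv.from_arrays(records["event"].astype(bool), records["time"])
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)

    if alpha is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=50)
        path.fit(Xs, y)
        alphas = path.alphas_
        rng = np.random.default_rng(seed)
        fold_ids = rng.permuted(np.arange(len(time)) % folds)
        cv_ll = np.zeros(len(alphas))
        for f in range(folds):
            tr = fold_ids != f
            te = ~tr
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(Xs[tr], y[tr])
            coefs = m.coef_  # features x alphas
            for ai in range(coefs.shape[1]):
                eta = Xs[te] @ coefs[:, ai]
                cv_ll[ai] += _breslow_loglik(eta, time[te], event[te])
        alpha = float(alphas[int(np.argmax(cv_ll))])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha], fit_baseline_model=False)
    final.fit(Xs, y)
    beta_std = final.coef_[:, 0]
    beta_raw = beta_std / sd
    nz = np.flatnonzero(beta_std != 0)
    return RiskModel(
        regulons=[survivors[i] for i in nz],
        coefficients=[float(beta_raw[i]) for i in nz],
        alpha=float(alpha),
        folds=folds,
        seed=seed,
        status="ok" if len(nz) else "all_coefficients_zero",
    )


def risk_score(scores: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Risk score per patient: RS = sum_i coef_i * score_i (no intercept)."""
    missing = set(model.regulons) - set(scores.columns)
    if missing:
        raise ValueError(f"missing regulon columns: {sorted(missing)}")
    if not model.regulons:
        return pd.Series(0.0, index=scores.index, name="risk_score")
    rs = scores[model.regulons].to_numpy() @ np.asarray(model.coefficients)
    return pd.Series(rs, index=scores.index, name="risk_score")


def stratify_median(rs: pd.Series) -> pd.Series:
    """High/low risk at the median RS; values equal to the median go to low."""
    if len(rs) < 2:
        raise ValueError("need at least 2 patients")
    med = rs.median()
    return pd.Series(np.where(rs > med, "high", "low"), index=rs.index, name="risk_group")


def _censor_km(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    return kmf


def time_roc(rs: pd.Series, records: pd.DataFrame, horizons: list[float]) -> pd.Series:
    """IPCW cumulative-case / dynamic-control AUC at each horizon.

    Cases at horizon t are subjects with an event at or before t, weighted by
    the inverse Kaplan-Meier censoring survival just before their event time;
    controls are subjects still under observation beyond t, weighted by
    ``1/G(t)``. AUC is the weighted fraction of correctly ordered
    case-control pairs (ties count 1/2). Horizons beyond follow-up are
    reported missing with a warning.
    """
    records = _check_records(records)
    s = rs.reindex(records.index).to_numpy(dtype=float)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    G = _censor_km(time, event)
    out = {}
    for t in horizons:
        if t >= time.max():
            warnings.warn(f"horizon {t} beyond follow-up; reported missing")
            out[t] = np.nan
            continue
        cases = (time <= t) & (event == 1)
        controls = time > t
        if cases.sum() < 1 or controls.sum() < 1:
            warnings.warn(f"no cases or controls at horizon {t}")
            out[t] = np.nan
            continue
        g_case = G.survival_function_at_times(np.maximum(time[cases] - 1e-12, 0)).to_numpy()
        g_ctrl = float(G.survival_function_at_times(t).iloc[0])
        w_case = np.where(g_case > 0, 1.0 / g_case, 0.0)
        w_ctrl = np.full(int(controls.sum()), 1.0 / g_ctrl if g_ctrl > 0 else 0.0)
        sc, st = s[cases], s[controls]
        gt = (sc[:, None] > st[None, :]).astype(float) + 0.5 * (sc[:, None] == st[None, :])
        W = np.outer(w_case, w_ctrl)
        out[t] = float((gt * W).sum() / W.sum())
    return pd.Series(out, name="auc")


def module_survival(
    bulk_expr: pd.DataFrame,
    module_markers: dict[str, list[str]],
    records: pd.DataFrame,
    minprop: float = 0.1,
) -> pd.DataFrame:
    """Prognostic stratification of cell-module marker signatures in bulk data.

    Per module: the mean expression of its marker genes present in
    ``bulk_expr`` (patients x genes; at least half must be present, else the
    module is skipped) is split at the maximally selected cutpoint; the
    high/low groups are compared by log-rank. Constant scores are skipped
    with status "constant_score".
    """
    records = _check_records(records)
    bulk = bulk_expr.loc[records.index]
    rows = []
    for module, markers in module_markers.items():
        present = [g for g in markers if g in bulk.columns]
        if len(present) < 0.5 * len(markers) or not present:
            rows.append({"module": module, "status": "insufficient_markers"})
            continue
        score = bulk[present].mean(axis=1)
        if score.std(ddof=0) == 0:
            rows.append({"module": module, "status": "constant_score"})
            continue
        try:
            cut, zmax = optimal_cutpoint(score, records, minprop=minprop)
        except ValueError as e:
            rows.append({"module": module, "status": f"no_cutpoint:{e}"})
            continue
        groups = np.where(score > cut, "high", "low")
        stat, dof, p = logrank(groups, records)
        rows.append(
            {
                "module": module,
                "status": "ok",
                "cutoff": cut,
                "max_z": zmax,
                "logrank_p": p,
                "n_high": int((groups == "high").sum()),
                "n_low": int((groups == "low").sum()),
            }
        )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def infiltration_correlation(
    scores: pd.DataFrame, infiltration: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of risk/regulon scores with immune infiltration.

    Long-format table of (score, cell_type, r, p, stars) over shared samples;
    star coding * p<0.05, ** p<0.01, *** p<0.001. Zero-variance columns are
    reported missing.
    """
    shared = scores.index.intersection(infiltration.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    from scipy import stats as st

    rows = []
    for sc in scores.columns:
        x = scores.loc[shared, sc].to_numpy(dtype=float)
        for ct in infiltration.columns:
            y = infiltration.loc[shared, ct].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                rows.append({"score": sc, "cell_type": ct, "r": np.nan, "pvalue": np.nan, "stars": ""})
                continue
            r, p = st.pearsonr(x, y)
            rows.append({"score": sc, "cell_type": ct, "r": float(r), "pvalue": float(p), "stars": _stars(p)})
    return pd.DataFrame(rows)
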