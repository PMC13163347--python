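"""Survival analytics: KM, log-rank, cutpoint, Cox, risk model, ROC."""

import numpy as np
import pandas as pd
import pytest

from tmekit.survival import (
    RiskModel,
    cox_hr,
    fit_risk_model,
    infiltration_correlation,
    km_estimate,
    logrank,
    module_survival,
    optimal_cutpoint,
    risk_score,
    split_cohort,
    stratify_median,
    time_roc,
)
from tmekit.synth import CohortConfig, generate_regulon_scores, generate_survival


def _records(time, event):
    n = len(time)
    age = 50.0 + np.arange(n) % 30  # varying, outcome-independent covariate
    return pd.DataFrame(
        {"time": time, "event": event, "age": age}, index=[f"P{i}" for i in range(n)]
    )


def km_oracle(time, event):
    """Product-limit estimator by direct risk-set enumeration."""
    out = {0.0: 1.0}
    s = 1.0
    for tau in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        n = (np.asarray(time) >= tau).sum()
        d = ((np.asarray(time) == tau) & (np.asarray(event) == 1)).sum()
        s *= 1 - d / n
        out[tau] = s
    return out


def logrank_oracle(time, event, groups):
    """Multigroup log-rank by risk-set enumeration (hypergeometric variance)."""
    time, event, groups = map(np.asarray, (time, event, groups))
    labels = np.unique(groups)
    g = len(labels)
    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for tau in sorted(set(time[event == 1])):
        at = time >= tau
        n = at.sum()
        d = ((time == tau) & (event == 1)).sum()
        ni = np.array([(at & (groups == l)).sum() for l in labels], dtype=float)
        di = np.array([((time == tau) & (event == 1) & (groups == l)).sum() for l in labels], dtype=float)
        O += di
        E += d * ni / n
        if n > 1:
            for a in range(g):
                for b in range(g):
                    if a == b:
                        V[a, b] += d * (n - d) / (n - 1) * ni[a] * (n - ni[a]) / n**2
                    else:
                        V[a, b] += -d * (n - d) / (n - 1) * ni[a] * ni[b] / n**2
    U = (O - E)[:-1]
    return float(U @ np.linalg.solve(V[:-1, :-1], U))


class TestKm:
    def test_no_events_flat_one(self):
        km = km_estimate(_records([1.0, 2.0, 3.0], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()

    def test_half_survival_at_second_death(self):
        km = km_estimate(_records([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0]))
        s_at_2 = km.set_index("time")["survival"].loc[2.0]
        assert s_at_2 == pytest.approx(0.5)  # (3/4) * (2/3)

    def test_matches_oracle_and_monotone(self, rng):
        time = rng.exponential(5.0, size=20).round(1) + 0.1
        event = rng.integers(0, 2, size=20)
        km = km_estimate(_records(time, event))
        ref = km_oracle(time, event)
        sf = km.set_index("time")["survival"]
        for tau, s in ref.items():
            assert sf.loc[tau] == pytest.approx(s, abs=1e-10)
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_uncensored_complements_ecdf(self, rng):
        time = rng.exponential(3.0, size=15) + 0.01
        km = km_estimate(_records(time, np.ones(15, dtype=int)))
        sf = km.set_index("time")["survival"]
        for t in time:
            assert 1 - sf.loc[t] == pytest.approx((time <= t).mean(), abs=1e-10)


class TestLogrank:
    def test_identical_groups_zero(self):
        rec = _records([1.0, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        stat, df, p = logrank(["A", "A", "A", "B", "B", "B"], rec)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("g", [2, 3])
    def test_matches_riskset_oracle(self, rng, g):
        for rep in range(5):
            n = 20
            time = rng.exponential(4.0, size=n).round(2) + 0.1
            event = rng.integers(0, 2, size=n)
            groups = rng.integers(0, g, size=n).astype(str)
            if len(np.unique(groups)) < g or event.sum() == 0:
                continue
            stat, df, _ = logrank(groups, _records(time, event))
            assert stat == pytest.approx(logrank_oracle(time, event, groups), abs=1e-10)
            assert df == len(np.unique(groups)) - 1


class TestOptimalCutpoint:
    def test_perfect_separation(self):
        # low scores all die early, high scores all censored late
        rec = _records(
            [1.0, 1.5, 2.0, 2.5, 3.0, 9.0, 9.5, 10.0, 10.5, 11.0],
            [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        )
        scores = pd.Series(
            [0.1, 0.15, 0.2, 0.25, 0.3, 0.7, 0.75, 0.8, 0.85, 0.9], index=rec.index
        )
        cut, z = optimal_cutpoint(scores, rec, minprop=0.2)
        assert 0.3 < cut < 0.7

    def test_minprop_half_leaves_median_split(self):
        rng = np.random.default_rng(1)
        rec = _records(rng.exponential(5, 10) + 0.1, np.ones(10, dtype=int))
        scores = pd.Series(np.arange(10, dtype=float), index=rec.index)
        cut, _ = optimal_cutpoint(scores, rec, minprop=0.5)
        assert cut == pytest.approx(4.5)

    def test_step_hazard_recovery(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = rng.uniform(0, 1, 500)
            rate = 0.1 * np.where(s > 0.5, 3.0, 1.0)
            t_ev = rng.exponential(1 / rate)
            t_c = rng.exponential(20.0, 500)
            rec = _records(np.minimum(t_ev, t_c), (t_ev <= t_c).astype(int))
            cut, _ = optimal_cutpoint(pd.Series(s, index=rec.index), rec)
            hits += 0.4 <= cut <= 0.6
        assert hits >= 9

    def test_zero_variance_rejected(self):
        rec = _records([1.0, 2, 3, 4], [1, 1, 0, 0])
        with pytest.raises(ValueError, match="variance"):
            optimal_cutpoint(pd.Series(1.0, index=rec.index), rec)


class TestCoxHr:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.normal(size=n)
        rec = _records(rng.exponential(5.0, n) + 0.01, np.ones(n, dtype=int))
        out = cox_hr(pd.Series(x, index=rec.index), rec, covariates=["age"])
        assert 0.9 <= out["hr"] <= 1.1

    def test_planted_hr_recovery_and_direction(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        rate = 0.2 * np.exp(np.log(2.0) * x)
        t_ev = rng.exponential(1 / rate)
        t_c = rng.exponential(50.0, n)
        rec = _records(np.minimum(t_ev, t_c), (t_ev <= t_c).astype(int))
        out = cox_hr(pd.Series(x, index=rec.index), rec, covariates=["age"])
        assert 1.7 <= out["hr"] <= 2.3
        assert out["direction"] == "Worse survival"
        assert out["ci_low"] < out["hr"] < out["ci_high"]

    def test_protective_direction_label(self):
        rng = np.random.default_rng(5)
        n = 800
        x = rng.integers(0, 2, n).astype(float)
        rate = 0.2 * np.exp(-0.7 * x)
        rec = _records(rng.exponential(1 / rate), np.ones(n, dtype=int))
        out = cox_hr(pd.Series(x, index=rec.index), rec, covariates=["age"])
        assert out["hr"] < 1
        assert out["direction"] == "Better survival"


class TestSplitCohort:
    def test_paper_cohort_arithmetic(self):
        for seed in range(10):
            tr, te = split_cohort(917, 0.7, seed=seed)
            assert (len(tr), len(te)) == (641, 276)

    @pytest.mark.parametrize("n,frac", [(10, 0.7), (2, 0.5), (101, 0.33)])
    def test_partition_properties(self, n, frac):
        tr, te = split_cohort(n, frac, seed=1)
        assert len(tr) == int(np.floor(frac * n))
        assert len(tr) + len(te) == n
        assert set(tr) | set(te) == set(range(n))
        assert set(tr) & set(te) == set()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(10, 1.0)


class TestRiskModel:
    def test_risk_score_is_dot_product(self, rng):
        scores = pd.DataFrame(rng.normal(size=(20, 9)), columns=[f"R{i}" for i in range(9)])
        model = RiskModel(regulons=[f"R{i}" for i in range(9)], coefficients=list(rng.normal(size=9)))
        rs = risk_score(scores, model)
        np.testing.assert_allclose(
            rs, scores.to_numpy() @ np.array(model.coefficients), atol=1e-12
        )
        # linearity
        np.testing.assert_allclose(risk_score(scores * 3.0, model), rs * 3.0, atol=1e-12)

    def test_simple_cases(self):
        scores = pd.DataFrame({"a": [2.0], "b": [3.0]})
        assert risk_score(scores, RiskModel(["a", "b"], [1.0, -1.0])).iloc[0] == pytest.approx(-1.0)
        assert risk_score(scores, RiskModel(["a", "b"], [0.0, 0.0])).iloc[0] == 0.0

    def test_missing_column_rejected(self):
        scores = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            risk_score(scores, RiskModel(["a", "zz"], [1.0, 1.0]))

    def test_single_candidate_unpenalized_matches_cox(self):
        betas = {"R00": 0.8, "R01": 0.0}
        cfg = CohortConfig(seed=9, n_patients=400, surv_betas=betas, censor_rate=0.02)
        scores = generate_regulon_scores(cfg, sorted(betas))
        rec, _ = generate_survival(scores, cfg)
        model = fit_risk_model(scores, rec, alpha=1e-9, seed=0)
        assert "R00" in model.regulons
        ref = cox_hr(scores["R00"], rec, covariates=[])
        beta_hat = model.coefficients[model.regulons.index("R00")]
        # same data, both unpenalized: coefficients agree closely
        assert beta_hat == pytest.approx(np.log(ref["hr"]), abs=1e-2)

    def test_planted_regulon_selection(self):
        betas = {f"R{i:02d}": (0.5 if i < 3 else 0.0) for i in range(20)}
        cfg = CohortConfig(seed=5, n_patients=600, surv_betas=betas, censor_rate=0.03)
        scores = generate_regulon_scores(cfg, sorted(betas))
        rec, _ = generate_survival(scores, cfg)
        model = fit_risk_model(scores, rec, seed=5)
        sel = set(model.regulons)
        assert {"R00", "R01", "R02"} <= sel
        assert len(sel - {"R00", "R01", "R02"}) <= 4
        assert model.status == "ok"

    def test_all_noise_returns_small_or_empty_model(self):
        betas = {f"R{i:02d}": 0.0 for i in range(10)}
        empty_or_small = 0
        for seed in range(5):
            cfg = CohortConfig(seed=100 + seed, n_patients=300, surv_betas=betas, censor_rate=0.02)
            scores = generate_regulon_scores(cfg, sorted(betas))
            rec, _ = generate_survival(scores, cfg)
            model = fit_risk_model(scores, rec, seed=seed)
            empty_or_small += len(model.regulons) <= 1
        assert empty_or_small >= 4

    def test_stratify_median(self):
        rs = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        grp = stratify_median(rs)
        assert set(rs.index[grp == "high"]) == {"c", "d"}
        # all-equal scores -> all low by the tie convention
        assert (stratify_median(pd.Series([2.0, 2.0, 2.0])) == "low").all()


class TestTimeRoc:
    def test_perfect_ranking_auc_one(self):
        time = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        rec = _records(time, np.ones(8, dtype=int))
        rs = pd.Series(-time, index=rec.index)  # higher score = earlier death
        auc = time_roc(rs, rec, horizons=[2.5, 4.5])
        assert np.allclose(auc.to_numpy(), 1.0)

    def test_matches_pair_counting_uncensored(self, rng):
        n = 8
        time = rng.exponential(5.0, n) + 0.1
        rec = _records(time, np.ones(n, dtype=int))
        rs = pd.Series(rng.normal(size=n), index=rec.index)
        t0 = float(np.median(time))
        auc = time_roc(rs, rec, horizons=[t0]).iloc[0]
        cases = time <= t0
        controls = time > t0
        num = den = 0.0
        for i in np.where(cases)[0]:
            for j in np.where(controls)[0]:
                num += (rs.iloc[i] > rs.iloc[j]) + 0.5 * (rs.iloc[i] == rs.iloc[j])
                den += 1
        assert auc == pytest.approx(num / den, abs=1e-12)

    def test_uninformative_score_near_half(self):
        rng = np.random.default_rng(8)
        n = 2000
        rec = _records(rng.exponential(5.0, n) + 0.01, np.ones(n, dtype=int))
        rs = pd.Series(rng.normal(size=n), index=rec.index)
        auc = time_roc(rs, rec, horizons=[3.0])
        assert 0.45 <= auc.iloc[0] <= 0.55

    def test_horizon_beyond_followup_missing(self):
        rec = _records([1.0, 2.0, 3.0], [1, 1, 1])
        rs = pd.Series([1.0, 2.0, 3.0], index=rec.index)
        with pytest.warns(UserWarning, match="beyond follow-up"):
            auc = time_roc(rs, rec, horizons=[10.0])
        assert np.isnan(auc.iloc[0])


class TestModuleSurvival:
    def test_planted_prognostic_module(self):
        rng = np.random.default_rng(2)
        n = 400
        genes = [f"g{j}" for j in range(40)]
        bulk = pd.DataFrame(rng.normal(size=(n, 40)), columns=genes, index=[f"P{i}" for i in range(n)])
        markers = {"CM1": genes[:30], "CM2": genes[30:40] + ["absent"] * 25}
        score = bulk[genes[:30]].mean(axis=1)
        rate = 0.1 * np.exp(1.5 * (score > score.median()))
        t_ev = rng.exponential(1 / rate)
        t_c = rng.exponential(30.0, n)
        rec = pd.DataFrame(
            {"time": np.minimum(t_ev, t_c), "event": (t_ev <= t_c).astype(int)}, index=bulk.index
        )
        out = module_survival(bulk, markers, rec).set_index("module")
        assert out.loc["CM1", "status"] == "ok"
        assert out.loc["CM1", "logrank_p"] < 0.01
        assert out.loc["CM2", "status"] == "insufficient_markers"

    def test_constant_module_skipped(self):
        bulk = pd.DataFrame({"g0": [1.0] * 10, "g1": [1.0] * 10}, index=[f"P{i}" for i in range(10)])
        rec = pd.DataFrame(
            {"time": np.arange(1.0, 11.0), "event": [1] * 10}, index=bulk.index
        )
        out = module_survival(bulk, {"CM1": ["g0", "g1"]}, rec)
        assert out.iloc[0]["status"] == "constant_score"

    def test_mean_of_markers_matches_row_mean(self, rng):
        bulk = pd.DataFrame(rng.normal(size=(60, 6)), columns=[f"g{j}" for j in range(6)])
        bulk.index = [f"P{i}" for i in range(60)]
        rec = pd.DataFrame(
            {"time": rng.exponential(5.0, 60) + 0.1, "event": 1}, index=bulk.index
        )
        out = module_survival(bulk, {"CM1": ["g0", "g1", "g2"]}, rec).iloc[0]
        score = bulk[["g0", "g1", "g2"]].mean(axis=1)
        assert out["n_high"] == int((score > out["cutoff"]).sum())


class TestInfiltrationCorrelation:
    def test_duplicated_column_r_one(self, rng):
        idx = [f"P{i}" for i in range(30)]
        scores = pd.DataFrame({"RS": rng.normal(size=30)}, index=idx)
        infil = pd.DataFrame({"Tcell": scores["RS"], "B": rng.normal(size=30)}, index=idx)
        out = infiltration_correlation(scores, infil).set_index("cell_type")
        assert out.loc["Tcell", "r"] == pytest.approx(1.0)
        assert out.loc["Tcell", "stars"] == "***"

    def test_matches_hand_computed_r(self, rng):
        idx = [f"P{i}" for i in range(12)]
        scores = pd.DataFrame({"R1": rng.normal(size=12)}, index=idx)
        infil = pd.DataFrame({"NK": rng.normal(size=12)}, index=idx)
        out = infiltration_correlation(scores, infil).iloc[0]
        x, y = scores["R1"], infil["NK"]
        r_ref = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out["r"] == pytest.approx(r_ref, abs=1e-12)

    def test_independent_columns_small_r(self):
        rng = np.random.default_rng(9)
        idx = [f"P{i}" for i in range(1000)]
        scores = pd.DataFrame({"RS": rng.normal(size=1000)}, index=idx)
        infil = pd.DataFrame({c: rng.normal(size=1000) for c in "abcde"}, index=idx)
        out = infiltration_correlation(scores, infil)
        assert (out["r"].abs() < 0.1).mean() >= 0.95
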