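import dataclasses

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.optimize import minimize_scalar

from modsurv import (
    ModsurvError,
    ModuleDMFSModel,
    ModuleSpec,
    NonIdentifiableError,
    SimulationConfig,
    bh_adjust,
    cox_stratified,
    km_median_split,
    module_dmfs_scan,
    score_signatures,
    select_covariates,
    simulate_cohort,
)
from modsurv._fastcox import univariate_cox_batch

from conftest import make_clinical, planted_signature


def hand_partial_loglik(beta, time, event, x, strata):
    """Independent oracle: stratified Cox partial log-likelihood written
    directly from its definition (Efron ties), evaluated by brute force."""
    ll = 0.0
    for s in np.unique(strata):
        m = strata == s
        t, e, xs = time[m], event[m], x[m]
        for ut in np.unique(t[e == 1]):
            deaths = (t == ut) & (e == 1)
            risk = t >= ut
            d = deaths.sum()
            theta_risk = np.exp(beta * xs[risk]).sum()
            theta_death = np.exp(beta * xs[deaths]).sum()
            ll += beta * xs[deaths].sum()
            for j in range(d):
                ll -= np.log(theta_risk - (j / d) * theta_death)
    return ll


class TestCoxStratified:
    def test_symmetric_construction_gives_hr_one(self):
        # two strata; within each, pairs with identical times and opposite
        # predictor signs, so the partial likelihood is symmetric in beta
        time = np.array([1.0, 1.0, 2.0, 2.0, 1.5, 1.5, 3.0, 3.0])
        event = np.ones(8, dtype=int)
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        strata = np.array(["a"] * 4 + ["b"] * 4)
        res = cox_stratified(time, event, x, strata)
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_partial_likelihood_oracle(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(size=10) + 0.1
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0, 1, 0, 1, 1, 0, 0, 1, 0])
        strata = np.array(["a"] * 5 + ["b"] * 5)
        res = cox_stratified(time, event, x, strata)
        opt = minimize_scalar(
            lambda b: -hand_partial_loglik(b, time, event, x, strata),
            bounds=(-4, 4), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.coef == pytest.approx(opt.x, abs=1e-4)

    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(5)
        n = 60
        x = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.4 * x))
        event = (rng.random(n) < 0.8).astype(int)
        res = cox_stratified(time, event, x, np.array(["only"] * n))
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e")
        assert res.coef == pytest.approx(cph.summary.loc["x", "coef"], abs=1e-8)
        assert res.se == pytest.approx(cph.summary.loc["x", "se(coef)"], abs=1e-8)

    def test_one_unit_convention_scaling(self):
        rng = np.random.default_rng(6)
        n = 80
        x = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.5 * x))
        event = np.ones(n, dtype=int)
        strata = np.array(["s"] * n)
        b1 = cox_stratified(time, event, x, strata).coef
        b2 = cox_stratified(time, event, 2.0 * x, strata).coef
        assert b2 == pytest.approx(b1 / 2.0, rel=1e-6)

    def test_ci_contains_hr_and_exp_relation(self):
        rng = np.random.default_rng(7)
        n = 50
        x = rng.normal(size=n)
        res = cox_stratified(rng.exponential(size=n), np.ones(n, dtype=int),
                             x, np.array(["s"] * n))
        assert res.ci_low < res.hr < res.ci_high
        assert res.hr == pytest.approx(np.exp(res.coef))

    def test_constant_predictor_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            cox_stratified([1, 2, 3, 4], [1, 1, 1, 1], [2.0] * 4, ["a"] * 4)

    def test_too_few_events(self):
        with pytest.raises(ModsurvError, match=">= 2 events"):
            cox_stratified([1, 2, 3], [1, 0, 0], [1.0, 2.0, 3.0], ["a"] * 3)


def test_fast_cox_matches_lifelines_with_ties():
    rng = np.random.default_rng(8)
    n = 120
    X = rng.normal(size=(n, 3))
    X[:, 1] = (X[:, 1] > 0).astype(float)  # binary covariate
    time = np.round(rng.exponential(np.exp(-0.5 * X[:, 0])), 1) + 0.1  # ties
    event = (rng.random(n) < 0.7).astype(int)
    beta, se, ok = univariate_cox_batch(time, event, X)
    assert ok.all()
    for j in range(3):
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event, "x": X[:, j]}), "t", "e")
        assert beta[j] == pytest.approx(cph.summary.loc["x", "coef"], abs=1e-6)
        assert se[j] == pytest.approx(cph.summary.loc["x", "se(coef)"], abs=1e-6)


class TestSelectCovariates:
    def test_empty_candidates_give_empty_selection(self, planted_cohort):
        _, _, clinical, _ = planted_cohort
        assert select_covariates(clinical, []) == []

    def test_planted_node_effect_is_selected(self):
        cfg = SimulationConfig(
            n_studies=4, samples_per_study=250, n_genes=10,
            covariate_log_hr={"nodal_status=positive": np.log(1.7)}, seed=42,
        )
        _, clinical, _ = simulate_cohort(cfg)
        selected = select_covariates(
            clinical, ["age_group", "nodal_status", "grade", "treatment"])
        assert "nodal_status" in selected

    def test_too_few_events_rejected(self):
        clin = make_clinical([1.0] * 20, [1] * 5 + [0] * 15)
        with pytest.raises(ModsurvError, match=">= 10"):
            select_covariates(clin, ["age_group"])


class TestModuleScan:
    def test_planted_module_flagged_significant(self, planted_cohort, planted_sig):
        _, studies, clinical, _ = planted_cohort
        scores = score_signatures(studies, [planted_sig])
        res = module_dmfs_scan(scores, clinical)
        assert len(res.results) == 1
        r = res.results[0]
        assert r.fdr == r.p  # single module: FDR equals p
        assert r.fdr < 0.05
        assert r.hr > 1.0

    def test_adjusted_scan_runs_with_explicit_covariates(self, planted_cohort, planted_sig):
        _, studies, clinical, _ = planted_cohort
        scores = score_signatures(studies, [planted_sig])
        res = ModuleDMFSModel(scores, clinical, adjust=["nodal_status", "grade"]).fit()
        assert res.covariates == ["nodal_status", "grade"]
        assert len(res.results) == 1
        summary = res.summary()
        assert {"predictor", "HR", "p", "FDR", "significant"} <= set(summary.columns)

    def test_bh_hand_case(self):
        # step-up on (.01,.02,.03,.04) with m=4 gives .04 everywhere
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_bh_monotone_and_at_least_p(self):
        rng = np.random.default_rng(9)
        p = rng.random(25)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestKMMedianSplit:
    def test_identical_groups_give_chi2_zero(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        scores = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        km = km_median_split(scores, time, event)
        assert km.chi_square == pytest.approx(0.0, abs=1e-12)
        assert km.p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(10)
        n = 40
        s = rng.normal(size=n)
        t = rng.exponential(size=n)
        e = np.ones(n, dtype=int)
        km1 = km_median_split(s, t, e)
        km2 = km_median_split(-s, t, e)  # high/low swap
        assert km1.chi_square == pytest.approx(km2.chi_square, rel=1e-9)

    def test_mass_at_median_rejected(self):
        # median equals the maximum -> the 'high' (> median) group is empty
        with pytest.raises(ModsurvError, match="empty group|zero variance"):
            km_median_split([1.0, 2.0, 2.0, 2.0], [1, 2, 3, 4], [1, 1, 1, 1])

    def test_km_without_censoring_is_empirical_survival(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        scores = np.array([0, 0, 0, 1, 1, 1.0])
        km = km_median_split(scores, time, event)
        sf = km.survival_functions["low"]  # times 1,2,3 all events
        # S(1)=2/3, S(2)=1/3, S(3)=0
        assert sf.loc[1.0].iloc[0] == pytest.approx(2 / 3)
        assert sf.loc[2.0].iloc[0] == pytest.approx(1 / 3)
        assert sf.loc[3.0].iloc[0] == pytest.approx(0.0)

    def test_planted_effect_separates_groups(self, planted_cohort, planted_sig):
        _, studies, clinical, _ = planted_cohort
        scores = score_signatures(studies, [planted_sig])
        df = clinical.df.set_index("sample_id").loc[scores.samples]
        km = km_median_split(scores.scaled["plant"].to_numpy(),
                             df["dmfs_time"].to_numpy(), df["dmfs_event"].to_numpy())
        assert km.p < 0.01
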