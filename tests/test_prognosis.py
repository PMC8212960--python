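"""Survival kernels: log-rank, maxstat, KM, Cox, search, tdROC."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet import simulate
from cernet.datatypes import SimulationConfig, log2p1
from cernet.prognosis import (
    exhaustive_signature_search,
    fit_cox,
    independence_analysis,
    km_estimate,
    logrank_test,
    maxstat_cutoff,
    risk_score,
    screen_survival_lncRNAs,
    time_dependent_auc,
)


def hand_logrank(time, event, group):
    """Log-rank statistic tabulated from first principles in exact arithmetic."""
    time = list(map(float, time))
    o_minus_e = Fraction(0)
    var = Fraction(0)
    for tau in sorted({t for t, e in zip(time, event) if e == 1}):
        at = [i for i, t in enumerate(time) if t >= tau]
        n = len(at)
        n1 = sum(1 for i in at if group[i])
        dead = [i for i, (t, e) in enumerate(zip(time, event))
                if t == tau and e == 1]
        d = len(dead)
        d1 = sum(1 for i in dead if group[i])
        if n <= 1:
            continue
        o_minus_e += d1 - Fraction(d * n1, n)
        var += (
            Fraction(d * n1, n)
            * Fraction(n - n1, n)
            * Fraction(n - d, n - 1)
        )
    return float(o_minus_e**2 / var) if var else 0.0


class TestLogrank:
    def test_identical_groups_null(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 0, 1] * 2
        group = [True] * 4 + [False] * 4
        chi2, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_ten_patient_hand_tabulation(self):
        time = [1, 2, 3, 4, 5, 2, 4, 5, 6, 8]
        event = [1, 1, 0, 1, 1, 1, 0, 1, 1, 0]
        group = [True] * 5 + [False] * 5
        chi2, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(hand_logrank(time, event, group), abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-15)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(0)
        time = rng.exponential(5, 40)
        event = rng.integers(0, 2, 40)
        event[0] = 1
        group = rng.integers(0, 2, 40).astype(bool)
        chi2, p = logrank_test(time, event, group)
        ref = ll_logrank(
            time[group], time[~group], event[group], event[~group]
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_null_permutation_calibration(self):
        """Permuted labels on null data give uniform p-values."""
        rng = np.random.default_rng(1)
        time = rng.exponential(5, 60)
        event = rng.integers(0, 2, 60)
        event[:5] = 1
        ps = []
        for _ in range(200):
            group = np.zeros(60, dtype=bool)
            group[rng.choice(60, 30, replace=False)] = True
            ps.append(logrank_test(time, event, group)[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            logrank_test([1, 2], [1, 1], [True, True])

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            logrank_test([1, 2], [0, 0], [True, False])


class TestMaxstat:
    def test_separable_clusters(self):
        values = np.array([1.0] * 15 + [10.0] * 15)
        time = np.array([10.0] * 15 + [1.0] * 15)
        event = np.ones(30, dtype=int)
        cutoff, chi2, p, p_corr = maxstat_cutoff(values, time, event)
        assert 1.0 <= cutoff < 10.0
        assert p < 1e-6
        assert p_corr >= p

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="admissible"):
            maxstat_cutoff(np.ones(30), np.arange(1, 31.0), np.ones(30, int))

    def test_matches_brute_force_scan(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, 30)
        time = rng.exponential(5, 30) * np.exp(-0.5 * values)
        event = rng.integers(0, 2, 30)
        event[:3] = 1
        cutoff, chi2, *_ = maxstat_cutoff(values, time, event)
        lo, hi = np.quantile(values, (0.1, 0.9))
        best = 0.0
        for c in np.unique(values):
            if not lo <= c <= hi:
                continue
            g = values > c
            if g.all() or (~g).all() or event[g].sum() == 0 or event[~g].sum() == 0:
                continue
            ref = ll_logrank(time[g], time[~g], event[g], event[~g])
            best = max(best, ref.test_statistic)
        assert chi2 == pytest.approx(best, rel=1e-9)


class TestKaplanMeier:
    def test_no_censoring_equals_ecdf(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(5, 50)
        sf, median = km_estimate(time, np.ones(50, int))
        for _, row in sf.iterrows():
            ecdf = np.mean(time > row["time"])
            assert row["survival"] == pytest.approx(ecdf, abs=1e-12)
        assert median == pytest.approx(np.sort(time)[24], abs=1e-12)

    def test_all_censored_flat_curve(self):
        sf, median = km_estimate([1, 2, 3], [0, 0, 0])
        assert (sf["survival"] == 1.0).all()
        assert np.isnan(median)

    def test_hand_product_with_censoring(self):
        # times (1, 2+, 3, 4), events (1, 0, 1, 1)
        sf, median = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        s = dict(zip(sf["time"], sf["survival"]))
        assert s[1.0] == pytest.approx(3 / 4)
        assert s[3.0] == pytest.approx(3 / 4 * 1 / 2)
        assert s[4.0] == pytest.approx(0.0)
        assert median == pytest.approx(3.0)


class TestCox:
    def test_null_covariate_small_coefficient(self):
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.normal(0, 1, n)
        time = rng.exponential(5, n)
        event = np.ones(n, int)
        res = fit_cox(x, time, event)
        assert res.converged
        assert abs(res.coef[0]) < 3 * res.se[0]

    def test_four_subject_grid_search_oracle(self):
        """Argmax of the explicitly enumerated partial likelihood."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = fit_cox(x, time, event)

        def log_pl(beta):
            theta = np.exp(beta * x)
            # risk sets at event times 1, 2, 4
            ll = 0.0
            for i, risk in [(0, [0, 1, 2, 3]), (1, [1, 2, 3]), (3, [3])]:
                ll += beta * x[i] - np.log(theta[risk].sum())
            return ll

        grid = np.arange(-3.0, 3.0, 1e-4)
        best = grid[np.argmax([log_pl(b) for b in grid])]
        assert res.coef[0] == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        n = 120
        X = rng.normal(0, 1, (n, 2))
        time = np.round(rng.exponential(5, n) * np.exp(-0.4 * X[:, 0]), 1) + 0.1
        event = rng.integers(0, 2, n)
        event[:10] = 1
        res = fit_cox(X, time, event, names=["a", "b"])
        df = pd.DataFrame({"t": time, "e": event, "a": X[:, 0], "b": X[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(res.coef, cph.params_.values, atol=1e-6)
        assert np.allclose(res.se, cph.standard_errors_.values, atol=1e-6)

    def test_planted_coefficient_recovery(self):
        coefs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.normal(0, 1, n)
            time = rng.exponential(10, n) * np.exp(-0.8 * x)
            cens = rng.uniform(0, 30, n)
            obs = np.minimum(time, cens)
            event = (time <= cens).astype(int)
            coefs.append(fit_cox(x, obs, event).coef[0])
        assert abs(np.mean(coefs) - 0.8) < 0.15

    def test_separation_flagged_not_raised(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, int)
        x = np.array([1.0, 1, 1, 0, 0, 0])  # perfect separation
        res = fit_cox(x, time, event)
        assert res.separation

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox(np.ones(10), np.arange(1, 11.0), np.ones(10, int))


class TestRiskScore:
    def _expr(self):
        return pd.DataFrame(
            [[15.0, 3.0], [1.0, 7.0]], index=["L1", "L2"], columns=["s1", "s2"]
        )

    def test_zero_coefficients(self):
        s = risk_score(self._expr(), {"L1": 0.0, "L2": 0.0})
        assert (s == 0).all()

    def test_identity_single_gene(self):
        s = risk_score(self._expr(), {"L1": 1.0})
        assert np.allclose(s.values, log2p1([15.0, 3.0]))

    def test_direct_arithmetic(self):
        # x=(0.5, -2) applied to working values e=(4, 1) -> 0
        expr = pd.DataFrame([[15.0], [1.0]], index=["L1", "L2"], columns=["s"])
        s = risk_score(expr, {"L1": 0.5, "L2": -2.0})
        assert s["s"] == pytest.approx(0.0)

    def test_missing_gene_named(self):
        with pytest.raises(ValueError, match="L9"):
            risk_score(self._expr(), {"L9": 1.0})


@pytest.fixture(scope="module")
def survival_dataset():
    cfg = SimulationConfig(
        n_patients=200, n_lncRNA=30, n_PCG=40, n_de_lnc=10, n_de_pcg=10,
        n_true_cerna=5, signature_coefs=(0.8, -0.8, 0.6), censor_rate=0.3,
        rng_seed=17,
    )
    data, truth = simulate.simulate_expression(cfg)
    surv = simulate.simulate_survival(data, cfg, truth)
    return cfg, data, truth, surv


class TestScreenAndSearch:
    def test_planted_signature_screened_in(self, survival_dataset):
        _, data, truth, surv = survival_dataset
        sig = [g for g, _ in truth.true_signature]
        screen = screen_survival_lncRNAs(sig, data, surv)
        assert screen["kept"].all()

    def test_empty_candidates_empty_output(self, survival_dataset):
        _, data, _, surv = survival_dataset
        out = screen_survival_lncRNAs([], data, surv)
        assert out.empty

    def test_single_candidate_single_model(self, survival_dataset):
        _, data, truth, surv = survival_dataset
        g = truth.true_signature[0][0]
        model, models = exhaustive_signature_search([g], data, surv)
        assert len(models) == 1
        assert models.attrs["n_evaluated"] == 1
        assert model is not None and model.lncRNAs == (g,)

    def test_subset_count_is_two_to_k_minus_one(self, survival_dataset):
        _, data, truth, surv = survival_dataset
        genes = [g for g, _ in truth.true_signature] + sorted(
            set(truth.de_lnc_ids) - {g for g, _ in truth.true_signature}
        )[:2]
        model, models = exhaustive_signature_search(genes, data, surv)
        assert models.attrs["n_evaluated"] == 2**5 - 1
        assert len(models) == 31
        assert models["bitmask"].is_unique

    def test_too_many_candidates_guarded(self, survival_dataset):
        _, data, _, surv = survival_dataset
        with pytest.raises(ValueError, match=r"\[1, 20\]"):
            exhaustive_signature_search([f"g{i}" for i in range(21)], data, surv)

    def test_coefficient_scaling_leaves_evaluation_invariant(
        self, survival_dataset
    ):
        """Scaling all risk-score coefficients by c > 0 changes neither the
        median split nor the log-rank p nor the AUCs."""
        _, data, truth, surv = survival_dataset
        coefs = pd.Series(dict(truth.true_signature))
        expr = data.expr[list(surv["sample"])]
        time, event = surv["time"].values, surv["event"].values
        for c in (1.0, 3.7):
            s = risk_score(expr, coefs * c).values
            group = s > np.median(s)
            if c == 1.0:
                base_group = group
                base_p = logrank_test(time, event, group)[1]
                base_auc = time_dependent_auc(s, time, event)
            else:
                assert (group == base_group).all()
                assert logrank_test(time, event, group)[1] == pytest.approx(
                    base_p
                )
                aucs = time_dependent_auc(s, time, event)
                for h in base_auc:
                    assert aucs[h] == pytest.approx(base_auc[h])


class TestTimeDependentAUC:
    def test_null_scores_near_half(self):
        rng = np.random.default_rng(6)
        n = 4000
        scores = rng.normal(0, 1, n)
        time = rng.exponential(5, n)
        event = np.ones(n, int)
        aucs = time_dependent_auc(scores, time, event, horizons=(1, 3, 5))
        for auc in aucs.values():
            assert auc == pytest.approx(0.5, abs=0.04)

    def test_perfect_ranking_uncensored(self):
        rng = np.random.default_rng(7)
        time = rng.uniform(0.5, 20, 300)
        aucs = time_dependent_auc(-time, time, np.ones(300, int), (1, 3, 5, 10))
        for auc in aucs.values():
            assert auc == pytest.approx(1.0)

    def test_uncensored_equals_plain_rank_auc(self):
        rng = np.random.default_rng(8)
        n = 250
        scores = rng.normal(0, 1, n)
        time = rng.exponential(5, n) * np.exp(-0.5 * scores)
        event = np.ones(n, int)
        aucs = time_dependent_auc(scores, time, event, horizons=(2, 5))
        for h in (2, 5):
            cases = (time <= h)
            controls = ~cases
            wins = (
                (scores[cases][:, None] > scores[controls][None, :]).sum()
                + 0.5 * (scores[cases][:, None] == scores[controls][None, :]).sum()
            )
            plain = wins / (cases.sum() * controls.sum())
            assert aucs[h] == pytest.approx(plain, abs=1e-12)

    def test_matches_scikit_survival(self):
        sksurv = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv

        rng = np.random.default_rng(9)
        n = 300
        scores = rng.normal(0, 1, n)
        time = rng.exponential(5, n) * np.exp(-0.6 * scores)
        cens = rng.uniform(0, 15, n)
        obs = np.minimum(time, cens)
        event = time <= cens
        y = Surv.from_arrays(event, obs)
        horizons = (1.0, 3.0)
        ref, _ = sksurv.cumulative_dynamic_auc(y, y, scores, horizons)
        aucs = time_dependent_auc(scores, obs, event.astype(int), horizons)
        for h, r in zip(horizons, ref):
            assert aucs[h] == pytest.approx(r, abs=0.02)

    def test_no_cases_flagged_undefined(self):
        aucs = time_dependent_auc([1, 2], [5, 6], [1, 1], horizons=(1,))
        assert np.isnan(aucs[1])


class TestIndependence:
    def test_table_shape_and_codings(self, survival_dataset):
        _, data, truth, surv = survival_dataset
        coefs = pd.Series(dict(truth.true_signature))
        s = risk_score(data.expr[list(surv["sample"])], coefs)
        high = (s.values > np.median(s.values)).astype(float)
        tab = independence_analysis(surv, high)
        assert len(tab) == 6
        assert set(tab["analysis"]) == {"univariate", "multivariable"}
        sig = tab[(tab["variable"] == "signature")
                  & (tab["analysis"] == "multivariable")]
        assert sig["HR"].iloc[0] > 1.0  # planted positive-risk signature

    def test_null_signature_ci_covers_one(self):
        """Risk labels independent of survival: CI covers HR = 1."""
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 200
            surv = pd.DataFrame(
                {
                    "sample": [f"s{i}" for i in range(n)],
                    "time": rng.exponential(5, n),
                    "event": rng.integers(0, 2, n),
                    "age": rng.integers(35, 85, n),
                    "stage": rng.choice(["I", "II", "III", "IV"], n),
                }
            )
            surv.loc[:10, "event"] = 1
            high = rng.integers(0, 2, n).astype(float)
            tab = independence_analysis(surv, high)
            row = tab[(tab["variable"] == "signature")
                      & (tab["analysis"] == "multivariable")].iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        # 3-sigma binomial band around nominal 95% coverage at 20 replicates:
        # 19 - 3 * sqrt(20 * 0.95 * 0.05) ~ 16
        assert covered >= 16
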