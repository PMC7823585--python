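import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from panclass.survival import (
    CoxFit,
    _cox_newton,
    cox_class_model,
    infiltrate_interaction,
    random_gene_classification,
    replicate_rng,
    v_score,
)

from ._oracles import cox_lifelines


def simulate_cohort(rng, n=200, log_hr=0.7, censor_scale=15.0):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(log_hr * x)))
    c = rng.uniform(0, censor_scale, n)
    return pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)],
         "time": np.maximum(np.minimum(t, c), 1e-9),
         "event": (t <= c).astype(int),
         "class": np.where(x == 1, "C2", "C1")}
    )


class TestCoxNewton:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        df = simulate_cohort(rng)
        x = (df["class"] == "C2").to_numpy(float)
        fit = _cox_newton(x, df["time"].to_numpy(), df["event"].to_numpy())
        beta, p = cox_lifelines(x, df["time"].to_numpy(), df["event"].to_numpy())
        assert fit.log_hr == pytest.approx(beta, abs=1e-5)
        assert fit.p == pytest.approx(p, rel=1e-3)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(7)
        df = simulate_cohort(rng)
        df["time"] = np.ceil(df["time"]).clip(lower=1)  # heavy ties -> Efron path
        x = (df["class"] == "C2").to_numpy(float)
        fit = _cox_newton(x, df["time"].to_numpy(), df["event"].to_numpy())
        beta, _ = cox_lifelines(x, df["time"].to_numpy(), df["event"].to_numpy())
        assert fit.log_hr == pytest.approx(beta, abs=1e-5)

    def test_null_p_uniform(self):
        pvals = []
        for seed in range(120):
            rng = np.random.default_rng(seed)
            df = simulate_cohort(rng, n=100, log_hr=0.0)
            x = (df["class"] == "C2").to_numpy(float)
            fit = _cox_newton(x, df["time"].to_numpy(), df["event"].to_numpy())
            pvals.append(fit.p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_separation_warns(self):
        # all events in one class, tiny n
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="monotone|non-identifiable"):
            fit = _cox_newton(x, time, event)
        assert fit.warning is not None


class TestCoxClassModel:
    def test_parameter_recovery(self, rng):
        df = simulate_cohort(rng, n=500, log_hr=0.7)
        fit = cox_class_model(df)
        assert isinstance(fit, CoxFit)
        assert fit.log_hr == pytest.approx(0.7, abs=0.3)
        lo, hi = fit.ci
        assert lo < fit.hr < hi

    def test_event_gate(self, rng):
        df = simulate_cohort(rng, n=30)
        df["event"] = 0
        df.loc[:4, "event"] = 1
        with pytest.raises(ValueError, match="events"):
            cox_class_model(df)

    def test_requires_both_classes(self, rng):
        df = simulate_cohort(rng)
        df["class"] = "C2"
        with pytest.raises(ValueError, match="both classes"):
            cox_class_model(df)

    def test_positive_times_required(self, rng):
        df = simulate_cohort(rng)
        df.loc[0, "time"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            cox_class_model(df)


class TestRandomGeneClassification:
    @pytest.fixture
    def expr(self, rng):
        return pd.DataFrame(rng.normal(size=(200, 60)),
                            index=[f"g{i}" for i in range(200)],
                            columns=[f"s{j}" for j in range(60)])

    def test_even_median_split(self, expr):
        labels = random_gene_classification(expr, n_genes=50, seed=0)
        assert labels.sum() == 30  # even n: exactly half above the median

    def test_determinism(self, expr):
        l1 = random_gene_classification(expr, n_genes=50, n_target=40, seed=3)
        l2 = random_gene_classification(expr, n_genes=50, n_target=40, seed=3)
        pd.testing.assert_series_equal(l1, l2)

    def test_recovers_planted_clusters(self, rng):
        # two clusters separated along every gene's axis
        n = 80
        truth = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.normal(size=(60, n)) + 4.0 * truth[None, :]
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(60)],
                            columns=[f"s{j}" for j in range(n)])
        labels = random_gene_classification(expr, n_genes=50, seed=1)
        agree = max((labels == truth).mean(), (labels == 1 - truth).mean())
        assert agree >= 0.95

    def test_too_few_genes(self, expr):
        with pytest.raises(ValueError, match="genes"):
            random_gene_classification(expr.iloc[:10], n_genes=50)

    def test_n_target_bound(self, expr):
        with pytest.raises(ValueError, match="n_target"):
            random_gene_classification(expr, n_genes=10, n_target=1000)


class TestVScore:
    @pytest.fixture
    def cohort(self, rng):
        expr = pd.DataFrame(rng.normal(size=(150, 100)),
                            index=[f"g{i}" for i in range(150)],
                            columns=[f"s{j}" for j in range(100)])
        rec = simulate_cohort(rng, n=100, log_hr=0.0)
        rec["sample_id"] = expr.columns
        return expr, rec

    def test_equals_independent_oracle_loop(self, cohort):
        expr, rec = cohort
        obs = cox_class_model(rec)
        R, seed = 50, 9
        res = v_score(expr, rec, obs, R=R, seed=seed)
        # oracle loop: same seeding contract, lifelines Cox fits
        rec_idx = rec.set_index("sample_id")
        n_target = int(rec_idx["class"].isin(["C1", "C2"]).sum())
        wins = 0
        for i in range(R):
            rng_i = replicate_rng(seed, i)
            labels = random_gene_classification(expr, n_genes=50,
                                                n_target=n_target, rng=rng_i)
            sub = rec_idx.loc[labels.index]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta, p = cox_lifelines(labels.to_numpy(float),
                                        sub["time"].to_numpy(), sub["event"].to_numpy())
            if abs(beta) > abs(obs.log_hr) and p < obs.p:
                wins += 1
        assert res.v_score == wins / R

    def test_null_observed_gives_high_v(self, cohort):
        expr, rec = cohort
        res = v_score(expr, rec, (1.0, 1.0), R=100, seed=1)
        assert res.v_score > 0.95

    def test_overwhelming_observed_gives_zero(self, cohort):
        expr, rec = cohort
        res = v_score(expr, rec, (np.exp(50.0), 1e-300), R=100, seed=1)
        assert res.v_score == 0.0

    def test_monotone_in_observed_p(self, cohort):
        expr, rec = cohort
        v_weak = v_score(expr, rec, (1.5, 0.5), R=100, seed=2).v_score
        v_strong = v_score(expr, rec, (1.5, 0.001), R=100, seed=2).v_score
        assert v_strong <= v_weak

    def test_determinism(self, cohort):
        expr, rec = cohort
        r1 = v_score(expr, rec, (1.2, 0.3), R=60, seed=4)
        r2 = v_score(expr, rec, (1.2, 0.3), R=60, seed=4)
        assert r1.v_score == r2.v_score

    def test_r_validation(self, cohort):
        expr, rec = cohort
        with pytest.raises(ValueError, match="R"):
            v_score(expr, rec, (1.0, 0.5), R=0, seed=0)


def simulate_interaction(seed, n=400, effect=(-0.7, 0.7)):
    rng = np.random.default_rng(seed)
    cls = np.where(rng.random(n) < 0.5, "C1", "C2")
    inf = rng.random(n)
    hi = (inf > np.median(inf)).astype(float)
    eff = np.where(cls == "C1", effect[0], effect[1]) * hi
    t = rng.exponential(1.0 / (0.1 * np.exp(eff)))
    c = rng.uniform(0, 20, n)
    return pd.DataFrame(
        {"time": np.maximum(np.minimum(t, c), 1e-9), "event": (t <= c).astype(int),
         "class": cls, "cd8": inf}
    )


class TestInfiltrateInteraction:
    def test_detects_opposite_effects(self):
        df = simulate_interaction(0)
        res = infiltrate_interaction(df, "cd8")
        assert res["interaction_p"] < 0.05
        assert res["deviance"] >= 0
        assert res["deviance_p"] < 0.05
        assert res["per_class_hr"]["C1"]["log_hr"] < 0 < res["per_class_hr"]["C2"]["log_hr"]

    def test_null_interaction_p_uniform(self):
        pvals = []
        for seed in range(40):
            df = simulate_interaction(seed, n=150, effect=(0.0, 0.0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = infiltrate_interaction(df, "cd8", min_events=1)
            pvals.append(res["interaction_p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_deviance_nonnegative_on_nested_models(self):
        for seed in range(5):
            df = simulate_interaction(seed, n=120, effect=(0.3, 0.3))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = infiltrate_interaction(df, "cd8", min_events=1)
            assert res["deviance"] >= 0

    def test_empty_stratum_errors(self):
        df = simulate_interaction(1)
        df["class"] = "C2"
        with pytest.raises(ValueError, match="empty stratum"):
            infiltrate_interaction(df, "cd8")

    def test_low_event_warning(self):
        df = simulate_interaction(2, n=60)
        df.loc[df["class"] == "C1", "event"] = 0
        df.loc[df[df["class"] == "C1"].index[:2], "event"] = 1
        with pytest.warns(UserWarning, match="events"):
            infiltrate_interaction(df, "cd8")
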