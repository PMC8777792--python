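"""Bayesian logit fits: closed forms, shrinkage, AIC, PSIS-LOO, ROC."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trpcap.metabolite_models import (
    INTERCEPT,
    ConvergenceError,
    DesignMatrix,
    MetaboliteModel,
    PriorSpec,
    aic_rank,
    build_design,
    dominant_taxa,
    fit_bayes_logit,
    load_models,
    or_table,
    predict_proba,
    psis_loo,
    roc_holdout,
    save_models,
    significance_band,
    wald_tests,
)
from trpcap.synthetic_data import SimSpec, gen_capability_db
from conftest import make_capability

FLAT = PriorSpec(slope_scale=1000.0, intercept_scale=1000.0)


def design_from_arrays(X: dict[str, np.ndarray], y, metabolite="met", host="mouse"):
    return DesignMatrix(X=pd.DataFrame(X), y=np.asarray(y, float),
                        metabolite=metabolite, host_family=host)


def two_by_two_design(a=8, b=2, c=2, d=8):
    """Group 1 (x=1): a producers, b non; group 0: c producers, d non."""
    x = [1] * (a + b) + [0] * (c + d)
    y = [1] * a + [0] * b + [1] * c + [0] * d
    return design_from_arrays({INTERCEPT: np.ones(len(x)), "g": np.array(x)}, y)


class TestBuildDesign:
    @pytest.fixture()
    def cap(self):
        rows = {
            "m1": {"X": True}, "m2": {"X": False}, "m3": {"X": True}, "m4": {"X": False},
        }
        genera = {"m1": "Clostridium", "m2": "Clostridium", "m3": "Rare", "m4": "Bacteroides"}
        mouse = {"m1": True, "m2": False, "m3": True, "m4": False}
        return make_capability(rows, genera, mouse_flags=mouse)

    def test_indicator_coding(self, cap):
        d = build_design(cap, "X", "mouse", ["Clostridium", "Bacteroides"])
        row = d.X.loc["m1"]
        assert row[INTERCEPT] == 1 and row["Clostridium"] == 1
        assert row["Bacteroides"] == 0 and row["mouse_gut"] == 1

    def test_non_dominant_genus_is_baseline(self, cap):
        d = build_design(cap, "X", "mouse", ["Clostridium", "Bacteroides"])
        assert d.X.loc["m3", ["Clostridium", "Bacteroides"]].sum() == 0

    def test_response_equals_capability_column(self, cap):
        d = build_design(cap, "X", "mouse", ["Clostridium"])
        assert np.array_equal(d.y, cap.values["X"].to_numpy(float))

    def test_missing_metabolite_raises(self, cap):
        with pytest.raises(KeyError):
            build_design(cap, "nope", "mouse", ["Clostridium"])


class TestFitBayesLogit:
    def test_flat_prior_recovers_cross_product_odds_ratio(self):
        model = fit_bayes_logit(two_by_two_design(), prior=FLAT)
        # 2x2 closed form: OR = ad/bc = (8*8)/(2*2) = 16
        assert np.exp(model.beta[1]) == pytest.approx(16.0, rel=0.01)

    def test_all_zero_response_shrinks_to_prior(self):
        rng = np.random.default_rng(0)
        X = {INTERCEPT: np.ones(40), "g1": rng.integers(0, 2, 40).astype(float),
             "g2": rng.integers(0, 2, 40).astype(float)}
        with pytest.warns(UserWarning, match="all 0"):
            model = fit_bayes_logit(design_from_arrays(X, np.zeros(40)))
        assert np.all(np.abs(model.beta[1:]) < 0.5)
        assert np.all(predict_proba(model, pd.DataFrame(X)) < 0.1)

    def test_duplicating_data_leaves_mle_unchanged(self):
        d = two_by_two_design(7, 3, 3, 7)
        d2 = design_from_arrays(
            {c: np.tile(d.X[c].to_numpy(), 2) for c in d.X.columns}, np.tile(d.y, 2)
        )
        m1 = fit_bayes_logit(d, prior=FLAT)
        m2 = fit_bayes_logit(d2, prior=FLAT)
        assert np.allclose(m1.beta, m2.beta, atol=1e-4)

    def test_matches_statsmodels_mle_under_flat_prior(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 400
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        eta = -0.5 + 1.2 * x1 - 0.7 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        d = design_from_arrays({INTERCEPT: np.ones(n), "x1": x1, "x2": x2}, y)
        ours = fit_bayes_logit(d, prior=PriorSpec(slope_scale=1e6, intercept_scale=1e6))
        theirs = sm.Logit(y, d.X.to_numpy()).fit(disp=0, method="newton", tol=1e-10)
        assert np.allclose(ours.beta, theirs.params, atol=1e-4)

    def test_posterior_draws_are_seeded(self):
        d = two_by_two_design()
        m1 = fit_bayes_logit(d, seed=42)
        m2 = fit_bayes_logit(d, seed=42)
        assert np.array_equal(m1.draws, m2.draws)
        assert not np.array_equal(m1.draws, fit_bayes_logit(d, seed=43).draws)

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError, match="two observations"):
            fit_bayes_logit(design_from_arrays({INTERCEPT: np.ones(1)}, [1.0]))


class TestWaldTests:
    def model(self, beta, cov):
        return MetaboliteModel(
            metabolite="m", host_family="mouse", columns=[f"c{i}" for i in range(len(beta))],
            beta=np.array(beta, float), cov=np.array(cov, float), prior=PriorSpec(),
            log_lik=0.0, n_obs=10,
        )

    def test_zero_coefficient_p_is_one(self):
        t = wald_tests(self.model([0.0], [[1.0]]))
        assert t["p"].iloc[0] == pytest.approx(1.0)

    def test_z_at_95_quantile(self):
        t = wald_tests(self.model([1.959964], [[1.0]]))
        assert t["p"].iloc[0] == pytest.approx(0.05, abs=1e-6)

    def test_p_monotone_in_abs_z(self):
        t = wald_tests(self.model([0.1, -0.5, 1.0, 3.0], np.eye(4)))
        assert list(t["p"]) == sorted(t["p"], reverse=True)

    def test_non_pd_covariance_raises(self):
        from trpcap.reference_network import TrpcapError

        with pytest.raises(TrpcapError, match="positive definite"):
            wald_tests(self.model([1.0, 1.0], [[1.0, 2.0], [2.0, 1.0]]))

    def test_significance_bands(self):
        assert [significance_band(p) for p in (0.0005, 0.005, 0.03, 0.07, 0.5)] == [
            "<0.001", "<0.01", "<0.05", "<0.1", "ns",
        ]


class TestAicRank:
    def stub(self, k, log_lik, y):
        return MetaboliteModel(
            metabolite="m", host_family="mouse", columns=[f"c{i}" for i in range(k)],
            beta=np.zeros(k), cov=np.eye(k), prior=PriorSpec(), log_lik=log_lik,
            n_obs=len(y), y=np.asarray(y, float),
        )

    def test_aic_formula(self):
        assert self.stub(2, -10.0, [0, 1]).aic == pytest.approx(24.0)

    def test_ties_prefer_fewer_parameters(self):
        y = [0, 1, 0, 1]
        small = self.stub(2, -10.0, y)
        big = self.stub(3, -10.0, y)  # same logLik, one more parameter
        ranked = aic_rank([big, small])
        assert ranked[0] is small

    def test_near_tied_loglik_prefers_smaller_model(self):
        y = [0, 1, 0, 1]
        small = self.stub(2, -10.5, y)  # delta logLik < 1 does not justify +1 param
        big = self.stub(3, -10.0, y)
        assert aic_rank([big, small])[0] is small

    def test_mixed_observations_raise(self):
        with pytest.raises(ValueError, match="identical observations"):
            aic_rank([self.stub(2, -10.0, [0, 1]), self.stub(2, -10.0, [0, 1, 1])])

    def test_genus_plus_host_wins_on_planted_data(self):
        spec = SimSpec(seed=8, n_models_per_genus=80)
        cap, _ = gen_capability_db(spec)
        dom_g = dominant_taxa(cap, rank="genus")
        dom_p = dominant_taxa(cap, rank="phylum")
        met = cap.metabolites[0]
        fits = [
            fit_bayes_logit(build_design(cap, met, "mouse", dom_g), seed=1),
            fit_bayes_logit(build_design(cap, met, "mouse", dom_g, include_host=False), seed=1),
            fit_bayes_logit(build_design(cap, met, "mouse", dom_p, rank="phylum"), seed=1),
        ]
        ranked = aic_rank(fits)
        assert ranked[0] is fits[0]


class TestPsisLoo:
    def test_intercept_only_matches_bernoulli_entropy(self):
        n = 1000
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        d = design_from_arrays({INTERCEPT: np.ones(n)}, y)
        model = fit_bayes_logit(d, seed=0)
        loo = psis_loo(model)
        assert loo.elpd_loo == pytest.approx(n * np.log(0.5), rel=0.01)

    def test_elpd_never_exceeds_in_sample_lpd(self):
        rng = np.random.default_rng(2)
        for seed in range(3):
            n = 120
            x = rng.integers(0, 2, n).astype(float)
            y = (rng.random(n) < 0.3 + 0.4 * x).astype(float)
            d = design_from_arrays({INTERCEPT: np.ones(n), "x": x}, y)
            loo = psis_loo(fit_bayes_logit(d, seed=seed))
            assert loo.elpd_loo <= loo.in_sample_lpd

    def test_degenerate_draws_give_equal_weights(self):
        d = two_by_two_design()
        model = fit_bayes_logit(d, seed=0)
        model.draws = np.tile(model.beta, (500, 1))  # identical draws: flat ratios
        loo = psis_loo(model)
        assert loo.elpd_loo == pytest.approx(loo.in_sample_lpd, abs=1e-10)

    def test_too_few_draws_raise(self):
        model = fit_bayes_logit(two_by_two_design(), n_draws=50)
        with pytest.raises(ValueError, match="100"):
            psis_loo(model)

    def test_pareto_k_is_finite(self):
        loo = psis_loo(fit_bayes_logit(two_by_two_design(), seed=1))
        assert np.isfinite(loo.pareto_k).all()


class TestRocHoldout:
    def deterministic_cap(self, n_per=40):
        """Production fully determined by genus: a perfectly separable problem."""
        rows, genera, mouse = {}, {}, {}
        for g, produces in (("Clostridium", True), ("Bacteroides", False)):
            for i in range(n_per):
                mid = f"{g[:4]}{i}"
                rows[mid] = {"X": produces}
                genera[mid] = g
                mouse[mid] = bool(i % 2)
        return make_capability(rows, genera, mouse_flags=mouse)

    def test_perfect_separation_gives_auc_one(self):
        cap = self.deterministic_cap()
        roc = roc_holdout(cap, "X", "mouse", dominant=["Clostridium", "Bacteroides"],
                          seed=0, n_min=5)
        assert roc.auc == pytest.approx(1.0)

    def test_constant_scores_give_auc_half(self):
        rng = np.random.default_rng(6)
        rows = {f"m{i}": {"X": bool(rng.random() < 0.5)} for i in range(100)}
        genera = {k: "OnlyGenus" for k in rows}
        cap = make_capability(rows, genera)  # mouse flag False everywhere
        # no informative column varies: every score identical
        roc = roc_holdout(cap, "X", "mouse", dominant=["OnlyGenus"], seed=0)
        assert roc.auc == pytest.approx(0.5)

    def test_degenerate_split_reseeds_with_warning(self):
        rng = np.random.default_rng(3)
        rows = {f"m{i}": {"X": i == 0} for i in range(50)}  # single producer
        genera = {k: "G" for k in rows}
        cap = make_capability(rows, genera)
        # most splits put the lone producer in train; function must reseed
        with pytest.warns(UserWarning, match="reseeded"):
            for attempt_seed in range(20):
                roc = roc_holdout(cap, "X", "mouse", dominant=["G"], seed=attempt_seed)
                break


class TestBundleIO:
    def test_round_trip_preserves_predictions(self, tmp_path):
        spec = SimSpec(seed=5, n_models_per_genus=20)
        cap, _ = gen_capability_db(spec)
        dom = dominant_taxa(cap, n_min=5)
        models = {m: fit_bayes_logit(build_design(cap, m, "mouse", dom), seed=3)
                  for m in cap.metabolites[:2]}
        p = tmp_path / "models.json"
        save_models(models, p)
        loaded = load_models(p)
        for met, m in models.items():
            assert loaded[met].columns == m.columns
            assert np.allclose(loaded[met].beta, m.beta)
            assert np.allclose(loaded[met].cov, m.cov)
        t = or_table(loaded)
        assert set(t.columns) == set(models)
        assert (t > 0).all().all()
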