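import numpy as np
import pandas as pd
import pytest

import taplearn as tl
from taplearn import curvefit
from taplearn.curvefit import (
    HierarchicalCurveModel,
    McmcConfig,
    ParamState,
    PosteriorDraws,
)
from taplearn.errors import DiagnosticsError, IdentifiabilityError

LOG_2PI = np.log(2 * np.pi)


def _trials(values_by_subject):
    rows = []
    for sid, vals in values_by_subject.items():
        rows += [(sid, "day1", t, v) for t, v in enumerate(vals, start=1)]
    return pd.DataFrame(
        rows, columns=["subject_id", "session", "trial", "correct_sequences"]
    )


def _factors(subject_ids):
    return pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "piano": "non-player",
            "age_group": "younger",
            "intelligence": "control",
            "gender": "female",
            "age_years": 25.0,
            "piano_hours": 0.0,
            "delay": "24h",
        }
    )


def _state(n_subjects, n_groups=1, **kw):
    base = dict(
        I=np.full(n_subjects, 5.0), C=np.full(n_subjects, 10.0),
        R=np.full(n_subjects, 0.5),
        mu_I=np.full(n_groups, 5.0), mu_C=np.full(n_groups, 10.0),
        mu_R=np.full(n_groups, 0.5), sigma_I=np.ones(n_groups),
        sigma_C=np.ones(n_groups), sigma_R=np.full(n_groups, 0.1),
        sigma_obs=np.ones(n_groups),
    )
    for k, v in kw.items():
        base[k] = np.asarray(v, dtype=float)
    return ParamState(**base)


class TestLearningCurve:
    @pytest.mark.parametrize(
        "I, C, R, t, expected",
        [(5, 10, 0.5, 1, 5.0), (5, 10, 0.5, 3, 12.5), (2, 8, 0.9, 1, 2.0)],
    )
    def test_values(self, I, C, R, t, expected):
        assert tl.learning_curve(I, C, R, t) == pytest.approx(expected)

    def test_monotone_approach_to_asymptote(self):
        t = np.arange(1, 200)
        y = tl.learning_curve(2.0, 8.0, 0.9, t)
        assert np.all(np.diff(y) > 0)
        assert y[-1] == pytest.approx(10.0, abs=1e-6)

    def test_invalid_trial_index(self):
        with pytest.raises(ValueError):
            tl.learning_curve(5, 10, 0.5, 0)


class TestLogDensity:
    def test_observations_on_curve_unit_noise(self):
        # each exact observation contributes -log(sqrt(2*pi)) at sd 1
        y = tl.learning_curve(5.0, 10.0, 0.5, np.arange(1, 4))
        model = HierarchicalCurveModel(
            _trials({"S0": y}), _factors(["S0"]), hierarchical=False
        )
        ll = model.log_likelihood(_state(1))
        assert ll == pytest.approx(-0.5 * LOG_2PI * 3)

    def test_support_constraints(self):
        model = HierarchicalCurveModel(
            _trials({"S0": [5, 8, 10]}), _factors(["S0"])
        )
        assert model.log_density(_state(1, R=[1.2])) == -np.inf
        assert model.log_density(_state(1, sigma_obs=[0.0])) == -np.inf
        assert model.log_density(_state(1, sigma_R=[-1.0])) == -np.inf
        assert np.isfinite(model.log_density(_state(1)))

    def test_likelihood_additivity_over_subjects(self):
        ya, yb = [5.0, 8.0, 10.0, 11.0], [3.0, 6.0, 7.0, 7.5]
        both = HierarchicalCurveModel(
            _trials({"A": ya, "B": yb}), _factors(["A", "B"]),
            hierarchical=False,
        )
        single_a = HierarchicalCurveModel(
            _trials({"A": ya}), _factors(["A"]), hierarchical=False
        )
        single_b = HierarchicalCurveModel(
            _trials({"B": yb}), _factors(["B"]), hierarchical=False
        )
        assert both.log_likelihood(_state(2)) == pytest.approx(
            single_a.log_likelihood(_state(1))
            + single_b.log_likelihood(_state(1))
        )

    def test_doubled_data_doubles_data_term(self):
        y = [5.0, 8.0, 10.0, 11.0]
        one = HierarchicalCurveModel(
            _trials({"A": y}), _factors(["A"]), hierarchical=False
        )
        two = HierarchicalCurveModel(
            _trials({"A": y, "A2": y}), _factors(["A", "A2"]),
            hierarchical=False,
        )
        assert two.log_likelihood(_state(2)) == pytest.approx(
            2.0 * one.log_likelihood(_state(1))
        )

    def test_state_dimension_mismatch(self):
        model = HierarchicalCurveModel(
            _trials({"S0": [5, 8, 10]}), _factors(["S0"])
        )
        with pytest.raises(ValueError):
            model.log_density(_state(3))


class TestMcmcFit:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=100, n_burnin=100).validate()
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1).validate()
        with pytest.raises(ValueError):
            McmcConfig(thinning=0).validate()

    def test_too_few_trials(self):
        with pytest.raises(IdentifiabilityError):
            tl.mcmc_fit(_trials({"A": [5, 8], "B": [5, 8]}), _factors(["A", "B"]))

    def test_too_few_subjects_per_group(self):
        with pytest.raises(IdentifiabilityError):
            tl.mcmc_fit(_trials({"A": [5, 8, 10]}), _factors(["A"]))

    def test_determinism(self, one_group_lownoise):
        trials, factors, _ = one_group_lownoise
        cfg = McmcConfig(n_iterations=300, n_burnin=100, seed=5)
        a = tl.mcmc_fit(trials, factors, cfg)
        b = tl.mcmc_fit(trials, factors, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.param_names == b.param_names

    def test_low_noise_subject_recovery(self, one_group_lownoise):
        trials, factors, truth = one_group_lownoise
        cfg = McmcConfig(n_iterations=4000, n_burnin=1000, seed=3)
        draws = tl.mcmc_fit(trials, factors, cfg)
        _, est = tl.summarize(draws)
        for _, row in est.iterrows():
            assert abs(row["I"] - truth[row["subject_id"]].I) < 0.2

    def test_support_invariants(self, one_group_lownoise):
        trials, factors, _ = one_group_lownoise
        cfg = McmcConfig(n_iterations=400, n_burnin=100, seed=5)
        draws = tl.mcmc_fit(trials, factors, cfg)
        for stem in ("R",):
            cols = [i for i, n in enumerate(draws.param_names)
                    if n.startswith(f"{stem}[")]
            vals = draws.draws[:, :, cols]
            assert np.all((vals > 0) & (vals < 1))
        sig_cols = [i for i, n in enumerate(draws.param_names)
                    if n.startswith("sigma")]
        assert np.all(draws.draws[:, :, sig_cols] > 0)

    def test_conjugate_limit_matches_linear_gaussian(self):
        # R fixed and flat priors: the model is an independent linear
        # regression per subject, with closed-form posterior N(bhat, s2*(X'X)^-1)
        rng = np.random.default_rng(8)
        R_true, sigma = 0.55, 1.0
        t = np.arange(1, 13)
        X = np.column_stack([np.ones_like(t, dtype=float),
                             1.0 - R_true ** (t - 1.0)])
        data, exact = {}, {}
        for sid in ("A", "B", "C", "D"):
            beta = np.array([rng.uniform(4, 10), rng.uniform(5, 12)])
            y = X @ beta + rng.normal(0, sigma, size=len(t))
            data[sid] = y
            XtXi = np.linalg.inv(X.T @ X)
            exact[sid] = (XtXi @ X.T @ y, sigma * np.sqrt(np.diag(XtXi)))
        cfg = McmcConfig(
            n_iterations=6000, n_burnin=1000, seed=10,
            hierarchical=False, fixed_r=R_true, fixed_sigma_obs=sigma,
        )
        draws = tl.mcmc_fit(_trials(data), _factors(list(data)), cfg)
        import arviz as az
        for sid, (mean_exact, sd_exact) in exact.items():
            for j, stem in enumerate(("I", "C")):
                x = draws.extract(f"{stem}[{sid}]")
                ess = float(
                    np.asarray(az.ess(az.convert_to_dataset(x[..., None]))["x"])[0]
                )
                se_mean = x.std(ddof=1) / np.sqrt(ess)
                assert abs(x.mean() - mean_exact[j]) < 3 * se_mean
                se_sd = sd_exact[j] / np.sqrt(2 * (ess - 1))
                assert abs(x.std(ddof=1) - sd_exact[j]) < 3 * se_sd


class TestSummarize:
    def _draws(self, arr):
        arr = np.asarray(arr, dtype=float)
        P = arr.shape[2]
        return PosteriorDraws(
            draws=arr, param_names=[f"p{i}" for i in range(P)],
            subject_ids=[], group_names=[], config=McmcConfig(),
        )

    def test_constant_draws(self):
        d = self._draws(np.full((2, 200, 1), 3.5))
        summary, _ = curvefit.summarize(d)
        row = summary.iloc[0]
        assert row["mean"] == 3.5
        assert row["sd"] == 0.0
        assert row["q2.5"] == row["q97.5"] == 3.5
        assert row["rhat"] == pytest.approx(1.0)

    def test_rhat_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        d = self._draws(rng.normal(size=(2, 10_000, 1)))
        summary, _ = curvefit.summarize(d)
        # >= 1 up to the estimator's numerical tolerance
        assert 1.0 - 1e-6 <= summary["rhat"].iloc[0] <= 1.05

    def test_rhat_flags_separated_chains(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(2, 500, 1)) * 0.1
        arr[1] += 100.0
        summary, _ = curvefit.summarize(self._draws(arr))
        # the rank-normalized statistic saturates near 1.83 for two fully
        # separated chains; anything this far above 1.01 flags divergence
        assert summary["rhat"].iloc[0] > 1.5

    def test_interval_contains_mean(self, one_group_lownoise):
        trials, factors, _ = one_group_lownoise
        cfg = McmcConfig(n_iterations=600, n_burnin=200, seed=5)
        summary, _ = tl.summarize(tl.mcmc_fit(trials, factors, cfg))
        assert (summary["q2.5"] <= summary["mean"]).all()
        assert (summary["mean"] <= summary["q97.5"]).all()
        # rank-normalized R-hat is >= 1 up to estimator noise
        assert (summary["rhat"] >= 0.99).all()

    def test_too_few_draws(self):
        with pytest.raises(DiagnosticsError):
            curvefit.summarize(self._draws(np.zeros((2, 50, 1))))
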