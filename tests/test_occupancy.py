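import logging

import arviz as az
import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit, logit

import occudyn as od
from occudyn import MCMCConfig
from occudyn.data_model import DetectionHistory, ValidationError
from occudyn.occupancy import ModelSpec, _MarginalEngine

from oracles import brute_force_loglik, random_toy


def toy_stations(x_cov):
    n = len(x_cov)
    df = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "x": np.arange(n, dtype=float), "y": 0.0, "habitat": "forest",
            "elevation": np.asarray(x_cov).ravel(), "slope": 0.0,
            "dist_coast": 0.0, "dist_any_water": 0.0, "dist_freshwater": 0.0,
            "ground_cover": 0.0,
        }
    )
    return od.StationTable(df)


def toy_history(y):
    n, t, _ = y.shape
    effort = (~np.isnan(y)).any(axis=2).astype(float) * 5
    return DetectionHistory(
        y=y, effort=effort, site_ids=[f"s{i}" for i in range(n)],
        season_labels=[f"t{j}" for j in range(t)],
    )


class TestNeighborGraph:
    def test_mutual_within_radius(self, two_station_table):
        g = od.build_neighbor_graph(two_station_table, 1000)
        assert g.neighbors[0].tolist() == [1] and g.neighbors[1].tolist() == [0]

    def test_isolated_below_radius(self, two_station_table):
        g = od.build_neighbor_graph(two_station_table, 100)
        assert g.counts.tolist() == [0, 0]

    def test_collinear_chain(self):
        df = toy_stations(np.zeros(3)).df.copy()
        df["x"] = [0.0, 800.0, 1600.0]
        g = od.build_neighbor_graph(od.StationTable(df), 1000)
        assert g.counts.tolist() == [1, 2, 1]


class TestAutoCovariate:
    def test_neighbor_mean(self):
        g = od.NeighborGraph(neighbors=[np.array([1, 2, 3]), np.array([0]),
                                        np.array([0]), np.array([0])])
        d = od.auto_covariate(np.array([0, 1, 0, 1]), g)
        assert d[0] == pytest.approx(2 / 3)

    def test_all_zero_neighbors(self):
        g = od.NeighborGraph(neighbors=[np.array([1]), np.array([0])])
        assert od.auto_covariate(np.array([0, 0]), g).tolist() == [0, 0]

    def test_isolated_site_warns(self, caplog):
        g = od.NeighborGraph(neighbors=[np.array([], int)])
        with caplog.at_level(logging.WARNING):
            d = od.auto_covariate(np.array([1]), g)
        assert d[0] == 0.0
        assert "isolated" in caplog.text


class TestDynamicLoglik:
    def test_single_site_single_survey_detection(self):
        # one site, one season, one survey with a detection: L = psi * p
        st = toy_stations([0.0])
        y = np.ones((1, 1, 1))
        spec = ModelSpec()
        psi, p = 0.37, 0.62
        ll = od.dynamic_loglik(
            {"psi1": [logit(psi)], "p": [logit(p)]}, spec, toy_history(y), st
        )
        assert ll == pytest.approx(np.log(psi * p), abs=1e-12)

    def test_single_site_all_zero_history(self):
        # y = (0,0): L = psi (1-p)^2 + (1-psi)
        st = toy_stations([0.0])
        y = np.zeros((1, 1, 2))
        psi, p = 0.37, 0.62
        ll = od.dynamic_loglik(
            {"psi1": [logit(psi)], "p": [logit(p)]}, ModelSpec(), toy_history(y), st
        )
        assert ll == pytest.approx(np.log(psi * (1 - p) ** 2 + (1 - psi)), abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2024)
        spec = ModelSpec(psi1=("elevation",), p=("elevation",))
        for _ in range(25):
            n, n_seasons, x_cov, theta, y, mats = random_toy(rng)
            st = toy_stations(x_cov)
            ll = od.dynamic_loglik(theta, spec, toy_history(y), st)
            assert ll == pytest.approx(brute_force_loglik(theta, *mats, y), abs=1e-10)

    def test_flat_vector_equals_dict(self):
        rng = np.random.default_rng(5)
        _, _, x_cov, theta, y, _ = random_toy(rng, max_seasons=3)
        while y.shape[1] == 1:
            _, _, x_cov, theta, y, _ = random_toy(rng, max_seasons=3)
        st = toy_stations(x_cov)
        spec = ModelSpec(psi1=("elevation",), p=("elevation",))
        flat = np.concatenate([theta["psi1"], theta["gamma"], theta["eps"], theta["p"]])
        h = toy_history(y)
        assert od.dynamic_loglik(flat, spec, h, st) == od.dynamic_loglik(theta, spec, h, st)

    def test_nonfinite_params_rejected(self):
        st = toy_stations([0.0])
        with pytest.raises(ValueError):
            od.dynamic_loglik(
                np.array([np.nan, 0, 0, 0]), ModelSpec(),
                toy_history(np.zeros((1, 2, 4))), st,
            )

    def test_frozen_dynamics_factorize_into_seasons(self):
        # gamma -> 0, eps -> 0: the chain likelihood equals a shared-z product
        rng = np.random.default_rng(8)
        n, n_seasons = 3, 3
        y = rng.integers(0, 2, (n, n_seasons, 4)).astype(float)
        st = toy_stations(np.zeros(n))
        psi, p = 0.55, 0.4
        ll = od.dynamic_loglik(
            {"psi1": [logit(psi)], "gamma": [-40.0], "eps": [-40.0], "p": [logit(p)]},
            ModelSpec(), toy_history(y), st,
        )
        s1 = y.sum(axis=2)
        s0 = (1 - y).sum(axis=2)
        expected = 0.0
        for i in range(n):
            occ = psi * np.prod(p ** s1[i] * (1 - p) ** s0[i])
            unocc = (1 - psi) * float((s1[i] == 0).all())
            expected += np.log(occ + unocc)
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_auto_spec_refused(self):
        st = toy_stations([0.0])
        spec = ModelSpec(gamma_auto=True)
        with pytest.raises(ValidationError, match="auto"):
            od.dynamic_loglik(np.zeros(5), spec, toy_history(np.zeros((1, 2, 4))), st)


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        c = rng.normal(0, 1, 4000)
        chains = np.stack([c, c, c])
        assert od.gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_stationary_chains_converged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(0, 1, (3, 5000))
        assert od.gelman_rubin(chains) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(0, 1, (2, 2000))
        chains[1] += 10
        assert od.gelman_rubin(chains) > 2.0

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            od.gelman_rubin(np.zeros((1, 100)))

    def test_agrees_with_arviz_split_rhat(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(0, 1, (3, 1000)).cumsum(axis=1) * 0.01 + rng.normal(
            0, 1, (3, 1000)
        )
        ours = od.gelman_rubin(chains)
        theirs = float(az.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, rel=1e-9)


class TestFitting:
    def test_posterior_mode_near_ml_on_toy(self, intercept_history):
        X, y, _ = intercept_history
        spec = ModelSpec()
        m = od.DynamicOccupancyModel(spec=spec, mcmc=MCMCConfig(seed=1)).fit(X, y)
        st = m.stations_
        eng = _MarginalEngine(spec, m.history_, st)
        res = optimize.minimize(
            lambda v: -eng.loglik(v), np.zeros(eng.layout.dim), method="Nelder-Mead"
        )
        assert np.allclose(m.posterior_mean_, res.x, atol=0.15)

    def test_missing_site_z_posterior_equals_prior_predictive(self):
        # a site with no surveys: its occupancy posterior is psi itself
        rng = np.random.default_rng(4)
        n = 120
        z = rng.random(n) < 0.55
        y = (rng.random((n, 1, 4)) < z[:, None, None] * 0.5).astype(float)
        y[0] = np.nan
        X = pd.DataFrame({"id": [f"s{i}" for i in range(n)]})
        m = od.SingleSeasonOccupancyModel(spec=ModelSpec(), mcmc=MCMCConfig(seed=2)).fit(X, y)
        psi_draws = expit(m.draws_.reshape(-1, 2)[:, 0])
        assert m.z_draws_[:, 0, 0].mean() == pytest.approx(psi_draws.mean(), abs=0.04)

    def test_perfect_detection_pao_equals_naive(self):
        rng = np.random.default_rng(6)
        n = 60
        z = (rng.random(n) < 0.5).astype(float)
        y = np.repeat(z[:, None, None], 4, axis=2)
        X = pd.DataFrame({"id": [f"s{i}" for i in range(n)]})
        m = od.SingleSeasonOccupancyModel(
            spec=ModelSpec(), mcmc=MCMCConfig(seed=3, n_burn=300, n_keep=500)
        ).fit(X, y)
        assert np.allclose(m.pao_draws_, z.mean())

    def test_all_zero_histories_pull_psi_down(self):
        y = np.zeros((40, 1, 4))
        X = pd.DataFrame({"id": [f"s{i}" for i in range(40)]})
        m = od.SingleSeasonOccupancyModel(
            spec=ModelSpec(), mcmc=MCMCConfig(seed=4, n_burn=300, n_keep=500, prior_sd=1.5)
        ).fit(X, y)
        psi_draws = expit(m.draws_.reshape(-1, 2)[:, 0])
        assert psi_draws.mean() < 0.5  # below the symmetric prior mean

    def test_transition_probabilities_conserved(self, intercept_history):
        X, y, _ = intercept_history
        m = od.DynamicOccupancyModel(
            spec=ModelSpec(), mcmc=MCMCConfig(seed=5, n_burn=200, n_keep=300)
        ).fit(X, y)
        flat = m.draws_.reshape(-1, 4)
        gamma, eps = expit(flat[:, 1]), expit(flat[:, 2])
        rows = np.stack([1 - gamma + gamma, eps + 1 - eps])
        assert np.allclose(rows, 1.0)
        assert np.all((m.pao_draws_ >= 0) & (m.pao_draws_ <= 1))

    def test_collinear_spec_refused(self, std_landscape93):
        std, _ = std_landscape93
        flagged = od.collinearity_screen(std, ["elevation", "dist_coast"])
        assert flagged  # the generator builds this collinearity in
        spec = ModelSpec(psi1=("elevation", "dist_coast"))
        with pytest.raises(ValidationError, match="collinear"):
            od.DynamicOccupancyModel(spec=spec, flagged_pairs=flagged).fit(
                std, np.zeros((93, 2, 4))
            )

    def test_single_season_rejects_multi(self, two_station_table):
        with pytest.raises(ValidationError, match="single-season"):
            od.SingleSeasonOccupancyModel(spec=ModelSpec()).fit(
                two_station_table, np.zeros((2, 2, 4))
            )


class TestResponseCurve:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(9)
        n = 150
        x = rng.normal(0, 1, n)
        psi = expit(0.3 - 1.1 * x)
        z = rng.random(n) < psi
        y = (rng.random((n, 1, 4)) < z[:, None, None] * 0.6).astype(float)
        X = pd.DataFrame({"id": [f"s{i}" for i in range(n)], "dist_freshwater": x})
        spec = ModelSpec(psi1=("dist_freshwater",))
        return od.SingleSeasonOccupancyModel(spec=spec, mcmc=MCMCConfig(seed=7)).fit(X, y)

    def test_monotone_negative_slope(self, fitted):
        curve = fitted.response_curve("psi1", "dist_freshwater")
        assert (np.diff(curve["mean"]) < 0).all()

    def test_zero_slope_gives_flat_curve(self):
        m = od.SingleSeasonOccupancyModel.__new__(od.SingleSeasonOccupancyModel)
        m.spec_ = ModelSpec(psi1=("elevation",))
        m.history_ = od.DetectionHistory(
            y=np.zeros((2, 1, 1)), effort=np.ones((2, 1)),
            site_ids=["a", "b"], season_labels=["s"],
        )
        m.draws_ = np.array([[[0.4, 0.0]]])
        curve = m.response_curve("psi1", "elevation")
        assert np.allclose(curve["mean"], expit(0.4))

    def test_absent_covariate_errors(self, fitted):
        with pytest.raises(ValidationError):
            fitted.response_curve("psi1", "slope")

    def test_quadratic_vertex(self, two_station_table):
        # deterministic check on the curve arithmetic: U-shape minimum at -b/(2c)
        m = od.SingleSeasonOccupancyModel.__new__(od.SingleSeasonOccupancyModel)
        m.spec_ = ModelSpec(psi1=("elevation", "elevation^2"))
        m.history_ = od.DetectionHistory(
            y=np.zeros((2, 1, 1)), effort=np.ones((2, 1)),
            site_ids=["a", "b"], season_labels=["s"],
        )
        b, c = -0.8, 0.6
        m.draws_ = np.array([[[0.1, b, c]]])
        curve = m.response_curve("psi1", "elevation", grid=np.linspace(-2.5, 2.5, 201))
        vertex = curve["elevation"][curve["mean"].idxmin()]
        assert vertex == pytest.approx(-b / (2 * c), abs=0.05)

    def test_back_transform_to_raw_scale(self, fitted):
        scaling = od.CovariateScaling(mean={"dist_freshwater": 200.0},
                                      sd={"dist_freshwater": 100.0})
        curve = fitted.response_curve(
            "psi1", "dist_freshwater", grid=np.array([100.0, 200.0, 300.0]),
            scaling=scaling,
        )
        assert curve["dist_freshwater"].tolist() == [100.0, 200.0, 300.0]
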