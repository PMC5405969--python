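"""Generative agents: choice-rule equivalence, population sampling, studies."""

import numpy as np
import pytest

from horizontask.agents import (
    AgentParams,
    PopulationParams,
    default_population,
    gamma_from_mean_sd,
    sample_population,
    simulate_first_free_choice,
    simulate_game,
    simulate_study,
)
from horizontask.choice_model import ParameterError, choice_probability
from horizontask.task_design import EQUAL, UNEQUAL, GameSpec, SessionConfig

UNEQUAL_GAME = GameSpec(0, 6, UNEQUAL, 40, 60, ("L", "R", "R", "R"), "L")
EQUAL_GAME = GameSpec(1, 6, EQUAL, 60, 40, ("L", "R", "L", "R"), None)

ALL_CELLS = [(h, i) for h in (1, 6, 11) for i in (EQUAL, UNEQUAL)]


def make_params(A=0.0, B=0.0, sigma=5.0):
    return AgentParams(
        A={h: A for h in (1, 6, 11)},
        B={c: B for c in ALL_CELLS},
        sigma={c: sigma for c in ALL_CELLS},
    )


class TestFirstFreeChoice:
    def test_noiseless_limit_picks_higher_mean(self, rng):
        params = make_params(sigma=1e-9)
        history = {"L": [60, 70], "R": [50, 55]}
        assert all(
            simulate_first_free_choice(history, EQUAL_GAME, params, rng) == "L"
            for _ in range(20)
        )

    def test_dominant_information_bonus(self, rng):
        params = make_params(A=1e6, sigma=5.0)
        history = {"L": [10], "R": [90, 95, 99]}  # informative side pays far less
        assert all(
            simulate_first_free_choice(history, UNEQUAL_GAME, params, rng) == "L"
            for _ in range(20)
        )

    def test_nonpositive_noise_rejected(self, rng):
        with pytest.raises(ParameterError):
            make_params(sigma=0.0)

    @pytest.mark.parametrize(
        "history,game,A,B,sigma",
        [
            ({"L": [60, 60], "R": [50, 50]}, EQUAL_GAME, 0.0, 0.0, 10.0),
            ({"L": [55], "R": [50, 60, 58]}, UNEQUAL_GAME, 4.0, 1.0, 8.0),
            ({"L": [40, 45], "R": [60, 50]}, EQUAL_GAME, 0.0, -3.0, 15.0),
        ],
    )
    def test_simulation_matches_logistic_probability(self, history, game, A, B, sigma):
        # Monte-Carlo frequency vs the closed-form Bernoulli probability
        rng = np.random.default_rng(2024)
        params = make_params(A=A, B=B, sigma=sigma)
        n = 20_000
        hits = sum(
            simulate_first_free_choice(history, game, params, rng) == "L"
            for _ in range(n)
        )
        from horizontask.choice_model import encode_game

        obs = encode_game(game, history)
        p_ref = choice_probability(
            obs.dR, obs.dI, obs.dl, A if game.info_condition == UNEQUAL else 0.0,
            B, sigma,
        )
        p_left = p_ref if obs.reference == "L" else 1 - p_ref
        se = np.sqrt(p_left * (1 - p_left) / n)
        assert abs(hits / n - p_left) < 3 * se + 1e-9


class TestPopulationSampling:
    def test_gamma_parameterization(self):
        k, scale = gamma_from_mean_sd(8.0, 4.0)
        assert k * scale == pytest.approx(8.0)
        assert np.sqrt(k) * scale == pytest.approx(4.0)

    def test_degenerate_population_is_identical_subjects(self, rng):
        pop = PopulationParams(
            mu_A={6: 5.0}, sd_A={6: 0.0},
            mu_B={(6, UNEQUAL): 1.0}, sd_B={(6, UNEQUAL): 0.0},
            k_sigma={(6, UNEQUAL): 1e9}, scale_sigma={(6, UNEQUAL): 5e-9},
        )
        agents = sample_population(pop, 5, rng)
        assert all(a.A[6] == 5.0 and a.B[(6, UNEQUAL)] == 1.0 for a in agents)
        sigmas = [a.sigma[(6, UNEQUAL)] for a in agents]
        assert np.allclose(sigmas, 5.0, rtol=1e-3)

    def test_sample_moments_match_population(self, rng):
        pop = PopulationParams(
            mu_A={6: 5.0}, sd_A={6: 2.0},
            mu_B={(6, UNEQUAL): 0.0}, sd_B={(6, UNEQUAL): 1.0},
            k_sigma={(6, UNEQUAL): 4.0}, scale_sigma={(6, UNEQUAL): 2.0},
        )
        agents = sample_population(pop, 10_000, rng)
        A = np.array([a.A[6] for a in agents])
        sig = np.array([a.sigma[(6, UNEQUAL)] for a in agents])
        assert abs(A.mean() - 5.0) < 3 * 2.0 / np.sqrt(len(A))
        # Gamma(shape 4, scale 2): mean 8, SD 4
        assert abs(sig.mean() - 8.0) < 3 * 4.0 / np.sqrt(len(sig))
        assert sig.min() > 0


class TestSimulateGame:
    def test_horizon_determines_trial_count(self, rng):
        cfg = SessionConfig()
        params = make_params()
        for horizon, n_trials in ((1, 5), (6, 10), (11, 15)):
            game = GameSpec(0, horizon, EQUAL, 40, 60, ("L", "R", "L", "R"), None)
            rows = simulate_game(game, params, cfg, rng)
            assert len(rows) == n_trials
            assert [r["forced"] for r in rows] == [1] * 4 + [0] * horizon

    def test_greedy_agent_tracks_empirical_best(self, rng):
        cfg = SessionConfig(reward_sd=0.0)  # rewards equal the true means
        params = make_params(sigma=1e-9)
        game = GameSpec(0, 11, EQUAL, 60, 40, ("L", "R", "L", "R"), None)
        rows = simulate_game(game, params, cfg, rng)
        assert all(r["choice"] == "L" for r in rows if not r["forced"])


class TestSimulateStudy:
    def test_crossover_arithmetic(self, small_study, small_config):
        trials, games = small_study.trials, small_study.games
        assert len(games) == 2 * 2 * small_config.n_games
        per_game = trials.groupby(["subject_id", "treatment", "game_id"]).size()
        horizons = games.set_index(["subject_id", "treatment", "game_id"])["horizon"]
        assert (per_game == horizons.reindex(per_game.index) + 4).all()

    def test_every_invariant_on_smoke_dataset(self, small_study):
        trials = small_study.trials
        assert trials["reward"].between(1, 100).all()
        assert ((trials["trial_index"] < 4) == (trials["forced"] == 1)).all()
        assert set(trials["choice"]) <= {"L", "R"}
        assert (trials["rt_ms"] > 0).all()

    def test_noisier_horizon_means_more_exploration(self):
        # sigma much larger in horizon-6 cells than horizon-1 cells makes the
        # first free choice pick the lower observed option more often
        from horizontask.analysis import exploration_rate

        pop = {
            "placebo": PopulationParams(
                mu_A={h: 0.0 for h in (1, 6, 11)},
                sd_A={h: 0.0 for h in (1, 6, 11)},
                mu_B={c: 0.0 for c in ALL_CELLS},
                sd_B={c: 0.0 for c in ALL_CELLS},
                k_sigma={(h, i): 400.0 if h > 1 else 1.0 for h, i in ALL_CELLS},
                scale_sigma={(h, i): 0.05 if h > 1 else 1.0 for h, i in ALL_CELLS},
            )
        }
        ds = simulate_study(pop_by_treatment=pop, n_subjects=4, seed=11)
        rates = (
            exploration_rate(ds.observations())
            .groupby("horizon")["proportion"]
            .mean()
        )
        assert rates[6] > rates[1]
        assert rates[11] > rates[1]

    def test_default_population_encodes_study_conditions(self):
        for treatment in ("placebo", "drug"):
            pop = default_population(treatment)
            for info in (EQUAL, UNEQUAL):
                assert pop.sigma_mean((6, info)) > pop.sigma_mean((1, info))
                assert pop.sigma_mean((11, info)) > pop.sigma_mean((1, info))
            assert pop.mu_A[6] > pop.mu_A[1] and pop.mu_A[11] > pop.mu_A[1]
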