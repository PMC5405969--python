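"""Generative agents: simulate Horizon Task choices from known parameters.

Subjects are simulated from the same model later used for inference: on the
first free choice of each game the agent chooses by a Bernoulli draw from the
logistic choice probability (information bonus A, spatial bias B, decision
noise sigma). Subject-level parameters are drawn from population
distributions — Gaussian for A and B, Gamma for sigma — so a simulated study
has the same two-level structure the hierarchical fit assumes.

Only the first free choice carries the experimental signal; later free
choices are filled in with the same rule applied to the running observed
means, purely so that simulated sessions are structurally complete and task
performance is computable.

Default population parameters emulate the published study conditions: a
within-subject crossover of 22 subjects x 2 treatment sessions x 120 games,
decision noise increasing from horizon 1 to horizons 6/11 (more so under
placebo), larger noise under unequal information, and an information bonus
that grows with horizon identically in both treatments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import choice_model
from .choice_model import ParameterError, choice_probability, encode_game
from .task_design import (
    EQUAL,
    UNEQUAL,
    GameSpec,
    SessionConfig,
    draw_reward,
    generate_session,
)

Cell = tuple[int, str]  # (horizon, info_condition)


@dataclass(frozen=True)
class AgentParams:
    """One subject's generative parameters in one treatment session.

    ``A`` is keyed by horizon (it only acts in unequal-information games,
    where the information difference is nonzero); ``B`` and ``sigma`` are
    keyed by (horizon, info_condition).
    """

    A: Mapping[int, float]
    B: Mapping[Cell, float]
    sigma: Mapping[Cell, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma.values()):
            raise ParameterError("decision noise sigma must be > 0 in every cell")

    def for_game(self, game: GameSpec) -> tuple[float, float, float]:
        cell = (game.horizon, game.info_condition)
        A = self.A[game.horizon] if game.info_condition == UNEQUAL else 0.0
        return A, self.B[cell], self.sigma[cell]


@dataclass(frozen=True)
class PopulationParams:
    """Population distributions the subject parameters are drawn from.

    A ~ Gaussian(mu_A, sd_A) per horizon; B ~ Gaussian(mu_B, sd_B) and
    sigma ~ Gamma(shape k_sigma, scale scale_sigma) per (horizon, info).
    """

    mu_A: Mapping[int, float]
    sd_A: Mapping[int, float]
    mu_B: Mapping[Cell, float]
    sd_B: Mapping[Cell, float]
    k_sigma: Mapping[Cell, float]
    scale_sigma: Mapping[Cell, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sd_A.values()) or any(
            v < 0 for v in self.sd_B.values()
        ):
            raise ParameterError("population SDs must be non-negative")
        if any(v <= 0 for v in self.k_sigma.values()) or any(
            v <= 0 for v in self.scale_sigma.values()
        ):
            raise ParameterError("Gamma shape and scale must be > 0")

    def sigma_mean(self, cell: Cell) -> float:
        return self.k_sigma[cell] * self.scale_sigma[cell]

    def sigma_sd(self, cell: Cell) -> float:
        return float(np.sqrt(self.k_sigma[cell])) * self.scale_sigma[cell]


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of the Gamma distribution with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ParameterError("Gamma mean and SD must be > 0")
    return (mean / sd) ** 2, sd**2 / mean


# Group-level decision-noise estimates (mean, SD of the population Gamma) the
# generator emulates, per treatment and (horizon, info_condition) cell.
_NOISE_TABLE: dict[str, dict[Cell, tuple[float, float]]] = {
    "placebo": {
        (1, EQUAL): (4.162, 2.129),
        (6, EQUAL): (6.369, 1.652),
        (11, EQUAL): (9.562, 0.502),
        (1, UNEQUAL): (5.217, 2.037),
        (6, UNEQUAL): (9.790, 2.750),
        (11, UNEQUAL): (9.665, 1.510),
    },
    "drug": {
        (1, EQUAL): (4.388, 0.591),
        (6, EQUAL): (7.180, 0.492),
        (11, EQUAL): (7.121, 0.934),
        (1, UNEQUAL): (6.214, 0.843),
        (6, UNEQUAL): (7.601, 1.336),
        (11, UNEQUAL): (8.702, 7.042),
    },
}

# Information bonus grows with horizon (directed exploration); treatment does
# not move it. Values in points.
_BONUS_MEANS = {1: 1.0, 6: 5.0, 11: 6.0}
_BONUS_SD = 2.0
# Small left/right response tendency.
_BIAS_MEAN, _BIAS_SD = 0.5, 1.5

TREATMENTS = ("placebo", "drug")


def default_population(treatment: str = "placebo") -> PopulationParams:
    """Study-condition population parameters for one treatment arm."""
    if treatment not in _NOISE_TABLE:
        raise ParameterError(f"unknown treatment {treatment!r}")
    noise = _NOISE_TABLE[treatment]
    cells = list(noise)
    k, scale = {}, {}
    for cell, (mean, sd) in noise.items():
        k[cell], scale[cell] = gamma_from_mean_sd(mean, sd)
    return PopulationParams(
        mu_A={h: _BONUS_MEANS[h] for h in (1, 6, 11)},
        sd_A={h: _BONUS_SD for h in (1, 6, 11)},
        mu_B={c: _BIAS_MEAN for c in cells},
        sd_B={c: _BIAS_SD for c in cells},
        k_sigma=k,
        scale_sigma=scale,
    )


def sample_population(
    pop: PopulationParams, n_subjects: int, rng: np.random.Generator
) -> list[AgentParams]:
    """Draw i.i.d. subject parameters from the population distributions."""
    agents = []
    for _ in range(n_subjects):
        A = {h: float(rng.normal(pop.mu_A[h], pop.sd_A[h])) for h in pop.mu_A}
        B = {c: float(rng.normal(pop.mu_B[c], pop.sd_B[c])) for c in pop.mu_B}
        sigma = {}
        for c in pop.k_sigma:
            draw = 0.0
            while draw <= 0.0:  # Gamma support is (0, inf); guard underflow to 0
                draw = float(rng.gamma(pop.k_sigma[c], pop.scale_sigma[c]))
            sigma[c] = draw
        agents.append(AgentParams(A=A, B=B, sigma=sigma))
    return agents


def simulate_first_free_choice(
    obs_history: dict[str, Sequence[float]],
    game: GameSpec,
    params: AgentParams,
    rng: np.random.Generator,
) -> str:
    """Simulate the first free choice after the four forced trials."""
    obs = encode_game(game, obs_history)
    A, B, sigma = params.for_game(game)
    p_ref = choice_probability(obs.dR, obs.dI, obs.dl, A, B, sigma)
    ref = obs.reference
    other = "R" if ref == "L" else "L"
    return ref if rng.random() < p_ref else other


def _post_choice(
    rewards: dict[str, list[float]],
    game: GameSpec,
    params: AgentParams,
    rng: np.random.Generator,
) -> str:
    """One post-first free choice from running observed means (plumbing)."""
    A, B, sigma = params.for_game(game)
    dR = float(np.mean(rewards["L"]) - np.mean(rewards["R"]))
    nL, nR = len(rewards["L"]), len(rewards["R"])
    dI = int(np.sign(nR - nL))  # less-sampled option is the more informative
    p_left = choice_probability(dR, dI, 1, A, B, sigma)
    return "L" if rng.random() < p_left else "R"


def simulate_game(
    game: GameSpec,
    params: AgentParams,
    config: SessionConfig,
    rng: np.random.Generator,
    rt_median_ms: float = 1065.0,
    rt_sdlog: float = 0.35,
) -> list[dict]:
    """Simulate all 4 + horizon trials of one game; returns trial dicts."""
    rows: list[dict] = []
    rewards: dict[str, list[float]] = {"L": [], "R": []}

    def play(choice: str, t: int, forced: bool) -> None:
        reward = draw_reward(game.mean(choice), config, rng)
        rewards[choice].append(reward)
        rt = float(rng.lognormal(np.log(rt_median_ms), rt_sdlog))
        rows.append(
            {
                "game_id": game.game_id,
                "horizon": game.horizon,
                "info_condition": game.info_condition,
                "trial_index": t,
                "forced": int(forced),
                "choice": choice,
                "reward": reward,
                "rt_ms": rt,
            }
        )

    for t, side in enumerate(game.forced_sequence):
        play(side, t, True)
    play(simulate_first_free_choice(rewards, game, params, rng), 4, False)
    for t in range(5, game.n_trials):
        play(_post_choice(rewards, game, params, rng), t, False)
    return rows


@dataclass
class BehavioralDataset:
    """A simulated study: trial table, game designs, and the generative truth."""

    trials: pd.DataFrame
    games: pd.DataFrame
    agent_params: dict[tuple[int, str], AgentParams]  # (subject_id, treatment)
    population: dict[str, PopulationParams]  # per treatment

    def observations(self) -> pd.DataFrame:
        """Encode every game's first free choice for model fitting."""
        return choice_model.encode_dataset(self.trials, self.games)


def simulate_study(
    config: SessionConfig | None = None,
    pop_by_treatment: Mapping[str, PopulationParams] | None = None,
    n_subjects: int = 22,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BehavioralDataset:
    """Simulate a full crossover study.

    Every subject completes one session per treatment (session order
    alternates across subjects); each session is a freshly generated game
    set. Subject parameters are drawn independently per treatment arm from
    that arm's population distributions.
    """
    config = config or SessionConfig()
    if pop_by_treatment is None:
        pop_by_treatment = {t: default_population(t) for t in TREATMENTS}
    rng = rng if rng is not None else np.random.default_rng(seed)

    agents_by_treatment = {
        t: sample_population(pop, n_subjects, rng) for t, pop in pop_by_treatment.items()
    }

    trial_rows: list[dict] = []
    game_rows: list[dict] = []
    agent_params: dict[tuple[int, str], AgentParams] = {}
    treatments = list(pop_by_treatment)
    for subject in range(n_subjects):
        order = treatments if subject % 2 == 0 else treatments[::-1]
        for session_id, treatment in enumerate(order):
            params = agents_by_treatment[treatment][subject]
            agent_params[(subject, treatment)] = params
            session_seed = int(rng.integers(0, 2**31 - 1))
            games = generate_session(config, rng_seed=session_seed)
            for game in games:
                for row in simulate_game(game, params, config, rng):
                    row.update(
                        subject_id=subject, session_id=session_id, treatment=treatment
                    )
                    trial_rows.append(row)
                game_rows.append(
                    {
                        "subject_id": subject,
                        "treatment": treatment,
                        "session_id": session_id,
                        "game_id": game.game_id,
                        "horizon": game.horizon,
                        "info_condition": game.info_condition,
                        "mean_left": game.mean_left,
                        "mean_right": game.mean_right,
                        "more_informative_side": game.more_informative_side,
                    }
                )

    from .task_design import TRIAL_COLUMNS

    trials = pd.DataFrame(trial_rows)[TRIAL_COLUMNS]
    games_df = pd.DataFrame(game_rows)
    return BehavioralDataset(
        trials=trials,
        games=games_df,
        agent_params=agent_params,
        population=dict(pop_by_treatment),
    )
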