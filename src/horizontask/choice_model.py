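"""Logistic choice model for the first free choice of a Horizon Task game.

Each option i is valued as ``Q^i = R^i + A I^i + B l^i + sigma n^i`` where
``R^i`` is the mean payoff observed for that option during the forced trials,
``I^i`` codes which option is more informative, ``l^i`` codes screen side and
``n^i`` is logistic noise. Choosing the larger ``Q`` is then equivalent to a
Bernoulli draw with

    p = 1 / (1 + exp(-(dR + A*dI + B*dl) / sigma))

for a designated reference option, where ``dR`` is the difference in mean
observed reward (reference minus other), ``dI`` is +1 if the reference option
is the more informative one (0 in the equal-information condition) and ``dl``
is +1 if the reference option is on the left.

The free parameters are the information bonus ``A`` (points awarded to the
less-sampled option), the spatial bias ``B`` (points awarded to one screen
side) and the decision noise ``sigma`` (points; the inverse slope of the
choice curve).

Reference-option convention: in unequal-information games probabilities are
expressed for the more-informative option (so ``dI = +1`` always); in
equal-information games, for the left option (so ``dl = +1`` and ``dI = 0``).
The model's label symmetry makes this convention immaterial to fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .task_design import UNEQUAL, GameSpec, DataError

#: columns of the encoded first-free-choice table
OBSERVATION_COLUMNS = [
    "subject_id",
    "treatment",
    "game_id",
    "horizon",
    "info_condition",
    "dR",
    "dI",
    "dl",
    "chose_reference",
]


class ParameterError(ValueError):
    """Raised for invalid model parameters (e.g. non-positive noise)."""


@dataclass(frozen=True)
class FirstFreeObservation:
    """Regression-ready encoding of one game's first free choice."""

    dR: float
    dI: int
    dl: int
    chosen: str  # side actually chosen, L/R
    reference: str  # side whose choice probability the model expresses
    horizon: int
    info_condition: str
    treatment: str | None = None

    @property
    def chose_reference(self) -> bool:
        return self.chosen == self.reference


def reference_side(game: GameSpec) -> str:
    """The option whose choice probability is modelled (see module docstring)."""
    if game.info_condition == UNEQUAL:
        return game.more_informative_side  # type: ignore[return-value]
    return "L"


def encode_game(
    game: GameSpec,
    forced_rewards: dict[str, Sequence[float]],
    chosen: str | None = None,
    treatment: str | None = None,
) -> FirstFreeObservation:
    """Encode a game's forced-trial outcomes as (dR, dI, dl).

    ``forced_rewards`` maps side -> rewards observed on the forced trials,
    exactly four outcomes in total. ``dR`` is the difference of unweighted
    arithmetic means (reference option minus the other).
    """
    n_obs = sum(len(v) for v in forced_rewards.values())
    if n_obs != 4:
        raise DataError(f"expected 4 forced outcomes, got {n_obs}")
    ref = reference_side(game)
    other = "R" if ref == "L" else "L"
    expected = {s: game.forced_sequence.count(s) for s in ("L", "R")}
    observed = {s: len(forced_rewards.get(s, ())) for s in ("L", "R")}
    if expected != observed:
        raise DataError(
            f"forced outcomes per side {observed} do not match the game's "
            f"forced sequence {expected}"
        )
    dR = float(np.mean(forced_rewards[ref]) - np.mean(forced_rewards[other]))
    dI = 1 if game.info_condition == UNEQUAL else 0
    dl = 1 if ref == "L" else -1
    return FirstFreeObservation(
        dR=dR,
        dI=dI,
        dl=dl,
        chosen=chosen if chosen is not None else ref,
        reference=ref,
        horizon=game.horizon,
        info_condition=game.info_condition,
        treatment=treatment,
    )


def decision_value(dR, dI, dl, A, B):
    """The deterministic part of the value difference, dR + A*dI + B*dl."""
    return np.asarray(dR, dtype=float) + A * np.asarray(dI) + B * np.asarray(dl)


def choice_probability(dR, dI, dl, A, B, sigma):
    """Probability that the reference option is chosen.

    Vectorized over all arguments; ``sigma`` must be strictly positive.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ParameterError("decision noise sigma must be > 0")
    return expit(decision_value(dR, dI, dl, A, B) / sigma)


def log_likelihood(
    observations: pd.DataFrame,
    params: dict[tuple, tuple[float, float, float]],
) -> float:
    """Bernoulli log likelihood of encoded first free choices.

    ``observations`` is a table with OBSERVATION_COLUMNS; ``params`` maps a
    condition key ``(treatment, horizon, info_condition)`` to ``(A, B, sigma)``.
    Evaluated in the log domain so extreme probabilities do not underflow.
    """
    total = 0.0
    keys = observations[["treatment", "horizon", "info_condition"]].apply(tuple, axis=1)
    for key, group in observations.groupby(keys, sort=False):
        A, B, sigma = params[key]
        if sigma <= 0:
            raise ParameterError(f"sigma must be > 0 in condition {key}")
        z = decision_value(
            group["dR"].to_numpy(), group["dI"].to_numpy(), group["dl"].to_numpy(),
            A, B,
        ) / sigma
        y = group["chose_reference"].to_numpy(dtype=bool)
        # log p for chosen=reference, log(1-p) otherwise
        total += float(np.sum(log_expit(np.where(y, z, -z))))
    return total


def observations_to_frame(
    observations: Sequence[FirstFreeObservation],
    subject_ids: Sequence[int] | None = None,
    game_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, obs in enumerate(observations):
        rows.append(
            {
                "subject_id": subject_ids[i] if subject_ids is not None else 0,
                "treatment": obs.treatment,
                "game_id": game_ids[i] if game_ids is not None else i,
                "horizon": obs.horizon,
                "info_condition": obs.info_condition,
                "dR": obs.dR,
                "dI": obs.dI,
                "dl": obs.dl,
                "chose_reference": obs.chose_reference,
            }
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def encode_dataset(trials: pd.DataFrame, games: pd.DataFrame) -> pd.DataFrame:
    """Encode every game's first free choice from a trial table.

    ``games`` carries one row per (subject_id, treatment, game_id) with the
    game design columns (info_condition, more_informative_side, horizon).
    Returns a table with OBSERVATION_COLUMNS.
    """
    keys = ["subject_id", "treatment", "game_id"]
    game_info = games.set_index(keys)
    rows = []
    for key, g in trials.groupby(keys, sort=False):
        info = game_info.loc[key]
        forced = g[g["forced"] == 1]
        free = g[(g["forced"] == 0) & (g["trial_index"] == 4)]
        if len(forced) != 4 or len(free) != 1:
            raise DataError(f"game {key}: needs 4 forced trials and a first free choice")
        if info["info_condition"] == UNEQUAL:
            ref = info["more_informative_side"]
        else:
            ref = "L"
        other = "R" if ref == "L" else "L"
        ref_rewards = forced.loc[forced["choice"] == ref, "reward"]
        oth_rewards = forced.loc[forced["choice"] == other, "reward"]
        rows.append(
            {
                "subject_id": key[0],
                "treatment": key[1],
                "game_id": key[2],
                "horizon": int(info["horizon"]),
                "info_condition": info["info_condition"],
                "dR": float(ref_rewards.mean() - oth_rewards.mean()),
                "dI": 1 if info["info_condition"] == UNEQUAL else 0,
                "dl": 1 if ref == "L" else -1,
                "chose_reference": free["choice"].iloc[0] == ref,
            }
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
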