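"""Generative design of Horizon Task sessions.

A session is a sequence of two-armed bandit games. Each game fixes a mean
payoff for the left and right option; single-trial payoffs are Gaussian
around those means with a common standard deviation and are bounded into the
displayed point range. The first four trials of every game are forced
choices that control how much has been observed from each option before the
first free choice: either two plays of each option (equal information,
``[2 2]``) or three plays of one and a single play of the other (unequal
information, ``[1 3]``). The number of free choices that follow — the
horizon — is 1, 6 or 11, so games last 5, 10 or 15 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

EQUAL = "equal_22"
UNEQUAL = "unequal_13"
SIDES = ("L", "R")

#: columns of the trial table, in canonical order
TRIAL_COLUMNS = [
    "subject_id",
    "session_id",
    "treatment",
    "game_id",
    "horizon",
    "info_condition",
    "trial_index",
    "forced",
    "choice",
    "reward",
    "rt_ms",
]


class ConfigurationError(ValueError):
    """Raised when a session configuration violates the task design."""


class DataError(ValueError):
    """Raised when a trial table violates the task invariants."""


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one session's game set.

    Defaults reproduce the shortened task variant: 120 games in four blocks
    of 30, horizons 1/6/11 interleaved with 40 games of each length, four
    forced trials per game, payoff SD 8 points, one option anchored at a
    mean of 40 or 60 and the other offset by 0, 5 or 10 points up or down,
    with payoffs bounded into [1, 100].
    """

    n_games: int = 120
    n_blocks: int = 4
    horizons: tuple[int, ...] = (1, 6, 11)
    n_forced: int = 4
    reward_sd: float = 8.0
    anchor_means: tuple[float, ...] = (40.0, 60.0)
    mean_offsets: tuple[float, ...] = (0.0, 5.0, 10.0)
    reward_bounds: tuple[float, float] = (1.0, 100.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_games % len(self.horizons) != 0:
            raise ConfigurationError(
                f"n_games={self.n_games} not divisible by the "
                f"{len(self.horizons)} horizon conditions"
            )
        if self.n_forced != 4:
            raise ConfigurationError("the task design requires 4 forced trials")
        if self.reward_sd < 0:
            raise ConfigurationError("reward_sd must be non-negative")
        if self.reward_bounds[0] >= self.reward_bounds[1]:
            raise ConfigurationError("reward_bounds must be ordered (low, high)")


@dataclass(frozen=True)
class GameSpec:
    """One game's generative design."""

    game_id: int
    horizon: int
    info_condition: str
    mean_left: float
    mean_right: float
    forced_sequence: tuple[str, ...]
    more_informative_side: str | None

    def __post_init__(self) -> None:
        counts = {s: self.forced_sequence.count(s) for s in SIDES}
        if len(self.forced_sequence) != 4 or set(self.forced_sequence) - set(SIDES):
            raise ConfigurationError("forced_sequence must hold 4 sides (L/R)")
        if self.info_condition == EQUAL:
            if counts["L"] != 2 or self.more_informative_side is not None:
                raise ConfigurationError("equal games sample each side twice")
        elif self.info_condition == UNEQUAL:
            if sorted(counts.values()) != [1, 3]:
                raise ConfigurationError("unequal games sample sides 1-and-3")
            rare = "L" if counts["L"] == 1 else "R"
            if self.more_informative_side != rare:
                raise ConfigurationError(
                    "more_informative_side must be the once-sampled side"
                )
        else:
            raise ConfigurationError(f"unknown info condition {self.info_condition!r}")

    @property
    def n_trials(self) -> int:
        return 4 + self.horizon

    def mean(self, side: str) -> float:
        return self.mean_left if side == "L" else self.mean_right


def _balanced_cells(rng: np.random.Generator, n: int, cells: list) -> list:
    """n draws over the cells: the floor share of each, remainder w/o replacement."""
    reps, extra = divmod(n, len(cells))
    out = cells * reps
    if extra:
        idx = rng.choice(len(cells), size=extra, replace=False)
        out += [cells[i] for i in idx]
    return out


def _forced_sequence(
    rng: np.random.Generator, info: str, more_informative: str | None
) -> tuple[str, ...]:
    if info == EQUAL:
        seq = np.array(["L", "L", "R", "R"])
    else:
        other = "R" if more_informative == "L" else "L"
        seq = np.array([more_informative, other, other, other])
    return tuple(str(s) for s in rng.permutation(seq))


def generate_session(
    config: SessionConfig, rng_seed: int | None = None
) -> list[GameSpec]:
    """Generate one session's games with balanced factorial structure.

    Within each horizon the two information conditions split the games
    exactly in half.  Within each (horizon, information) stratum the design
    cells (anchor side x offset magnitude x offset sign) each receive their
    floor share of games and the remainder is assigned by sampling cells
    without replacement; the 40/60 anchor value and — in unequal games — the
    more-informative side are balanced as evenly as the stratum size allows.
    The final game order is a random interleaving.
    """
    seed = rng_seed if rng_seed is not None else config.seed
    rng = np.random.default_rng(seed)
    per_horizon = config.n_games // len(config.horizons)
    if per_horizon % 2 != 0:
        raise ConfigurationError(
            "games per horizon must be even to balance the information conditions"
        )
    per_stratum = per_horizon // 2

    cells = [
        (anchor_side, offset, sign)
        for anchor_side in SIDES
        for offset in config.mean_offsets
        for sign in (+1.0, -1.0)
    ]

    games: list[GameSpec] = []
    for horizon in config.horizons:
        for info in (EQUAL, UNEQUAL):
            assignment = _balanced_cells(rng, per_stratum, cells)
            rng.shuffle(assignment)
            anchors = _balanced_cells(rng, per_stratum, list(config.anchor_means))
            rng.shuffle(anchors)
            rare_sides = _balanced_cells(rng, per_stratum, list(SIDES))
            rng.shuffle(rare_sides)
            for (anchor_side, offset, sign), anchor, rare in zip(
                assignment, anchors, rare_sides
            ):
                other = anchor + sign * offset
                mean_left, mean_right = (
                    (anchor, other) if anchor_side == "L" else (other, anchor)
                )
                more_informative = rare if info == UNEQUAL else None
                games.append(
                    GameSpec(
                        game_id=-1,  # assigned after interleaving
                        horizon=horizon,
                        info_condition=info,
                        mean_left=mean_left,
                        mean_right=mean_right,
                        forced_sequence=_forced_sequence(rng, info, more_informative),
                        more_informative_side=more_informative,
                    )
                )

    order = rng.permutation(len(games))
    return [replace(games[i], game_id=g) for g, i in enumerate(order)]


def draw_reward(
    mean: float,
    config: SessionConfig,
    rng: np.random.Generator,
    *,
    bound: bool = True,
) -> float:
    """Draw one payoff: Gaussian around ``mean`` with the configured SD.

    With ``bound=True`` (the played task) the draw is rounded to an integer
    and clipped into ``config.reward_bounds``; ``bound=False`` exposes the
    raw Gaussian draw for calibration checks.
    """
    value = rng.normal(mean, config.reward_sd)
    if not bound:
        return float(value)
    low, high = config.reward_bounds
    return float(np.clip(np.round(value), low, high))


def _validate_trials(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "rt_ms"]
    if missing:
        raise DataError(f"trial table missing columns: {missing}")
    bad_side = ~df["choice"].isin(SIDES)
    if bad_side.any():
        row = int(np.flatnonzero(bad_side.to_numpy())[0])
        raise DataError(f"row {row}: column 'choice' must be L or R")
    forced = df["forced"].astype(int)
    expect_forced = (df["trial_index"] < 4).astype(int)
    mismatch = forced != expect_forced
    if mismatch.any():
        row = int(np.flatnonzero(mismatch.to_numpy())[0])
        raise DataError(
            f"row {row}: column 'forced' inconsistent with trial_index "
            "(trials 0-3 are forced, later trials are free)"
        )


def write_session(path: str | Path, records: pd.DataFrame) -> None:
    """Write a trial table to CSV (schema: TRIAL_COLUMNS)."""
    df = records.copy()
    if "rt_ms" not in df.columns:
        df["rt_ms"] = np.nan
    _validate_trials(df)
    df = df[TRIAL_COLUMNS]
    df.to_csv(path, index=False)


def read_session(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_session`."""
    df = pd.read_csv(
        path,
        dtype={
            "subject_id": int,
            "session_id": int,
            "treatment": str,
            "game_id": int,
            "horizon": int,
            "info_condition": str,
            "trial_index": int,
            "forced": int,
            "choice": str,
            "reward": float,
        },
    )
    if df.empty:
        return df.reindex(columns=TRIAL_COLUMNS)
    _validate_trials(df)
    return df[TRIAL_COLUMNS]


def write_config(path: str | Path, config: SessionConfig) -> None:
    data = {
        "n_games": config.n_games,
        "n_blocks": config.n_blocks,
        "horizons": list(config.horizons),
        "n_forced": config.n_forced,
        "reward_sd": config.reward_sd,
        "anchor_means": list(config.anchor_means),
        "mean_offsets": list(config.mean_offsets),
        "reward_bounds": list(config.reward_bounds),
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data))


def read_config(path: str | Path) -> SessionConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("horizons", "anchor_means", "mean_offsets", "reward_bounds"):
        if key in data:
            data[key] = tuple(data[key])
    return SessionConfig(**data)
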