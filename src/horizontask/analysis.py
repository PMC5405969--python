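"""Model-free and model-based statistics on Horizon Task data.

The model-free statistic is the per-cell proportion of games whose first
free choice took the option with the lower mean observed forced-trial reward
(an exploratory choice). Model-based analyses run factorial ANOVAs on the
parameter estimates; reaction-time and performance summaries compare
treatments on the first free trial and on all free choices respectively.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import AnovaRM, anova_lm

from .task_design import DataError

CELL_KEYS = ["subject_id", "treatment", "horizon", "info_condition"]


def exploration_rate(observations: pd.DataFrame) -> pd.DataFrame:
    """Proportion of exploratory first free choices per design cell.

    A choice is exploratory when it takes the option whose forced-trial
    rewards had the lower mean. Games with tied observed means carry no
    signal either way and are excluded; a cell with no eligible games gets a
    missing proportion and ``n_games`` 0.
    """
    obs = observations.copy()
    eligible = obs["dR"] != 0
    # reference chosen and reference worse, or other chosen and other worse
    explored = np.where(
        obs["chose_reference"], obs["dR"] < 0, obs["dR"] > 0
    )
    obs["explored"] = np.where(eligible, explored.astype(float), np.nan)
    out = (
        obs.groupby(CELL_KEYS, dropna=False)["explored"]
        .agg(proportion="mean", n_games="count")
        .reset_index()
    )
    out["n_games"] = out["n_games"].astype(int)
    return out


def _check_cells(df: pd.DataFrame, factors: list[str]) -> None:
    levels = [df[f].unique() for f in factors]
    counts = df.groupby(factors, dropna=False).size()
    for combo in product(*levels):
        key = combo if len(combo) > 1 else combo[0]
        if key not in counts.index:
            raise DataError(f"empty design cell {dict(zip(factors, combo))}")


def factorial_anova(
    estimates: pd.DataFrame, dv: str, factors: list[str]
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA with a between-cells error term.

    Returns one row per effect: F, numerator/denominator df, p-value.
    Matches textbook sums of squares on balanced designs.
    """
    _check_cells(estimates, factors)
    formula = f"{dv} ~ " + " * ".join(f"C({f})" for f in factors)
    table = anova_lm(ols(formula, data=estimates).fit(), typ=2)
    resid_df = float(table.loc["Residual", "df"])
    rows = []
    for effect, row in table.iterrows():
        if effect == "Residual":
            continue
        label = effect.replace("C(", "").replace(")", "").replace(":", " x ")
        F, p = float(row["F"]), float(row["PR(>F)"])
        if not np.isfinite(F) and float(row["sum_sq"]) <= 1e-12:
            F, p = 0.0, 1.0  # no effect variance at all
        rows.append(
            {
                "effect": label,
                "F": F,
                "df_num": int(row["df"]),
                "df_den": int(resid_df),
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def repeated_measures_anova(
    table: pd.DataFrame, dv: str, within: list[str], subject: str = "subject_id"
) -> pd.DataFrame:
    """Repeated-measures ANOVA (within-subject error term) for cell means."""
    _check_cells(table, within)
    res = AnovaRM(data=table, depvar=dv, subject=subject, within=within).fit()
    tab = res.anova_table
    return pd.DataFrame(
        {
            "effect": [e.replace(":", " x ") for e in tab.index],
            "F": tab["F Value"].to_numpy(float),
            "df_num": tab["Num DF"].to_numpy(int),
            "df_den": tab["Den DF"].to_numpy(int),
            "p": tab["Pr > F"].to_numpy(float),
        }
    )


def rt_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean and variability of first-free-trial reaction times per treatment.

    Summaries are computed per subject (mean and SD over games), averaged per
    treatment, and compared across the two treatments with paired t tests.
    Subjects with a single eligible trial get a missing variability entry.
    """
    first_free = trials[(trials["forced"] == 0) & (trials["trial_index"] == 4)]
    if first_free["rt_ms"].isna().all():
        raise DataError("rt_ms column holds no reaction times")
    per_subject = (
        first_free.groupby(["treatment", "subject_id"])["rt_ms"]
        .agg(mean_rt="mean", sd_rt=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan)
        .reset_index()
    )
    out = (
        per_subject.groupby("treatment")[["mean_rt", "sd_rt"]]
        .mean()
        .reset_index()
        .rename(columns={"mean_rt": "mean_rt_ms", "sd_rt": "rt_variability_ms"})
    )
    treatments = sorted(out["treatment"])
    if len(treatments) == 2:
        wide = per_subject.pivot(index="subject_id", columns="treatment")
        for col, name in (("mean_rt", "p_mean"), ("sd_rt", "p_variability")):
            a = wide[(col, treatments[0])]
            b = wide[(col, treatments[1])]
            ok = a.notna() & b.notna()
            out[name] = (
                stats.ttest_rel(a[ok], b[ok]).pvalue if ok.sum() > 1 else np.nan
            )
    return out


def performance_summary(trials: pd.DataFrame, games: pd.DataFrame) -> pd.DataFrame:
    """Task performance per treatment: points earned and percent correct.

    ``correct`` means a free choice of the option with the higher generative
    mean; games whose two means are equal are excluded from percent correct.
    Mean reward is averaged over free-choice trials. Paired t tests compare
    the two treatments on per-subject summaries.
    """
    free = trials[trials["forced"] == 0].merge(
        games[["subject_id", "treatment", "game_id", "mean_left", "mean_right"]],
        on=["subject_id", "treatment", "game_id"],
        validate="many_to_one",
    )
    better = np.where(
        free["mean_left"] > free["mean_right"], "L",
        np.where(free["mean_right"] > free["mean_left"], "R", ""),
    )
    free = free.assign(
        correct=np.where(better == "", np.nan, (free["choice"] == better).astype(float))
    )
    per_subject = (
        free.groupby(["treatment", "subject_id"])
        .agg(mean_reward=("reward", "mean"), percent_correct=("correct", "mean"))
        .reset_index()
    )
    per_subject["percent_correct"] *= 100.0
    out = (
        per_subject.groupby("treatment")[["mean_reward", "percent_correct"]]
        .mean()
        .reset_index()
    )
    treatments = sorted(out["treatment"])
    if len(treatments) == 2:
        wide = per_subject.pivot(index="subject_id", columns="treatment")
        for col, name in (("mean_reward", "p_reward"), ("percent_correct", "p_correct")):
            a, b = wide[(col, treatments[0])], wide[(col, treatments[1])]
            out[name] = stats.ttest_rel(a, b).pvalue if len(a) > 1 else np.nan
    return out
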