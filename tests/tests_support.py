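"""Shared helpers: simple agent populations and an ANOVA oracle."""

from horizontask.agents import PopulationParams
from horizontask.task_design import EQUAL, UNEQUAL


def brute_force_two_way(df, dv, f1, f2):
    """Textbook fixed-effects sums of squares for a balanced two-way design."""
    grand = df[dv].mean()
    ss_a = sum(len(g) * (g[dv].mean() - grand) ** 2 for _, g in df.groupby(f1))
    ss_b = sum(len(g) * (g[dv].mean() - grand) ** 2 for _, g in df.groupby(f2))
    ss_cells = sum(
        len(g) * (g[dv].mean() - grand) ** 2 for _, g in df.groupby([f1, f2])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((g[dv] - g[dv].mean()) ** 2).sum() for _, g in df.groupby([f1, f2])
    )
    a, b = df[f1].nunique(), df[f2].nunique()
    df_err = len(df) - a * b
    ms_err = ss_err / df_err
    return {
        f1: (ss_a / (a - 1) / ms_err, a - 1, df_err),
        f2: (ss_b / (b - 1) / ms_err, b - 1, df_err),
        "interaction": (
            ss_ab / ((a - 1) * (b - 1)) / ms_err,
            (a - 1) * (b - 1),
            df_err,
        ),
    }

ALL_CELLS = [(h, i) for h in (1, 6, 11) for i in (EQUAL, UNEQUAL)]


def constant_population(A=0.0, B=0.0, sigma=5.0) -> PopulationParams:
    """A population in which every subject has the same (A, B, sigma)."""
    return PopulationParams(
        mu_A={h: A for h in (1, 6, 11)},
        sd_A={h: 0.0 for h in (1, 6, 11)},
        mu_B={c: B for c in ALL_CELLS},
        sd_B={c: 0.0 for c in ALL_CELLS},
        k_sigma={c: 1e8 for c in ALL_CELLS},
        scale_sigma={c: sigma / 1e8 for c in ALL_CELLS},
    )
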