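"""Hierarchical Bayesian estimation of the choice-model parameters.

Each subject s has, in each condition cell n (treatment x horizon x
information condition), a spatial bias B_ns and a decision noise sigma_ns;
the information bonus A is indexed by treatment x horizon only, since the
information difference is zero in equal-information games and A is therefore
informed solely by unequal-information choices. Subject-level parameters are
tied together by population distributions,

    A_ns ~ Gaussian(mu_A^n, sd_A^n)
    B_ns ~ Gaussian(mu_B^n, sd_B^n)
    sigma_ns ~ Gamma(shape k^n, scale lambda^n)

with broad hyperpriors: the population means are Gaussian(0, 1000) (second
argument a standard deviation), the precisions 1/sd^2 of the population
Gaussians are Gamma(0.001, 0.001) shape-rate (the standard vague conjugate
prior of BUGS-family samplers; placing it on the SD itself would pile almost
all prior mass at degenerately small SDs), and the Gamma shape and scale get
Exponential priors with rate 0.001 (mean 1000).

Sampling is adaptive Metropolis-within-Gibbs: the conditionally independent
subject-level parameters are updated with elementwise random-walk proposals
(log-scale for sigma), the population means with exact conjugate Gibbs draws,
and the remaining hyperparameters with log-scale random walks. Proposal
scales adapt toward a 44% acceptance rate during burn-in only, so the
retained chains are draws from a fixed transition kernel. The default
schedule runs four independent chains, discards 500 burn-in sweeps, then
draws 5000 samples per chain keeping every 5th — 1000 retained per chain,
4000 in all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_expit

from .choice_model import ParameterError

__all__ = [
    "McmcSchedule",
    "HierarchicalModel",
    "PosteriorDraws",
    "PosteriorSummary",
    "ModelError",
    "build_model",
    "run_mcmc",
    "summarize",
    "fit",
]

# hyperprior constants
_MU_PRIOR_SD = 1000.0
_PREC_PRIOR_SHAPE = 0.001  # Gamma shape-rate prior on 1/sd^2
_PREC_PRIOR_RATE = 0.001
_EXP_PRIOR_RATE = 0.001

_TARGET_ACCEPT = 0.44


class ModelError(ValueError):
    """Raised when the data cannot support the hierarchical model."""


@dataclass(frozen=True)
class McmcSchedule:
    """Chain bookkeeping: burn-in discarded, then thinned samples retained."""

    n_chains: int = 4
    burn_in: int = 500
    samples_per_chain: int = 5000
    thin: int = 5

    def __post_init__(self) -> None:
        if min(self.n_chains, self.samples_per_chain, self.thin) < 1 or self.burn_in < 0:
            raise ParameterError("invalid MCMC schedule")

    @property
    def retained_per_chain(self) -> int:
        return self.samples_per_chain // self.thin

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain


class HierarchicalModel:
    """Joint density over subject- and population-level parameters.

    Built from a table of encoded first free choices (one row per game per
    subject, columns as in ``choice_model.OBSERVATION_COLUMNS``).
    """

    def __init__(self, observations: pd.DataFrame):
        obs = observations.copy()
        obs["treatment"] = obs["treatment"].fillna("none")
        self.subjects = np.sort(obs["subject_id"].unique())
        self.S = len(self.subjects)
        cells = sorted(
            set(zip(obs["treatment"], obs["horizon"], obs["info_condition"]))
        )
        self.cells: list[tuple] = cells  # (treatment, horizon, info)
        self.N = len(cells)
        a_cells = sorted({(t, h) for t, h, _ in cells})
        self.a_cells: list[tuple] = a_cells  # (treatment, horizon)
        self.M = len(a_cells)

        cell_of = {c: i for i, c in enumerate(cells)}
        a_cell_of = {c: i for i, c in enumerate(a_cells)}
        subj_of = {s: i for i, s in enumerate(self.subjects)}

        self.dR = obs["dR"].to_numpy(float)
        self.dI = obs["dI"].to_numpy(float)
        self.dl = obs["dl"].to_numpy(float)
        self.sign = np.where(obs["chose_reference"].to_numpy(bool), 1.0, -1.0)
        self.sub = obs["subject_id"].map(subj_of).to_numpy(int)
        self.cell = np.array(
            [
                cell_of[(t, h, i)]
                for t, h, i in zip(obs["treatment"], obs["horizon"], obs["info_condition"])
            ]
        )
        self.a_cell = np.array(
            [a_cell_of[(t, h)] for t, h in zip(obs["treatment"], obs["horizon"])]
        )
        # flat group ids for per-(cell, subject) likelihood sums
        self.g_cell = self.cell * self.S + self.sub
        self.g_a_cell = self.a_cell * self.S + self.sub

        counts = np.bincount(self.g_cell, minlength=self.N * self.S)
        if (counts == 0).any():
            k = int(np.flatnonzero(counts == 0)[0])
            cell, s = divmod(k, self.S)
            raise ModelError(
                f"subject {self.subjects[s]} has no observations in condition "
                f"cell {self.cells[cell]}"
            )

    # ------------------------------------------------------------------ #

    def _loglik_obs(self, A: np.ndarray, B: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Per-observation Bernoulli log likelihood (log domain throughout)."""
        z = (
            self.dR
            + A[self.a_cell, self.sub] * self.dI
            + B[self.cell, self.sub] * self.dl
        ) / sigma[self.cell, self.sub]
        return log_expit(self.sign * z)

    def _init_state(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Overdispersed start drawn inside a numerically safe range."""
        state = {
            "mu_A": rng.normal(0.0, 3.0, self.M),
            "sd_A": rng.uniform(0.5, 3.0, self.M),
            "mu_B": rng.normal(0.0, 3.0, self.N),
            "sd_B": rng.uniform(0.5, 3.0, self.N),
            "k_sigma": rng.uniform(1.0, 8.0, self.N),
            "scale_sigma": rng.uniform(0.5, 2.0, self.N),
        }
        state["A"] = rng.normal(state["mu_A"][:, None], state["sd_A"][:, None], (self.M, self.S))
        state["B"] = rng.normal(state["mu_B"][:, None], state["sd_B"][:, None], (self.N, self.S))
        state["sigma"] = np.clip(
            rng.gamma(state["k_sigma"][:, None], state["scale_sigma"][:, None], (self.N, self.S)),
            0.5,
            50.0,
        )
        return state

    def _sweep(
        self,
        state: dict[str, np.ndarray],
        steps: dict[str, np.ndarray],
        rng: np.random.Generator,
        ll_obs: np.ndarray,
        adapt_rate: float | None,
    ) -> np.ndarray:
        """One full update of all parameters; returns refreshed ll_obs."""
        S, N, M = self.S, self.N, self.M

        def accept_subject_block(name: str, group: np.ndarray, size: int,
                                 prop: np.ndarray, new_ll: np.ndarray,
                                 prior_delta: np.ndarray) -> np.ndarray:
            delta = (
                np.bincount(group, weights=new_ll - ll_obs, minlength=size)
                .reshape(-1, S)
                + prior_delta
            )
            acc = np.log(rng.random(prior_delta.shape)) < delta
            if adapt_rate is not None:
                alpha = np.exp(np.minimum(delta, 0.0))
                steps[name] *= np.exp(adapt_rate * (alpha - _TARGET_ACCEPT))
            state[name] = np.where(acc, prop, state[name])
            return np.where(acc[group // S, group % S], new_ll, ll_obs)

        # --- information bonus A (only dI != 0 observations move it) ---
        prop = state["A"] + steps["A"] * rng.standard_normal((M, S))
        new_ll = self._loglik_obs(prop, state["B"], state["sigma"])
        prior = -((prop - state["mu_A"][:, None]) ** 2 - (state["A"] - state["mu_A"][:, None]) ** 2) / (
            2 * state["sd_A"][:, None] ** 2
        )
        ll_obs = accept_subject_block("A", self.g_a_cell, M * S, prop, new_ll, prior)

        # --- spatial bias B ---
        prop = state["B"] + steps["B"] * rng.standard_normal((N, S))
        new_ll = self._loglik_obs(state["A"], prop, state["sigma"])
        prior = -((prop - state["mu_B"][:, None]) ** 2 - (state["B"] - state["mu_B"][:, None]) ** 2) / (
            2 * state["sd_B"][:, None] ** 2
        )
        ll_obs = accept_subject_block("B", self.g_cell, N * S, prop, new_ll, prior)

        # --- decision noise sigma (log-scale walk, Gamma prior + Jacobian) ---
        dlog = steps["sigma"] * rng.standard_normal((N, S))
        prop = state["sigma"] * np.exp(dlog)
        new_ll = self._loglik_obs(state["A"], state["B"], prop)
        prior = state["k_sigma"][:, None] * dlog - (prop - state["sigma"]) / state[
            "scale_sigma"
        ][:, None]
        ll_obs = accept_subject_block("sigma", self.g_cell, N * S, prop, new_ll, prior)

        # --- group moves -------------------------------------------------
        # Independent per-parameter walks mix slowly across hierarchical
        # geometry: when a population SD shrinks, subject values pin to the
        # mean (funnel), and the Gamma shape/scale pair is strongly
        # anti-correlated (ridge). Joint moves fix both: translate or
        # rescale a whole Gaussian family at once, slide (k, lambda) along
        # the ridge, and rescale lambda together with the sigmas it governs.

        def group_accept(name: str, group: np.ndarray, size: int, delta_extra,
                         new_ll: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            delta = (
                np.bincount(group, weights=new_ll - ll_obs, minlength=size * S)
                .reshape(size, S)
                .sum(axis=1)
                + delta_extra
            )
            acc = np.log(rng.random(size)) < delta
            if adapt_rate is not None:
                alpha = np.exp(np.minimum(delta, 0.0))
                steps[name] *= np.exp(adapt_rate * (alpha - _TARGET_ACCEPT))
            return acc, np.where(acc[group // S], new_ll, ll_obs)

        for par, mu, sd, grp, size, shift_key, scale_key in (
            ("A", "mu_A", "sd_A", self.g_a_cell, M, "A_shift", "A_scale"),
            ("B", "mu_B", "sd_B", self.g_cell, N, "B_shift", "B_scale"),
        ):
            # translate family: subject values and mean move together
            d = steps[shift_key] * rng.standard_normal(size)
            prop_mu = state[mu] + d
            prop_par = state[par] + d[:, None]
            new_ll = self._loglik_obs(
                prop_par if par == "A" else state["A"],
                prop_par if par == "B" else state["B"],
                state["sigma"],
            )
            dprior = -(prop_mu**2 - state[mu] ** 2) / (2 * _MU_PRIOR_SD**2)
            acc, ll_obs = group_accept(shift_key, grp, size, dprior, new_ll)
            state[mu] = np.where(acc, prop_mu, state[mu])
            state[par] = np.where(acc[:, None], prop_par, state[par])

            # rescale family: SD and subject deviations move together
            dlog = steps[scale_key] * rng.standard_normal(size)
            c = np.exp(dlog)
            prop_sd = state[sd] * c
            prop_par = state[mu][:, None] + c[:, None] * (state[par] - state[mu][:, None])
            new_ll = self._loglik_obs(
                prop_par if par == "A" else state["A"],
                prop_par if par == "B" else state["B"],
                state["sigma"],
            )
            # Gaussian prior ratio of subject values (-S log c), Jacobian
            # ((S+1) log c) and the Gamma prior on the precision 1/sd^2
            # combine to -2*shape*log c - rate * (1/sd'^2 - 1/sd^2)
            dprior = -2 * _PREC_PRIOR_SHAPE * dlog - _PREC_PRIOR_RATE * (
                1 / prop_sd**2 - 1 / state[sd] ** 2
            )
            acc, ll_obs = group_accept(scale_key, grp, size, dprior, new_ll)
            state[sd] = np.where(acc, prop_sd, state[sd])
            state[par] = np.where(acc[:, None], prop_par, state[par])

        # rescale the noise family: lambda and every sigma in the cell
        dlog = steps["sig_scale"] * rng.standard_normal(N)
        c = np.exp(dlog)
        prop_lam = state["scale_sigma"] * c
        prop_sig = state["sigma"] * c[:, None]
        new_ll = self._loglik_obs(state["A"], state["B"], prop_sig)
        dprior = dlog - _EXP_PRIOR_RATE * (prop_lam - state["scale_sigma"])
        acc, ll_obs = group_accept("sig_scale", self.g_cell, N, dprior, new_ll)
        state["scale_sigma"] = np.where(acc, prop_lam, state["scale_sigma"])
        state["sigma"] = np.where(acc[:, None], prop_sig, state["sigma"])

        # --- population means: exact conjugate Gibbs draws ---
        for mu, sd, par in (("mu_A", "sd_A", "A"), ("mu_B", "sd_B", "B")):
            prec = S / state[sd] ** 2 + 1.0 / _MU_PRIOR_SD**2
            mean = (state[par].sum(axis=1) / state[sd] ** 2) / prec
            state[mu] = rng.normal(mean, 1.0 / np.sqrt(prec))

        # --- population SDs: exact conjugate Gibbs draws on the precision ---
        for sd, mu, par in (("sd_A", "mu_A", "A"), ("sd_B", "mu_B", "B")):
            ssq = ((state[par] - state[mu][:, None]) ** 2).sum(axis=1)
            tau = rng.gamma(
                _PREC_PRIOR_SHAPE + S / 2.0, 1.0 / (_PREC_PRIOR_RATE + ssq / 2.0)
            )
            state[sd] = 1.0 / np.sqrt(tau)

        # --- Gamma hyperparameters of sigma: log-scale walks, Exp priors ---
        log_sig_sum = np.log(state["sigma"]).sum(axis=1)
        sig_sum = state["sigma"].sum(axis=1)

        dlog = steps["k_sigma"] * rng.standard_normal(N)
        prop = state["k_sigma"] * np.exp(dlog)
        delta = (
            (prop - state["k_sigma"]) * (log_sig_sum - S * np.log(state["scale_sigma"]))
            - S * (gammaln(prop) - gammaln(state["k_sigma"]))
            - _EXP_PRIOR_RATE * (prop - state["k_sigma"])
            + dlog
        )
        acc = np.log(rng.random(N)) < delta
        if adapt_rate is not None:
            steps["k_sigma"] *= np.exp(adapt_rate * (np.exp(np.minimum(delta, 0.0)) - _TARGET_ACCEPT))
        state["k_sigma"] = np.where(acc, prop, state["k_sigma"])

        dlog = steps["scale_sigma"] * rng.standard_normal(N)
        prop = state["scale_sigma"] * np.exp(dlog)
        delta = (
            -S * state["k_sigma"] * dlog
            - sig_sum * (1 / prop - 1 / state["scale_sigma"])
            - _EXP_PRIOR_RATE * (prop - state["scale_sigma"])
            + dlog
        )
        acc = np.log(rng.random(N)) < delta
        if adapt_rate is not None:
            steps["scale_sigma"] *= np.exp(adapt_rate * (np.exp(np.minimum(delta, 0.0)) - _TARGET_ACCEPT))
        state["scale_sigma"] = np.where(acc, prop, state["scale_sigma"])

        # ridge moves: shape up, scale down (or vice versa) along the
        # anti-correlated (k, lambda) direction; sigma is unchanged so no
        # likelihood evaluation is needed and several repeats are cheap
        for _ in range(20):
            eps = steps["ridge"] * rng.standard_normal(N)
            prop_k = state["k_sigma"] * np.exp(eps)
            prop_lam = state["scale_sigma"] * np.exp(-eps)
            delta = (
                (prop_k - state["k_sigma"]) * log_sig_sum
                - sig_sum * (1 / prop_lam - 1 / state["scale_sigma"])
                - S * (prop_k * np.log(prop_lam) - state["k_sigma"] * np.log(state["scale_sigma"]))
                - S * (gammaln(prop_k) - gammaln(state["k_sigma"]))
                - _EXP_PRIOR_RATE * (prop_k - state["k_sigma"])
                - _EXP_PRIOR_RATE * (prop_lam - state["scale_sigma"])
            )
            acc = np.log(rng.random(N)) < delta
            if adapt_rate is not None:
                steps["ridge"] *= np.exp(
                    adapt_rate * (np.exp(np.minimum(delta, 0.0)) - _TARGET_ACCEPT)
                )
            state["k_sigma"] = np.where(acc, prop_k, state["k_sigma"])
            state["scale_sigma"] = np.where(acc, prop_lam, state["scale_sigma"])

        return ll_obs


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (chain, draw, ...)."""

    draws: dict[str, np.ndarray]
    model: HierarchicalModel
    schedule: McmcSchedule
    seed: int

    @property
    def retained_total(self) -> int:
        arr = next(iter(self.draws.values()))
        return arr.shape[0] * arr.shape[1]

    def rhat(self) -> pd.DataFrame:
        """Split R-hat per scalar parameter (max over elements per variable)."""
        if next(iter(self.draws.values())).shape[0] < 2:
            return pd.DataFrame(
                [{"parameter": n, "max_rhat": np.nan} for n in self.draws]
            )
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(posterior=self.draws)
            rh = az.rhat(idata)
        rows = [
            {"parameter": name, "max_rhat": float(np.nanmax(rh[name].values))}
            for name in self.draws
        ]
        return pd.DataFrame(rows)


def build_model(observations: pd.DataFrame) -> HierarchicalModel:
    """Construct the hierarchical model from encoded first free choices."""
    return HierarchicalModel(observations)


def run_mcmc(
    model: HierarchicalModel,
    schedule: McmcSchedule | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Run independent chains; deterministic given the seed."""
    schedule = schedule or McmcSchedule()
    tracked = ["A", "B", "sigma", "mu_A", "sd_A", "mu_B", "sd_B", "k_sigma", "scale_sigma"]
    out = {
        name: np.empty(
            (schedule.n_chains, schedule.retained_per_chain)
            + ((model.M, model.S) if name == "A" else
               (model.N, model.S) if name in ("B", "sigma") else
               (model.M,) if name in ("mu_A", "sd_A") else (model.N,))
        )
        for name in tracked
    }
    for chain, ss in enumerate(np.random.SeedSequence(seed).spawn(schedule.n_chains)):
        rng = np.random.default_rng(ss)
        state = model._init_state(rng)
        steps = {
            "A": np.full((model.M, model.S), 1.0),
            "B": np.full((model.N, model.S), 1.0),
            "sigma": np.full((model.N, model.S), 0.5),
            "k_sigma": np.full(model.N, 0.3),
            "scale_sigma": np.full(model.N, 0.3),
            "A_shift": np.full(model.M, 0.5),
            "A_scale": np.full(model.M, 0.3),
            "B_shift": np.full(model.N, 0.5),
            "B_scale": np.full(model.N, 0.3),
            "sig_scale": np.full(model.N, 0.2),
            "ridge": np.full(model.N, 0.5),
        }
        ll_obs = model._loglik_obs(state["A"], state["B"], state["sigma"])
        for t in range(schedule.burn_in):
            ll_obs = model._sweep(state, steps, rng, ll_obs, adapt_rate=(t + 1) ** -0.6)
        kept = 0
        for t in range(1, schedule.samples_per_chain + 1):
            ll_obs = model._sweep(state, steps, rng, ll_obs, adapt_rate=None)
            if t % schedule.thin == 0 and kept < schedule.retained_per_chain:
                for name in tracked:
                    out[name][chain, kept] = state[name]
                kept += 1
    result = PosteriorDraws(draws=out, model=model, schedule=schedule, seed=seed)
    rh = result.rhat()
    bad = rh[rh["max_rhat"] > 1.1]
    if not bad.empty:
        warnings.warn(
            "possible non-convergence (split R-hat > 1.1): "
            + ", ".join(f"{r.parameter}={r.max_rhat:.3f}" for r in bad.itertuples()),
            RuntimeWarning,
            stacklevel=2,
        )
    return result


@dataclass
class PosteriorSummary:
    """Posterior summaries at both levels, plus convergence diagnostics.

    ``subject_level`` holds posterior means and central 95% intervals of
    A_ns, B_ns and sigma_ns; ``population_level`` holds posterior medians
    (and 95% intervals) of the hyperparameters, including the implied
    population mean and SD of the decision-noise Gamma for group-level
    reporting.
    """

    subject_level: pd.DataFrame
    population_level: pd.DataFrame
    diagnostics: pd.DataFrame
    retained_total: int

    def noise_table(self) -> pd.DataFrame:
        """Group-level decision-noise table: population mean and SD per cell."""
        pop = self.population_level
        sel = pop[pop["parameter"].isin(["sigma_pop_mean", "sigma_pop_sd"])]
        return sel.pivot_table(
            index=["horizon", "info_condition"],
            columns=["parameter", "treatment"],
            values="median",
        )


def _flat(draws: np.ndarray) -> np.ndarray:
    """(chain, draw, ...) -> (chain*draw, ...)."""
    return draws.reshape((-1,) + draws.shape[2:])


def summarize(result: PosteriorDraws) -> PosteriorSummary:
    model, d = result.model, result.draws
    q = (2.5, 97.5)

    subj_rows = []
    A = _flat(d["A"])
    for m, (t, h) in enumerate(model.a_cells):
        lo, hi = np.percentile(A[:, m, :], q, axis=0)
        for s, sid in enumerate(model.subjects):
            subj_rows.append(
                dict(parameter="A", treatment=t, horizon=h, info_condition=None,
                     subject_id=sid, mean=A[:, m, s].mean(), q2_5=lo[s], q97_5=hi[s])
            )
    for name in ("B", "sigma"):
        X = _flat(d[name])
        for n, (t, h, i) in enumerate(model.cells):
            lo, hi = np.percentile(X[:, n, :], q, axis=0)
            for s, sid in enumerate(model.subjects):
                subj_rows.append(
                    dict(parameter=name, treatment=t, horizon=h, info_condition=i,
                         subject_id=sid, mean=X[:, n, s].mean(), q2_5=lo[s], q97_5=hi[s])
                )
    subject_level = pd.DataFrame(subj_rows)

    pop_rows = []

    def add_pop(parameter, treatment, horizon, info, samples):
        lo, hi = np.percentile(samples, q)
        pop_rows.append(
            dict(parameter=parameter, treatment=treatment, horizon=horizon,
                 info_condition=info, median=float(np.median(samples)),
                 q2_5=float(lo), q97_5=float(hi))
        )

    for m, (t, h) in enumerate(model.a_cells):
        add_pop("mu_A", t, h, None, _flat(d["mu_A"])[:, m])
        add_pop("sd_A", t, h, None, _flat(d["sd_A"])[:, m])
    k, lam = _flat(d["k_sigma"]), _flat(d["scale_sigma"])
    for n, (t, h, i) in enumerate(model.cells):
        add_pop("mu_B", t, h, i, _flat(d["mu_B"])[:, n])
        add_pop("sd_B", t, h, i, _flat(d["sd_B"])[:, n])
        add_pop("k_sigma", t, h, i, k[:, n])
        add_pop("scale_sigma", t, h, i, lam[:, n])
        add_pop("sigma_pop_mean", t, h, i, k[:, n] * lam[:, n])
        add_pop("sigma_pop_sd", t, h, i, np.sqrt(k[:, n]) * lam[:, n])
    population_level = pd.DataFrame(pop_rows)

    return PosteriorSummary(
        subject_level=subject_level,
        population_level=population_level,
        diagnostics=result.rhat(),
        retained_total=result.retained_total,
    )


def fit(
    observations: pd.DataFrame,
    schedule: McmcSchedule | None = None,
    seed: int = 0,
) -> PosteriorSummary:
    """Build, sample and summarize in one call."""
    return summarize(run_mcmc(build_model(observations), schedule, seed))
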