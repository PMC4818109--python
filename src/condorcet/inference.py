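"""One-step Bayesian fitting of the Extended Condorcet Model by MCMC.

The sampler is a Gibbs-within-Metropolis scheme over the full joint posterior:

* the discrete answer key Z_k is drawn exactly from its Bernoulli full
  conditional (two-term Bayes rule per item);
* abilities θ_i, difficulties δ_k and the logits of willingness b_i and
  guess bias g_i use coordinate-wise random-walk Metropolis steps whose
  scales adapt toward 44% acceptance during burn-in only (so the post-burn-in
  kernel is a fixed, valid Markov transition);
* regression coefficients of the latent person parameters on standardized
  covariates have conjugate normal full conditionals and are Gibbs-sampled;
* residual and difficulty scale hyperparameters carry half-Normal priors and
  move by Metropolis on the log scale.

Difficulties are recentered to sum to zero after every sweep, with the same
shift applied to abilities, which leaves θ_i − δ_k (and hence the likelihood)
unchanged and pins the otherwise translation-invariant Rasch scale.  The
regression intercept tracks the shift through its own conjugate update.

Everything is driven by ``numpy.random.Generator`` streams spawned from a
single seed, so a fit is bit-reproducible given its configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

from .data import DONT_KNOW, FALSE, TRUE, CovariateTable, DataError, ResponseMatrix
from .regression import TARGETS, RegressionSpec

logger = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "ConvergenceWarning",
    "fit_ecm",
    "gelman_rubin",
    "summarize_consensus",
    "summarize_persons",
    "PersonSummary",
]

# Weakly informative prior constants: Normal(0, 10^2) on regression
# coefficients (intercepts included), half-Normal(0, 5) on every scale.
COEF_PRIOR_SD = 10.0
SCALE_PRIOR_SD = 5.0

_TINY = 1e-300


class ConvergenceWarning(UserWarning):
    """Emitted when any monitored parameter exceeds the R-hat threshold."""


@dataclass
class McmcConfig:
    """MCMC run settings.

    Defaults mirror a conventional consensus-model analysis: 8 chains with
    1000 burn-in and 1000 retained iterations each, convergence declared at
    split-R̂ < 1.1.
    """

    n_chains: int = 8
    n_burnin: int = 1000
    n_samples: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence monitoring")
        if self.n_samples < 1 or self.n_burnin < 0:
            raise ValueError("n_samples must be >= 1 and n_burnin >= 0")
        if self.rhat_threshold <= 1:
            raise ValueError("rhat_threshold must exceed 1")


@dataclass
class PosteriorDraws:
    """Stacked MCMC draws, indexed (chain, iteration, ...), plus diagnostics.

    ``arrays`` holds, per parameter name, an array whose first two axes are
    chain and iteration:

    - ``"z"``: (C, S, M) binary answer-key draws
    - ``"theta"``, ``"b"``, ``"g"``: (C, S, N)
    - ``"delta"``: (C, S, M)
    - ``"sigma_delta"``: (C, S)
    - per regression target ``t``: ``"beta:t"`` (C, S, 1+P_t) and
      ``"sigma:t"`` (C, S)

    ``coef_names`` maps each target to its coefficient labels, starting with
    ``"intercept"``.
    """

    arrays: dict[str, np.ndarray]
    respondent_ids: list[str]
    item_ids: list[str]
    coef_names: dict[str, list[str]]
    config: McmcConfig
    rhat: dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_chains(self) -> int:
        return next(iter(self.arrays.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.arrays.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        try:
            return self.arrays[name]
        except KeyError:
            raise KeyError(f"no parameter {name!r} in draws") from None

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains pooled: shape (C*S, ...)."""
        arr = self.get(name)
        return arr.reshape(-1, *arr.shape[2:])

    def coefficient_draws(self, target: str, predictor: str) -> np.ndarray:
        """Pooled draws of one regression coefficient (``"intercept"`` allowed)."""
        if target not in self.coef_names:
            raise KeyError(f"no regression target {target!r}; have {list(self.coef_names)}")
        names = self.coef_names[target]
        if predictor not in names:
            raise KeyError(f"no predictor {predictor!r} for target {target!r}; have {names}")
        return self.stacked(f"beta:{target}")[:, names.index(predictor)]

    def consensus_probability(self) -> np.ndarray:
        """Posterior P(Z_k = 1) per item (mean of binary draws)."""
        return self.stacked("z").mean(axis=0)

    def save(self, path: str | Path) -> None:
        """Persist draws and metadata to a ``.npz`` archive."""
        meta = {
            "respondent_ids": np.array(self.respondent_ids),
            "item_ids": np.array(self.item_ids),
            "targets": np.array(list(self.coef_names)),
            "config": np.array(
                [
                    self.config.n_chains,
                    self.config.n_burnin,
                    self.config.n_samples,
                    self.config.seed,
                ]
            ),
            "rhat_threshold": np.array(self.config.rhat_threshold),
            "converged": np.array(self.converged),
        }
        for t, names in self.coef_names.items():
            meta[f"coefnames:{t}"] = np.array(names)
        for name, arr in self.rhat.items():
            meta[f"rhat:{name}"] = arr
        np.savez(path, **{f"draw:{k}": v for k, v in self.arrays.items()}, **meta)

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as archive:
            arrays = {k[5:]: archive[k] for k in archive.files if k.startswith("draw:")}
            rhat = {k[5:]: archive[k] for k in archive.files if k.startswith("rhat:")}
            coef_names = {
                str(t): [str(s) for s in archive[f"coefnames:{t}"]]
                for t in archive["targets"]
            }
            cfg_ints = archive["config"]
            config = McmcConfig(
                n_chains=int(cfg_ints[0]),
                n_burnin=int(cfg_ints[1]),
                n_samples=int(cfg_ints[2]),
                seed=int(cfg_ints[3]),
                rhat_threshold=float(archive["rhat_threshold"]),
            )
            return cls(
                arrays=arrays,
                respondent_ids=[str(s) for s in archive["respondent_ids"]],
                item_ids=[str(s) for s in archive["item_ids"]],
                coef_names=coef_names,
                config=config,
                rhat=rhat,
                converged=bool(archive["converged"]),
            )


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor R̂ for one scalar parameter.

    Each chain is split in half, then the classical between/within variance
    ratio is formed over the 2C half-chains.  Degenerate input (all chains a
    common constant) returns 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains of length >= 4")
    return float(_gelman_rubin_many(chains[:, :, None])[0])


def _gelman_rubin_many(chains: np.ndarray) -> np.ndarray:
    """Vectorized split-R̂ over a (C, S, K) stack; returns (K,)."""
    c, s, k = chains.shape
    half = s // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    n = half
    within = split.var(axis=1, ddof=1).mean(axis=0)
    between = n * split.mean(axis=1).var(axis=0, ddof=1)
    var_hat = (n - 1) / n * within + between / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / within)
    return np.where(within == 0, 1.0, rhat)


# ---------------------------------------------------------------------------
# Sampler internals


class _ChainState:
    __slots__ = ("z", "theta", "delta", "lb", "lg", "beta", "sigma", "sigma_delta")

    def __init__(self, z, theta, delta, lb, lg, beta, sigma, sigma_delta):
        self.z = z
        self.theta = theta
        self.delta = delta
        self.lb = lb  # logit willingness
        self.lg = lg  # logit guess bias
        self.beta = beta  # dict target -> coefficient vector
        self.sigma = sigma  # dict target -> residual sd
        self.sigma_delta = sigma_delta


class _EcmSampler:
    """Single-chain Gibbs-within-Metropolis kernel; see the module docstring."""

    def __init__(
        self,
        data: ResponseMatrix,
        designs: dict[str, np.ndarray],
        coef_names: dict[str, list[str]],
        prior_true: float = 0.5,
        likelihood_weight: float = 1.0,
        coef_prior_sd: float = COEF_PRIOR_SD,
        scale_prior_sd: float = SCALE_PRIOR_SD,
    ):
        self.coef_prior_sd = coef_prior_sd
        self.scale_prior_sd = scale_prior_sd
        y = data.values
        self.y_true = (y == TRUE).astype(float)
        self.y_false = (y == FALSE).astype(float)
        self.y_dk = (y == DONT_KNOW).astype(float)
        self.n, self.m = y.shape
        self.designs = designs  # target -> (N, 1+P) including intercept column
        self.coef_names = coef_names
        self.logit_prior_true = float(logit(prior_true))
        self.lik_weight = likelihood_weight
        # majority-vote key used to break the global reflection symmetry
        with np.errstate(invalid="ignore"):
            frac_true = self.y_true.sum(0) / np.maximum(
                (self.y_true + self.y_false).sum(0), 1
            )
        self.majority_key = (frac_true >= 0.5).astype(np.int8)
        obs_per_person = (self.y_true + self.y_false + self.y_dk).sum(1)
        tf_per_person = (self.y_true + self.y_false).sum(1)
        self.init_lb = logit(
            np.clip(tf_per_person / np.maximum(obs_per_person, 1), 0.02, 0.98)
        )
        self.init_lg = logit(
            np.clip(self.y_true.sum(1) / np.maximum(tf_per_person, 1), 0.02, 0.98)
        )

    # -- likelihood pieces ---------------------------------------------------

    def _cell_probs(self, state: _ChainState):
        d = expit(state.theta[:, None] - state.delta[None, :])
        b = expit(state.lb)[:, None]
        g = expit(state.lg)[:, None]
        return d, b, g

    def _row_loglik(self, theta, delta, z, lb, lg) -> np.ndarray:
        """Per-respondent log-likelihood, shape (N,)."""
        if self.lik_weight == 0.0:
            return np.zeros(theta.shape[0])
        d = expit(theta[:, None] - delta[None, :])
        b = expit(lb)[:, None]
        g = expit(lg)[:, None]
        miss = 1.0 - d
        p_t = d * z[None, :] + miss * b * g
        p_f = d * (1 - z[None, :]) + miss * b * (1 - g)
        p_dk = miss * (1 - b)
        cell = (
            self.y_true * np.log(p_t + _TINY)
            + self.y_false * np.log(p_f + _TINY)
            + self.y_dk * np.log(p_dk + _TINY)
        )
        return cell.sum(axis=1)

    def _col_loglik(self, theta, delta, z, lb, lg) -> np.ndarray:
        if self.lik_weight == 0.0:
            return np.zeros(delta.shape[0])
        d = expit(theta[:, None] - delta[None, :])
        b = expit(lb)[:, None]
        g = expit(lg)[:, None]
        miss = 1.0 - d
        p_t = d * z[None, :] + miss * b * g
        p_f = d * (1 - z[None, :]) + miss * b * (1 - g)
        p_dk = miss * (1 - b)
        cell = (
            self.y_true * np.log(p_t + _TINY)
            + self.y_false * np.log(p_f + _TINY)
            + self.y_dk * np.log(p_dk + _TINY)
        )
        return cell.sum(axis=0)

    # -- initialization ------------------------------------------------------

    def init_state(self, rng: np.random.Generator) -> _ChainState:
        jitter = 0.1
        theta = rng.normal(0.0, jitter, self.n)
        delta = rng.normal(0.0, jitter, self.m)
        delta -= delta.mean()
        lb = self.init_lb + rng.normal(0.0, jitter, self.n)
        lg = self.init_lg + rng.normal(0.0, jitter, self.n)
        beta = {}
        sigma = {}
        for t, x in self.designs.items():
            beta[t] = np.zeros(x.shape[1])
            v = {"ability": theta, "willingness_logit": lb, "guess_bias_logit": lg}[t]
            beta[t][0] = v.mean()
            sigma[t] = 1.0
        return _ChainState(
            z=self.majority_key.copy(),
            theta=theta,
            delta=delta,
            lb=lb,
            lg=lg,
            beta=beta,
            sigma=sigma,
            sigma_delta=1.0,
        )

    # -- individual updates --------------------------------------------------

    def update_z(self, st: _ChainState, rng) -> None:
        if self.lik_weight == 0.0:
            st.z = (rng.random(self.m) < expit(self.logit_prior_true)).astype(np.int8)
            return
        d, b, g = self._cell_probs(st)
        miss = 1.0 - d
        guess_t = miss * b * g
        guess_f = miss * b * (1 - g)
        ll1 = (
            self.y_true * np.log(d + guess_t + _TINY)
            + self.y_false * np.log(guess_f + _TINY)
        ).sum(axis=0)
        ll0 = (
            self.y_true * np.log(guess_t + _TINY)
            + self.y_false * np.log(d + guess_f + _TINY)
        ).sum(axis=0)
        p1 = expit(ll1 - ll0 + self.logit_prior_true)
        st.z = (rng.random(self.m) < p1).astype(np.int8)

    def _metropolis_rows(self, st, current, proposal, prior_mean, prior_sd, which, rng):
        """Coordinate-wise MH accept for a per-person parameter block.

        With the likelihood removed the full conditional is exactly the
        prior, so the block is drawn directly instead of random-walked
        (random-walk moves mix badly through the prior's funnel geometry).
        """
        if self.lik_weight == 0.0:
            draw = prior_mean + prior_sd * rng.standard_normal(current.shape[0])
            return draw, np.ones(current.shape[0], dtype=bool)
        args = dict(theta=st.theta, delta=st.delta, z=st.z, lb=st.lb, lg=st.lg)
        ll0 = self._row_loglik(**args)
        args[which] = proposal
        ll1 = self._row_loglik(**args)
        lp0 = -0.5 * ((current - prior_mean) / prior_sd) ** 2
        lp1 = -0.5 * ((proposal - prior_mean) / prior_sd) ** 2
        accept = np.log(rng.random(current.shape[0])) < (ll1 - ll0 + lp1 - lp0)
        return np.where(accept, proposal, current), accept

    def update_theta(self, st, scales, rng):
        mu = self.designs["ability"] @ st.beta["ability"]
        prop = st.theta + scales * rng.standard_normal(self.n)
        st.theta, acc = self._metropolis_rows(
            st, st.theta, prop, mu, st.sigma["ability"], "theta", rng
        )
        return acc

    def update_delta(self, st, scales, rng):
        if self.lik_weight == 0.0:
            st.delta = st.sigma_delta * rng.standard_normal(self.m)
            accept = np.ones(self.m, dtype=bool)
        else:
            prop = st.delta + scales * rng.standard_normal(self.m)
            ll0 = self._col_loglik(st.theta, st.delta, st.z, st.lb, st.lg)
            ll1 = self._col_loglik(st.theta, prop, st.z, st.lb, st.lg)
            lp0 = -0.5 * (st.delta / st.sigma_delta) ** 2
            lp1 = -0.5 * (prop / st.sigma_delta) ** 2
            accept = np.log(rng.random(self.m)) < (ll1 - ll0 + lp1 - lp0)
            st.delta = np.where(accept, prop, st.delta)
        # pin the translation-invariant scale: shift both delta and theta so
        # theta - delta (hence the likelihood) is unchanged; without a
        # likelihood there is nothing to preserve and shifting theta would
        # leak the shift into the intercept, so only delta is recentered
        shift = st.delta.mean()
        st.delta = st.delta - shift
        if self.lik_weight != 0.0:
            st.theta = st.theta - shift
        return accept

    def update_lb(self, st, scales, rng):
        mu = self.designs["willingness_logit"] @ st.beta["willingness_logit"]
        prop = st.lb + scales * rng.standard_normal(self.n)
        st.lb, acc = self._metropolis_rows(
            st, st.lb, prop, mu, st.sigma["willingness_logit"], "lb", rng
        )
        return acc

    def update_lg(self, st, scales, rng):
        mu = self.designs["guess_bias_logit"] @ st.beta["guess_bias_logit"]
        prop = st.lg + scales * rng.standard_normal(self.n)
        st.lg, acc = self._metropolis_rows(
            st, st.lg, prop, mu, st.sigma["guess_bias_logit"], "lg", rng
        )
        return acc

    def _log_halfnormal(self, sigma: float) -> float:
        return -0.5 * (sigma / self.scale_prior_sd) ** 2

    def _update_scale(self, sigma, residuals, n_dof, step, rng):
        """MH on log sigma with half-Normal prior; returns (sigma, accepted).

        ``n_dof`` is the effective dimension of the residual vector: the
        sum-to-zero-projected difficulties live on an (M-1)-dimensional
        subspace, so their scale update must use M-1 degrees of freedom or
        the scale drifts downward.
        """
        log_s = np.log(sigma)
        prop = np.exp(log_s + step * rng.standard_normal())
        ssq = float((residuals**2).sum())

        def logpost(s):
            return (
                -n_dof * np.log(s)
                - 0.5 * ssq / s**2
                + self._log_halfnormal(s)
                + np.log(s)  # Jacobian of the log transform
            )

        if np.log(rng.random()) < logpost(prop) - logpost(sigma):
            return prop, True
        return sigma, False

    def update_regressions(self, st: _ChainState, scale_steps, rng):
        values = {"ability": st.theta, "willingness_logit": st.lb, "guess_bias_logit": st.lg}
        acc = {}
        for t, x in self.designs.items():
            v = values[t]
            s2 = st.sigma[t] ** 2
            precision = x.T @ x / s2 + np.eye(x.shape[1]) / self.coef_prior_sd**2
            chol = np.linalg.cholesky(precision)
            mean = np.linalg.solve(
                chol.T, np.linalg.solve(chol, x.T @ v / s2)
            )
            st.beta[t] = mean + np.linalg.solve(chol.T, rng.standard_normal(x.shape[1]))
            st.sigma[t], acc[t] = self._update_scale(
                st.sigma[t], v - x @ st.beta[t], v.shape[0], scale_steps[t], rng
            )
        st.sigma_delta, acc["delta"] = self._update_scale(
            st.sigma_delta, st.delta, self.m - 1, scale_steps["delta"], rng
        )
        return acc

    # -- main loop -----------------------------------------------------------

    def run_chain(self, n_burnin: int, n_samples: int, rng: np.random.Generator):
        st = self.init_state(rng)
        s_theta = np.full(self.n, 0.5)
        s_delta = np.full(self.m, 0.5)
        s_lb = np.full(self.n, 0.8)
        s_lg = np.full(self.n, 0.8)
        scale_steps = {t: 0.3 for t in list(self.designs) + ["delta"]}
        target_rate = 0.44

        out = {
            "z": np.empty((n_samples, self.m), dtype=np.int8),
            "theta": np.empty((n_samples, self.n)),
            "delta": np.empty((n_samples, self.m)),
            "b": np.empty((n_samples, self.n)),
            "g": np.empty((n_samples, self.n)),
            "sigma_delta": np.empty(n_samples),
        }
        for t in self.designs:
            out[f"beta:{t}"] = np.empty((n_samples, self.designs[t].shape[1]))
            out[f"sigma:{t}"] = np.empty(n_samples)

        for it in range(n_burnin + n_samples):
            self.update_z(st, rng)
            acc_theta = self.update_theta(st, s_theta, rng)
            acc_delta = self.update_delta(st, s_delta, rng)
            acc_lb = self.update_lb(st, s_lb, rng)
            acc_lg = self.update_lg(st, s_lg, rng)
            acc_scales = self.update_regressions(st, scale_steps, rng)

            if it < n_burnin:
                # Robbins–Monro scale adaptation toward the target rate,
                # frozen at the end of burn-in
                gamma = 1.0 / (1.0 + it) ** 0.6
                s_theta *= np.exp(gamma * (acc_theta - target_rate))
                s_delta *= np.exp(gamma * (acc_delta - target_rate))
                s_lb *= np.exp(gamma * (acc_lb - target_rate))
                s_lg *= np.exp(gamma * (acc_lg - target_rate))
                for key, accepted in acc_scales.items():
                    scale_steps[key] *= np.exp(gamma * (accepted - target_rate))
            else:
                j = it - n_burnin
                out["z"][j] = st.z
                out["theta"][j] = st.theta
                out["delta"][j] = st.delta
                out["b"][j] = expit(st.lb)
                out["g"][j] = expit(st.lg)
                out["sigma_delta"][j] = st.sigma_delta
                for t in self.designs:
                    out[f"beta:{t}"][j] = st.beta[t]
                    out[f"sigma:{t}"][j] = st.sigma[t]
        return out


def _build_designs(
    n: int,
    covariates: CovariateTable | None,
    reg: RegressionSpec | None,
) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    designs: dict[str, np.ndarray] = {}
    coef_names: dict[str, list[str]] = {}
    for t in TARGETS:
        names = list(reg.design.get(t, [])) if reg is not None else []
        cols = [np.ones(n)]
        for name in names:
            cols.append(covariates.column(name))
        designs[t] = np.column_stack(cols)
        coef_names[t] = ["intercept"] + names
    return designs, coef_names


def fit_ecm(
    data: ResponseMatrix,
    covariates: CovariateTable | None = None,
    reg: RegressionSpec | None = None,
    config: McmcConfig | None = None,
    prior_true: float = 0.5,
    prior_only: bool = False,
    coef_prior_sd: float = COEF_PRIOR_SD,
    scale_prior_sd: float = SCALE_PRIOR_SD,
) -> PosteriorDraws:
    """Fit the ECM to a response matrix in one step.

    When ``covariates`` are supplied the latent person parameters are
    regressed on them inside the joint posterior (the "one-step" latent
    regression, which propagates estimation uncertainty into the coefficient
    posteriors instead of regressing point estimates).  With no explicit
    :class:`RegressionSpec`, every covariate enters every target.

    ``prior_only=True`` drops the likelihood so the sampler explores the
    prior — a sampler-correctness diagnostic, not a data analysis.

    Returns :class:`PosteriorDraws` with split-R̂ diagnostics.  A run whose
    monitored parameters exceed the threshold is still returned, but flagged
    via ``converged=False`` and a :class:`ConvergenceWarning`.
    """
    config = config or McmcConfig()
    if covariates is not None:
        if covariates.values.shape[0] != data.n_respondents:
            raise DataError("covariate rows do not match respondents")
        if not covariates.standardized:
            raise DataError(
                "covariates must be standardized before fitting "
                "(see standardize_covariates)"
            )
        if reg is None:
            reg = RegressionSpec.full(covariates.covariate_names)
        reg.validate_against(covariates.covariate_names)
    elif reg is not None and any(reg.design.values()):
        raise DataError("a regression design needs a covariate table")

    designs, coef_names = _build_designs(data.n_respondents, covariates, reg)
    sampler = _EcmSampler(
        data,
        designs,
        coef_names,
        prior_true=prior_true,
        likelihood_weight=0.0 if prior_only else 1.0,
        coef_prior_sd=coef_prior_sd,
        scale_prior_sd=scale_prior_sd,
    )
    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    per_chain = []
    for c, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        logger.info("chain %d/%d", c + 1, config.n_chains)
        per_chain.append(sampler.run_chain(config.n_burnin, config.n_samples, rng))

    arrays = {
        k: np.stack([chain[k] for chain in per_chain], axis=0) for k in per_chain[0]
    }
    draws = PosteriorDraws(
        arrays=arrays,
        respondent_ids=list(data.respondent_ids),
        item_ids=list(data.item_ids),
        coef_names=coef_names,
        config=config,
    )
    _attach_diagnostics(draws)
    return draws


def _attach_diagnostics(draws: PosteriorDraws) -> None:
    """Split-R̂ for every continuous scalar; warn when any exceeds threshold."""
    if draws.n_samples < 4:
        warnings.warn("too few iterations for split-R-hat; diagnostics skipped")
        return
    worst_name, worst = "", 1.0
    for name, arr in draws.arrays.items():
        if name == "z":
            continue  # discrete; monitored through the continuous parameters
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        rhat = _gelman_rubin_many(flat)
        draws.rhat[name] = rhat.reshape(arr.shape[2:]) if arr.ndim > 2 else rhat[0]
        top = float(np.nanmax(rhat))
        if top > worst:
            worst_name, worst = name, top
    if worst > draws.config.rhat_threshold:
        draws.converged = False
        warnings.warn(
            f"worst split-R-hat {worst:.3f} ({worst_name}) exceeds "
            f"{draws.config.rhat_threshold}; treat estimates with caution",
            ConvergenceWarning,
        )
    logger.info("worst split-R-hat %.3f (threshold %.2f)", worst, draws.config.rhat_threshold)


# ---------------------------------------------------------------------------
# Posterior summaries


def summarize_consensus(draws: PosteriorDraws, data: ResponseMatrix) -> pd.DataFrame:
    """Per-item consensus report: raw mean, label, posterior sd, difficulty rank.

    The consensus label is the posterior median of the binary key draws
    (True iff P(Z_k = 1) > 0.5; an exact tie falls back to the item's raw
    mean).  ``posterior_sd`` is the spread of the binary draws, so it is 0
    for items the posterior is certain about and ≈0.5 for an even split.
    Difficulty rank 1 marks the hardest item (largest posterior-mean δ).
    """
    from .data import raw_item_means

    if list(data.item_ids) != list(draws.item_ids):
        raise DataError("draws were fitted on a different set of items")
    p_true = draws.consensus_probability()
    raw = raw_item_means(data)
    label = np.where(p_true > 0.5, True, False)
    ties = p_true == 0.5
    if ties.any():
        label[ties] = raw[ties] > 0.5
    z_sd = draws.stacked("z").std(axis=0)
    delta_mean = draws.stacked("delta").mean(axis=0)
    rank = rankdata(-delta_mean, method="ordinal").astype(int)
    return pd.DataFrame(
        {
            "item": draws.item_ids,
            "raw_mean": raw,
            "consensus_label": np.where(label, "True", "False"),
            "p_true": p_true,
            "posterior_sd": z_sd,
            "difficulty_rank": rank,
        }
    )


@dataclass
class PersonSummary:
    """Posterior summaries of person (and item) parameters, histogram-ready."""

    persons: pd.DataFrame  # per person: mean/sd of theta, b, g
    items: pd.DataFrame  # per item: mean/sd of delta
    population: pd.DataFrame  # mean and sd of the posterior means per parameter


def summarize_persons(draws: PosteriorDraws) -> PersonSummary:
    """Distributions of person- and item-level posterior means.

    ``population`` reports, per parameter, the mean and standard deviation of
    the plotted per-person (or per-item) posterior means — the numbers one
    annotates on the histograms of ability, difficulty, willingness to guess
    and guess bias.
    """
    persons = pd.DataFrame({"respondent": draws.respondent_ids})
    for name, label in (("theta", "ability"), ("b", "willingness"), ("g", "guess_bias")):
        pooled = draws.stacked(name)
        persons[f"{label}_mean"] = pooled.mean(axis=0)
        persons[f"{label}_sd"] = pooled.std(axis=0, ddof=1)
    pooled_delta = draws.stacked("delta")
    items = pd.DataFrame(
        {
            "item": draws.item_ids,
            "difficulty_mean": pooled_delta.mean(axis=0),
            "difficulty_sd": pooled_delta.std(axis=0, ddof=1),
        }
    )
    rows = []
    for label in ("ability", "willingness", "guess_bias"):
        v = persons[f"{label}_mean"].to_numpy()
        rows.append((label, v.mean(), v.std(ddof=1)))
    v = items["difficulty_mean"].to_numpy()
    rows.append(("difficulty", v.mean(), v.std(ddof=1)))
    population = pd.DataFrame(rows, columns=["parameter", "mean", "sd"])
    return PersonSummary(persons=persons, items=items, population=population)
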