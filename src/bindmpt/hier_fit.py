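"""Hierarchical Bayesian estimation of MPT parameters.

The person model is a probit latent-trait structure: person ``p``'s value of
free parameter ``k`` is ``theta[p, k] = Phi(mu[k] + delta[p, k])`` with
``delta[p] ~ MVN(0, Sigma)``, where ``Phi`` is the standard-normal CDF.
Group-level probit means ``mu`` carry independent Normal(0, 1) priors (so each
group-level probability ``Phi(mu_k)`` is uniform a priori) and the person
covariance ``Sigma`` carries a weakly informative conjugate inverse-Wishart
prior.  Posterior sampling is Metropolis-within-Gibbs:

* random-walk updates of each ``delta[:, k]`` column (vectorised over persons
  and chains), using the conditional MVN prior and the single condition whose
  likelihood the parameter touches;
* random-walk updates of each ``mu[k]``;
* a joint "shift" move ``mu[k] += c, delta[:, k] -= c`` that leaves the
  likelihood invariant and decorrelates the group mean from the person
  offsets (accepted on the prior ratio alone);
* an exact conjugate Gibbs draw of ``Sigma``.

Proposal scales adapt toward standard acceptance rates during burn-in and are
frozen afterwards, so retained draws satisfy detailed balance. Setting
``heterogeneity=False`` fixes ``delta = 0`` and reduces the model to a single
set of group parameters with uniform priors on the probability scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .mpt_core import CATEGORIES, MPTModel, counts_array, load_model

__all__ = [
    "HierarchicalConfig",
    "PosteriorDraws",
    "HierarchicalMPT",
    "fit_hierarchical",
    "save_draws",
    "load_draws",
]

_ACCEPT_TARGET = 0.44


@dataclass
class HierarchicalConfig:
    """MCMC run configuration; the seed fully determines the output."""

    n_chains: int = 4
    n_iter: int = 10_000
    n_burnin: int = 2_000
    thin: int = 1
    seed: int = 0
    heterogeneity: bool = True
    prior_mu_sd: float = 1.0
    prior_scale: float = 1.0
    prior_df_add: int = 2
    step_init: float = 0.2
    adapt_every: int = 50
    person_draw_cap: int = 250
    max_init_retries: int = 10

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required (for convergence checks)")
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_mu_sd <= 0 or self.prior_scale <= 0:
            raise ValueError("prior scales must be positive")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "HierarchicalConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws from a hierarchical MPT fit.

    ``mu`` and ``theta`` have shape ``(n_chains, n_draws, K)``; ``theta`` is
    the group-level parameter on the probability scale, ``Phi(mu)``.
    ``person_probit`` holds a thinned subset of person-level probit values
    (``mu + delta``), used by posterior-predictive checks; the full-run mean
    ``person_probit_mean`` feeds the DIC point estimate.
    """

    model_name: str
    experiment: str | None
    parameter_names: tuple[str, ...]
    condition_labels: tuple[str, ...]
    participants: list
    mu: np.ndarray
    theta: np.ndarray
    deviance: np.ndarray
    sigma: np.ndarray | None
    person_probit: np.ndarray
    person_probit_mean: np.ndarray
    config: HierarchicalConfig

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    def parameter_index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise KeyError(
                f"parameter {name!r} not in fit (have {list(self.parameter_names)})"
            ) from None

    def group_posterior(self, name: str) -> np.ndarray:
        """Flattened probability-scale draws of one group-level parameter.

        Draws are ordered by (chain, iteration) so that independently fitted
        posteriors can be paired by index.
        """
        return self.theta[:, :, self.parameter_index(name)].reshape(-1)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and central quantiles per parameter (probability scale)."""
        flat = self.theta.reshape(-1, self.theta.shape[-1])
        q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {
                "parameter": self.parameter_names,
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
            }
        )

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format draw table (chain, iteration, parameter, value)."""
        c, s, k = self.theta.shape
        chains = np.repeat(np.arange(c), s * k)
        iters = np.tile(np.repeat(np.arange(s), k), c)
        params = np.tile(np.asarray(self.parameter_names), c * s)
        return pd.DataFrame(
            {
                "chain": chains,
                "iteration": iters,
                "parameter": params,
                "value": self.theta.reshape(-1),
            }
        )


def save_draws(draws: PosteriorDraws, path) -> None:
    """Serialise a posterior to ``.npz`` (arrays + JSON-encoded metadata)."""
    import json

    meta = {
        "model_name": draws.model_name,
        "experiment": draws.experiment,
        "parameter_names": list(draws.parameter_names),
        "condition_labels": list(draws.condition_labels),
        "participants": [str(p) for p in draws.participants],
        "config": {
            k: getattr(draws.config, k)
            for k in HierarchicalConfig.__dataclass_fields__
        },
    }
    arrays = {
        "mu": draws.mu,
        "deviance": draws.deviance,
        "person_probit": draws.person_probit,
        "person_probit_mean": draws.person_probit_mean,
    }
    if draws.sigma is not None:
        arrays["sigma"] = draws.sigma
    np.savez_compressed(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)


def load_draws(path) -> PosteriorDraws:
    """Load a posterior saved with :func:`save_draws`."""
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        mu = z["mu"]
        return PosteriorDraws(
            model_name=meta["model_name"],
            experiment=meta["experiment"],
            parameter_names=tuple(meta["parameter_names"]),
            condition_labels=tuple(meta["condition_labels"]),
            participants=list(meta["participants"]),
            mu=mu,
            theta=ndtr(mu),
            deviance=z["deviance"],
            sigma=z["sigma"] if "sigma" in z.files else None,
            person_probit=z["person_probit"],
            person_probit_mean=z["person_probit_mean"],
            config=HierarchicalConfig(**meta["config"]),
        )


class _CompiledModel:
    """Branch structure flattened for fast vectorised evaluation."""

    def __init__(self, model: MPTModel):
        self.model = model
        self.param_index = {p: i for i, p in enumerate(model.free_parameters)}
        self.n_params = len(model.free_parameters)
        self.cond_branches: list[list[tuple[int, list[tuple[bool, object, bool]]]]] = []
        self.param_conditions: list[set[int]] = [set() for _ in range(self.n_params)]
        for ci, cond in enumerate(model.conditions):
            compiled = []
            for br in model.branches_for(cond):
                factors = []
                for pname, complement in br.factors:
                    if pname in model.constants:
                        factors.append((True, model.constants[pname], complement))
                    else:
                        k = self.param_index[pname]
                        self.param_conditions[k].add(ci)
                        factors.append((False, k, complement))
                compiled.append((CATEGORIES.index(br.category), factors))
            self.cond_branches.append(compiled)

    def cond_probs(self, theta: np.ndarray, ci: int) -> np.ndarray:
        """Category probabilities for condition ``ci``; theta has shape (..., K)."""
        out = np.zeros(theta.shape[:-1] + (3,), dtype=float)
        for cat, factors in self.cond_branches[ci]:
            prob = np.ones(theta.shape[:-1], dtype=float)
            for is_const, val, complement in factors:
                f = float(val) if is_const else theta[..., val]
                prob = prob * ((1.0 - f) if complement else f)
            out[..., cat] += prob
        return out

    def cond_loglik(self, theta: np.ndarray, ci: int, counts: np.ndarray) -> np.ndarray:
        """Multinomial kernel per person for one condition.

        ``theta``: (..., N, K); ``counts``: (N, C, 3). Returns (..., N).
        """
        p = self.cond_probs(theta, ci)
        n = counts[:, ci, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(p)
            contrib = np.where(n > 0, n * lp, 0.0)
        return contrib.sum(axis=-1)

    def deviance(self, theta: np.ndarray, counts: np.ndarray) -> np.ndarray:
        """-2 * multinomial kernel summed over persons and conditions."""
        total = 0.0
        for ci in range(len(self.model.conditions)):
            total = total + self.cond_loglik(theta, ci, counts).sum(axis=-1)
        return -2.0 * total


def _sample(
    compiled: _CompiledModel,
    counts: np.ndarray,
    config: HierarchicalConfig,
) -> dict:
    """Run the Metropolis-within-Gibbs sampler; returns raw retained arrays."""
    model = compiled.model
    K = compiled.n_params
    N = counts.shape[0]
    C = config.n_chains
    het = config.heterogeneity
    rng = np.random.default_rng(config.seed)

    nu0 = K + config.prior_df_add
    psi0 = config.prior_scale * np.eye(K)
    mu_var = config.prior_mu_sd**2

    n_cond = len(model.conditions)

    def all_loglik(theta):
        ll = np.empty(theta.shape[:-1][:-1] + (N, n_cond))
        for ci in range(n_cond):
            ll[..., ci] = compiled.cond_loglik(theta, ci, counts)
        return ll

    # --- initialisation, retried on non-finite likelihood ---
    for attempt in range(config.max_init_retries):
        mu = 0.25 * rng.standard_normal((C, K))
        delta = (
            0.1 * rng.standard_normal((C, N, K)) if het else np.zeros((C, N, K))
        )
        sigma = np.broadcast_to(psi0 / max(nu0 - K - 1, 1), (C, K, K)).copy()
        lam = np.linalg.inv(sigma)
        theta = ndtr(mu[:, None, :] + delta)
        ll_cond = all_loglik(theta)
        if np.isfinite(ll_cond).all():
            break
    else:
        raise RuntimeError(
            "could not find a finite-likelihood initial state after "
            f"{config.max_init_retries} attempts; check the data against the model"
        )

    step_delta = np.full((C, K), config.step_init)
    step_mu = np.full((C, K), config.step_init)
    step_shift = np.full((C, K), config.step_init)
    acc_delta = np.zeros((C, K))
    acc_mu = np.zeros((C, K))
    acc_shift = np.zeros((C, K))

    n_ret = (config.n_iter - config.n_burnin) // config.thin
    person_thin = max(1, math.ceil(n_ret / config.person_draw_cap))
    mu_out = np.empty((C, n_ret, K))
    dev_out = np.empty((C, n_ret))
    sig_out = np.empty((C, n_ret, K, K)) if het else None
    pp_out = np.empty((C, math.ceil(n_ret / person_thin), N, K))
    pp_sum = np.zeros((N, K))

    cond_lists = [sorted(compiled.param_conditions[k]) for k in range(K)]
    ret = 0
    for it in range(config.n_iter):
        if het:
            # -- per-person latent offsets, one parameter column at a time --
            for k in range(K):
                conds = cond_lists[k]
                eps = step_delta[:, k, None] * rng.standard_normal((C, N))
                d_old = delta[:, :, k]
                d_new = d_old + eps
                theta_new_k = ndtr(mu[:, None, k] + d_new)
                theta_prop = theta.copy()
                theta_prop[:, :, k] = theta_new_k
                dll = np.zeros((C, N))
                ll_new = {}
                for ci in conds:
                    ll_new[ci] = compiled.cond_loglik(theta_prop, ci, counts)
                    dll += ll_new[ci] - ll_cond[:, :, ci]
                # conditional MVN prior change for coordinate k
                lam_kk = lam[:, k, k][:, None]
                s = np.einsum("cnj,cj->cn", delta, lam[:, :, k])
                dprior = -0.5 * lam_kk * (d_new**2 - d_old**2) - (d_new - d_old) * (
                    s - lam_kk * d_old
                )
                accept = np.log(rng.random((C, N))) < dll + dprior
                delta[:, :, k] = np.where(accept, d_new, d_old)
                theta[:, :, k] = np.where(accept, theta_new_k, theta[:, :, k])
                for ci in conds:
                    ll_cond[:, :, ci] = np.where(
                        accept, ll_new[ci], ll_cond[:, :, ci]
                    )
                acc_delta[:, k] += accept.mean(axis=1)

        # -- group-level probit means --
        for k in range(K):
            conds = cond_lists[k]
            eps = step_mu[:, k] * rng.standard_normal(C)
            mu_new = mu[:, k] + eps
            theta_new_k = ndtr(mu_new[:, None] + delta[:, :, k])
            theta_prop = theta.copy()
            theta_prop[:, :, k] = theta_new_k
            dll = np.zeros(C)
            ll_new = {}
            for ci in conds:
                ll_new[ci] = compiled.cond_loglik(theta_prop, ci, counts)
                dll += (ll_new[ci] - ll_cond[:, :, ci]).sum(axis=1)
            dprior = -0.5 * (mu_new**2 - mu[:, k] ** 2) / mu_var
            accept = np.log(rng.random(C)) < dll + dprior
            mu[:, k] = np.where(accept, mu_new, mu[:, k])
            theta[:, :, k] = np.where(accept[:, None], theta_new_k, theta[:, :, k])
            for ci in conds:
                ll_cond[:, :, ci] = np.where(
                    accept[:, None], ll_new[ci], ll_cond[:, :, ci]
                )
            acc_mu[:, k] += accept

        if het:
            # -- likelihood-invariant shift between mu_k and delta[:, k] --
            for k in range(K):
                c_shift = step_shift[:, k] * rng.standard_normal(C)
                mu_new = mu[:, k] + c_shift
                d_old = delta[:, :, k]
                d_new = d_old - c_shift[:, None]
                lam_kk = lam[:, k, k][:, None]
                s = np.einsum("cnj,cj->cn", delta, lam[:, :, k])
                dprior_d = (
                    -0.5 * lam_kk * (d_new**2 - d_old**2)
                    - (d_new - d_old) * (s - lam_kk * d_old)
                ).sum(axis=1)
                dprior_m = -0.5 * (mu_new**2 - mu[:, k] ** 2) / mu_var
                accept = np.log(rng.random(C)) < dprior_d + dprior_m
                mu[:, k] = np.where(accept, mu_new, mu[:, k])
                delta[:, :, k] = np.where(accept[:, None], d_new, d_old)
                acc_shift[:, k] += accept
            # theta unchanged by construction (mu + delta invariant)

            # -- conjugate Gibbs draw of the person covariance --
            for c in range(C):
                scatter = delta[c].T @ delta[c]
                draw = invwishart.rvs(
                    df=nu0 + N, scale=psi0 + scatter, random_state=rng
                )
                sigma[c] = np.atleast_2d(draw)
            lam = np.linalg.inv(sigma)

        # -- proposal adaptation during burn-in only --
        if it < config.n_burnin and (it + 1) % config.adapt_every == 0:
            w = config.adapt_every
            for step, acc in (
                (step_delta, acc_delta),
                (step_mu, acc_mu),
                (step_shift, acc_shift),
            ):
                step *= np.exp(np.clip(acc / w - _ACCEPT_TARGET, -0.5, 0.5))
                acc[:] = 0.0

        # -- retention --
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            mu_out[:, ret] = mu
            dev_out[:, ret] = -2.0 * ll_cond.sum(axis=(1, 2))
            if het:
                sig_out[:, ret] = sigma
            probit = mu[:, None, :] + delta
            pp_sum += probit.mean(axis=0)
            if ret % person_thin == 0:
                pp_out[:, ret // person_thin] = probit
            ret += 1

    return {
        "mu": mu_out,
        "deviance": dev_out,
        "sigma": sig_out,
        "person_probit": pp_out[:, : math.ceil(ret / person_thin)],
        "person_probit_mean": pp_sum / ret,
    }


def fit_hierarchical(
    model: MPTModel,
    data: pd.DataFrame,
    config: HierarchicalConfig | None = None,
) -> PosteriorDraws:
    """Fit the hierarchical latent-trait MPT model to a frequency table.

    ``data`` is a per-participant, per-condition count table (columns
    ``participant``, ``condition``, ``target``, ``lure``, ``new``); every
    participant must have counts for every model condition.
    """
    config = config or HierarchicalConfig()
    if len(data) == 0:
        raise ValueError("empty frequency table")
    participants, counts = counts_array(data, model)
    compiled = _CompiledModel(model)
    raw = _sample(compiled, counts, config)
    return PosteriorDraws(
        model_name=model.name,
        experiment=model.experiment,
        parameter_names=model.free_parameters,
        condition_labels=model.conditions,
        participants=participants,
        mu=raw["mu"],
        theta=ndtr(raw["mu"]),
        deviance=raw["deviance"],
        sigma=raw["sigma"],
        person_probit=raw["person_probit"],
        person_probit_mean=raw["person_probit_mean"],
        config=config,
    )


class HierarchicalMPT(BaseEstimator):
    """Hierarchical Bayesian MPT estimator with a probit latent-trait person model.

    Parameters
    ----------
    model : str or MPTModel, default="dependence"
        Shipped model name (``"independence"`` / ``"dependence"``) or a parsed
        :class:`~bindmpt.mpt_core.MPTModel`.
    experiment : str, default="E1"
        Which experiment's condition structure to load when ``model`` is a name.
    heterogeneity : bool, default=True
        If False, person offsets are fixed at zero (single set of group
        parameters, uniform priors on the probability scale).

    The remaining parameters mirror :class:`HierarchicalConfig`. After
    :meth:`fit`, the posterior is available as ``draws_`` and a probability-
    scale summary table as ``summary_``.
    """

    def __init__(
        self,
        model: str | MPTModel = "dependence",
        experiment: str = "E1",
        n_chains: int = 4,
        n_iter: int = 10_000,
        n_burnin: int = 2_000,
        thin: int = 1,
        seed: int = 0,
        heterogeneity: bool = True,
        prior_mu_sd: float = 1.0,
        prior_scale: float = 1.0,
        prior_df_add: int = 2,
        step_init: float = 0.2,
        adapt_every: int = 50,
        person_draw_cap: int = 250,
        max_init_retries: int = 10,
    ):
        self.model = model
        self.experiment = experiment
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.seed = seed
        self.heterogeneity = heterogeneity
        self.prior_mu_sd = prior_mu_sd
        self.prior_scale = prior_scale
        self.prior_df_add = prior_df_add
        self.step_init = step_init
        self.adapt_every = adapt_every
        self.person_draw_cap = person_draw_cap
        self.max_init_retries = max_init_retries

    def _config(self) -> HierarchicalConfig:
        fields = HierarchicalConfig.__dataclass_fields__
        return HierarchicalConfig(**{f: getattr(self, f) for f in fields})

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalMPT":
        """Fit to a frequency table (see :func:`fit_hierarchical`)."""
        if isinstance(self.model, MPTModel):
            self.model_ = self.model
        else:
            self.model_ = load_model(self.model, self.experiment)
        self.draws_ = fit_hierarchical(self.model_, X, self._config())
        self.summary_ = self.draws_.summary()
        self.participants_ = self.draws_.participants
        return self

    def group_posterior(self, name: str) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "draws_")
        return self.draws_.group_posterior(name)
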