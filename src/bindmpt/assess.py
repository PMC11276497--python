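"""Convergence diagnostics, DIC model comparison, and posterior predictive checks.

* R-hat — the Gelman–Rubin potential scale reduction factor, computed per
  group-level parameter from the between- and within-chain variances of the
  probability-scale draws.
* DIC — penalised deviance ``DIC = Dbar + p_D`` with the effective number of
  parameters ``p_D = Dbar - D(theta_bar)``; the point estimate is evaluated at
  the probit-scale posterior means of the person-level parameters, then
  transformed, which avoids the ambiguity of averaging on the probability
  scale through the nonlinear probit link. Deviance is the multinomial kernel
  times -2 (the multinomial coefficient is a constant and is omitted
  throughout), so absolute DIC values are comparable only within this
  convention; DIC *differences* between models on the same data are not
  affected.
* ppp — the posterior predictive p-value using a chi-square-style discrepancy
  on mean category frequencies (often called the T1 statistic): for each
  posterior draw, observed and model-replicated mean frequencies per
  condition x category are compared with the expected frequencies under the
  drawn parameters, and ppp is the fraction of draws in which the replicated
  discrepancy is at least as large as the observed one. Values near 0
  indicate misfit; a well-fitting model yields values spread over (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .hier_fit import PosteriorDraws, _CompiledModel
from .mpt_core import MPTModel, counts_array

__all__ = [
    "FitAssessment",
    "gelman_rubin",
    "compute_rhat",
    "compute_dic",
    "posterior_predictive_p",
    "assess_fit",
]


@dataclass
class FitAssessment:
    """Bundle of fit diagnostics for one group x model fit."""

    model_name: str
    rhat: dict[str, float]
    dic: float
    p_d: float
    mean_deviance: float
    ppp: float

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["max_rhat"] = self.max_rhat
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def gelman_rubin(x: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar quantity.

    ``x`` has shape ``(n_chains, n_draws)``. Uses the classic between/within
    formula: ``W`` the mean within-chain variance, ``B/n`` the variance of the
    chain means, pooled as ``(n-1)/n * W + B/n``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("R-hat requires draws from at least 2 chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("R-hat requires at least 10 retained draws per chain")
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def compute_rhat(draws: PosteriorDraws) -> dict[str, float]:
    """Gelman–Rubin R-hat per group-level parameter (probability scale)."""
    return {
        name: gelman_rubin(draws.theta[:, :, k])
        for k, name in enumerate(draws.parameter_names)
    }


def compute_dic(
    draws: PosteriorDraws, model: MPTModel, data: pd.DataFrame
) -> tuple[float, float]:
    """Penalised deviance: returns ``(dic, p_d)``; lower DIC is better."""
    if draws.deviance.shape[1] < 2:
        raise ValueError("DIC requires at least 2 posterior draws")
    _, counts = counts_array(data, model)
    compiled = _CompiledModel(model)
    dbar = float(draws.deviance.mean())
    theta_hat = ndtr(draws.person_probit_mean)
    d_hat = float(compiled.deviance(theta_hat, counts))
    p_d = dbar - d_hat
    return dbar + p_d, p_d


def _t1_discrepancy(mean_freq: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Chi-square-style distance between mean frequencies, summed over cells."""
    with np.errstate(divide="ignore", invalid="ignore"):
        cell = (mean_freq - expected) ** 2 / expected
    return np.where(expected > 0, cell, 0.0).sum(axis=(-2, -1))


def posterior_predictive_p(
    draws: PosteriorDraws,
    model: MPTModel,
    data: pd.DataFrame,
    seed: int = 0,
) -> float:
    """Posterior predictive p-value with the mean-frequency (T1) discrepancy."""
    participants, counts = counts_array(data, model)
    compiled = _CompiledModel(model)
    rng = np.random.default_rng(seed)
    c, s, n, k = draws.person_probit.shape
    theta = ndtr(draws.person_probit.reshape(c * s, n, k))
    n_draws = theta.shape[0]
    n_cond = len(model.conditions)
    n_trials = counts.sum(axis=2)  # (N, C)
    obs_mean = counts.mean(axis=0)  # (C, 3)

    probs = np.empty((n_draws, n, n_cond, 3))
    for ci in range(n_cond):
        probs[:, :, ci, :] = compiled.cond_probs(theta, ci)
    expected = (probs * n_trials[None, :, :, None]).mean(axis=1)  # (S, C, 3)

    t_obs = _t1_discrepancy(obs_mean[None], expected)
    # replicate each person's counts from the drawn person-level parameters
    rep_counts = np.empty((n_draws, n, n_cond, 3))
    for ci in range(n_cond):
        for pi in range(n):
            rep_counts[:, pi, ci, :] = rng.multinomial(
                n_trials[pi, ci], probs[:, pi, ci, :]
            )
    t_rep = _t1_discrepancy(rep_counts.mean(axis=1), expected)
    return float(np.mean(t_rep >= t_obs))


def assess_fit(
    draws: PosteriorDraws,
    model: MPTModel,
    data: pd.DataFrame,
    seed: int = 0,
) -> FitAssessment:
    """Full diagnostic bundle: R-hat, DIC with p_D, and ppp."""
    rhat = compute_rhat(draws)
    dic, p_d = compute_dic(draws, model, data)
    ppp = posterior_predictive_p(draws, model, data, seed=seed)
    return FitAssessment(
        model_name=model.name,
        rhat=rhat,
        dic=dic,
        p_d=p_d,
        mean_deviance=float(draws.deviance.mean()),
        ppp=ppp,
    )
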