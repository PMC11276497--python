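"""Synthetic designs and responses mirroring the working-memory binding task.

The generator emulates the study's structure: a within-subject 2x2 design
(binding type crossed with probe type in Experiment 1 or prior-knowledge
consistency in Experiment 2), 12 blocks of 24 critical trials balanced across
the four cells, and n = 30 participants per group. Stimulus descriptors
follow the task's construction rules — four memoranda shapes spaced 72 deg
apart on a shape wheel with a fifth shape reserved for the new probe,
memoranda colours drawn from two of six colour families with the new-probe
colour from a remaining family, and a lure that recombines presented
features. Descriptors are generated for design fidelity only; simulated
responses depend on the condition cell alone, via the MPT category
probabilities at person-level parameters Phi(mu + delta), delta ~ MVN(0,
Sigma) — exactly the heterogeneity structure the hierarchical model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

from .mpt_core import CATEGORIES, ConditionKey, MPTModel, conditions_for

__all__ = [
    "COLOUR_FAMILIES",
    "DesignSpec",
    "TrialSpec",
    "SimulationTruth",
    "generate_design",
    "simulate_responses",
    "simulate_counts",
    "aggregate",
]

COLOUR_FAMILIES = ("red", "yellow", "blue", "green", "grey", "brown")

#: angular spacing of the four memoranda on the shape wheel (degrees)
SHAPE_SEPARATION = 72.0


@dataclass(frozen=True)
class DesignSpec:
    """Experiment design dimensions (defaults match the study)."""

    experiment: str = "E1"
    n_blocks: int = 12
    trials_per_block: int = 24
    n_participants: int = 30

    def __post_init__(self):
        if self.experiment not in ("E1", "E2"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        n_cells = len(conditions_for(self.experiment))
        if self.trials_per_block % n_cells:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} is not divisible by "
                f"the {n_cells} condition cells"
            )
        if min(self.n_blocks, self.n_participants) < 1:
            raise ValueError("n_blocks and n_participants must be positive")

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def trials_per_condition(self) -> int:
        return self.total_trials // len(conditions_for(self.experiment))


@dataclass(frozen=True)
class TrialSpec:
    """One critical trial: condition plus stimulus descriptors.

    ``shape_angles`` are the four memoranda positions on the shape wheel
    (degrees), ``new_shape_angle`` the reserved fifth position. Probes are
    ``(shape_angle, colour)`` descriptor pairs.
    """

    participant: int
    block: int
    trial: int
    condition: ConditionKey
    shape_angles: tuple[float, float, float, float]
    new_shape_angle: float
    colour_families: tuple[str, str]
    memoranda_colours: tuple[str, str, str, str]
    probe_target: tuple[float, str]
    probe_lure: tuple[float, str]
    probe_new: tuple[float, str]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for recovery simulations.

    ``mu`` maps each free parameter to its group-level probit mean;
    ``sigma`` is the person covariance on the probit scale (positive
    semi-definite, in the parameter order of the model).
    """

    mu: dict[str, float]
    sigma: np.ndarray

    def __post_init__(self):
        sig = np.asarray(self.sigma, dtype=float)
        if sig.shape != (len(self.mu), len(self.mu)):
            raise ValueError("sigma must be square with one row per parameter")
        eig = np.linalg.eigvalsh((sig + sig.T) / 2)
        if eig.min() < -1e-10:
            raise ValueError("sigma must be positive semi-definite")

    @classmethod
    def from_probabilities(
        cls,
        model: MPTModel,
        p_b: float = 0.5,
        p_i: float = 0.7,
        sd: float = 0.5,
        corr: float = 0.3,
        overrides: dict[str, float] | None = None,
    ) -> "SimulationTruth":
        """Build a truth from probability-scale group means.

        Every ``P_B_*`` parameter gets probit(p_b), every ``P_I_*`` parameter
        probit(p_i), with per-parameter probability-scale ``overrides``; the
        covariance is exchangeable with standard deviation ``sd`` and
        correlation ``corr`` (the package's default heterogeneity).
        """
        overrides = overrides or {}
        mu = {}
        for name in model.free_parameters:
            p = overrides.get(name, p_b if name.startswith("P_B") else p_i)
            if not 0.0 < p < 1.0:
                raise ValueError(f"probability-scale mean for {name!r} not in (0,1)")
            mu[name] = float(norm.ppf(p))
        k = len(mu)
        sigma = sd**2 * (corr * np.ones((k, k)) + (1 - corr) * np.eye(k))
        return cls(mu=mu, sigma=sigma)


def _make_trial(
    rng: np.random.Generator,
    participant: int,
    block: int,
    trial: int,
    cond: ConditionKey,
) -> TrialSpec:
    base = float(rng.uniform(0.0, 360.0))
    angles = tuple(float((base + SHAPE_SEPARATION * i) % 360.0) for i in range(4))
    new_angle = float((base + SHAPE_SEPARATION * 4) % 360.0)
    fam_idx = rng.choice(len(COLOUR_FAMILIES), size=2, replace=False)
    families = (COLOUR_FAMILIES[fam_idx[0]], COLOUR_FAMILIES[fam_idx[1]])
    # two memoranda per family, distinguishable shades within family
    assignment = rng.permutation([0, 0, 1, 1])
    shades = {0: 0, 1: 0}
    colours = []
    for fam in assignment:
        colours.append(f"{families[fam]}.{shades[fam]}")
        shades[fam] += 1
    colours = tuple(colours)
    remaining = [f for f in COLOUR_FAMILIES if f not in families]
    new_colour = f"{rng.choice(remaining)}.0"

    target_idx = int(rng.integers(4))
    t_angle, t_colour = angles[target_idx], colours[target_idx]
    t_family = assignment[target_idx]
    if cond.experiment == "E2":
        # lure recombines with a presented item of the SAME colour family
        pool = [i for i in range(4) if assignment[i] == t_family and i != target_idx]
    else:
        # E1: lure comes from the other colour family to keep rejection hard
        pool = [i for i in range(4) if assignment[i] != t_family]
    lure_idx = int(rng.choice(pool))
    probe_on_colour = cond.experiment == "E1" and cond.probe == "colour"
    if probe_on_colour:
        # same target shape, differing colours
        probe_target = (t_angle, t_colour)
        probe_lure = (t_angle, colours[lure_idx])
        probe_new = (t_angle, new_colour)
    else:
        # same target colour, differing shapes
        probe_target = (t_angle, t_colour)
        probe_lure = (angles[lure_idx], t_colour)
        probe_new = (new_angle, t_colour)
    return TrialSpec(
        participant=participant,
        block=block,
        trial=trial,
        condition=cond,
        shape_angles=angles,
        new_shape_angle=new_angle,
        colour_families=families,
        memoranda_colours=colours,
        probe_target=probe_target,
        probe_lure=probe_lure,
        probe_new=probe_new,
    )


def generate_design(spec: DesignSpec, seed: int) -> list[TrialSpec]:
    """Seeded, balanced trial list for all participants.

    Condition cells are balanced within every block (equal counts, shuffled
    order), so each cell receives ``total_trials / 4`` trials per participant.
    """
    rng = np.random.default_rng(seed)
    cells = conditions_for(spec.experiment)
    per_cell = spec.trials_per_block // len(cells)
    trials: list[TrialSpec] = []
    for p in range(spec.n_participants):
        for b in range(spec.n_blocks):
            order = np.repeat(np.arange(len(cells)), per_cell)
            rng.shuffle(order)
            for t, ci in enumerate(order):
                trials.append(_make_trial(rng, p, b, t, cells[ci]))
    return trials


def _person_parameters(
    model: MPTModel, truth: SimulationTruth, n_participants: int, rng
) -> np.ndarray:
    names = model.free_parameters
    missing = [p for p in names if p not in truth.mu]
    if missing:
        raise ValueError(f"truth lacks group means for parameters {missing}")
    mu = np.array([truth.mu[p] for p in names])
    sigma = np.asarray(truth.sigma, dtype=float)
    delta = rng.multivariate_normal(
        np.zeros(len(names)), sigma, size=n_participants, method="eigh"
    )
    return ndtr(mu[None, :] + delta)  # (N, K)


def simulate_responses(
    design: list[TrialSpec],
    model: MPTModel,
    truth: SimulationTruth,
    seed: int,
) -> pd.DataFrame:
    """Sample a response category for every trial of a generated design.

    Returns a trial-level record table (one row per trial) with columns
    ``participant, experiment, block, trial, binding, probe_or_consistency,
    condition, response``.
    """
    if not design:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed)
    participants = sorted({t.participant for t in design})
    pidx = {p: i for i, p in enumerate(participants)}
    theta = _person_parameters(model, truth, len(participants), rng)
    names = model.free_parameters
    rows = []
    prob_cache: dict[tuple[int, str], np.ndarray] = {}
    for tr in design:
        key = (pidx[tr.participant], tr.condition.label)
        if key not in prob_cache:
            params = dict(zip(names, theta[key[0]]))
            prob_cache[key] = model.condition_probabilities(
                params, tr.condition.label
            )
        probs = prob_cache[key]
        cat = CATEGORIES[rng.choice(3, p=probs)]
        cond = tr.condition
        rows.append(
            {
                "participant": tr.participant,
                "experiment": cond.experiment,
                "block": tr.block,
                "trial": tr.trial,
                "binding": cond.binding,
                "probe_or_consistency": (
                    cond.probe if cond.experiment == "E1" else cond.consistency
                ),
                "condition": cond.label,
                "response": cat,
            }
        )
    return pd.DataFrame(rows)


def simulate_counts(
    model: MPTModel,
    truth: SimulationTruth,
    n_participants: int,
    trials_per_condition: int,
    seed: int,
) -> pd.DataFrame:
    """Directly simulate a frequency table (multinomial per person x condition).

    Equivalent in distribution to generating a balanced design and
    aggregating; used where trial-level stimulus descriptors are not needed.
    """
    rng = np.random.default_rng(seed)
    theta = _person_parameters(model, truth, n_participants, rng)
    names = model.free_parameters
    rows = []
    for i in range(n_participants):
        params = dict(zip(names, theta[i]))
        for cond in model.conditions:
            probs = model.condition_probabilities(params, cond)
            counts = rng.multinomial(trials_per_condition, probs)
            rows.append(
                {
                    "participant": i,
                    "condition": cond,
                    "target": counts[0],
                    "lure": counts[1],
                    "new": counts[2],
                }
            )
    return pd.DataFrame(rows)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Tally trial-level records into a per-participant, per-condition table."""
    cols = {"participant", "condition", "response"}
    if records.empty:
        return pd.DataFrame(columns=["participant", "condition", *CATEGORIES])
    missing = cols - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns {sorted(missing)}")
    bad = set(records["response"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories {sorted(bad)}")
    tab = (
        records.groupby(["participant", "condition"])["response"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    return tab
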