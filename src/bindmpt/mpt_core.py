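"""Multinomial processing tree (MPT) primitives.

An MPT model expresses the probability of each response category (here:
``target``, ``lure``, ``new`` in a three-alternative working-memory probe
task) as a sum over tree branches, each branch being a product of latent
process probabilities (binding memory ``P_B``, item memory ``P_I``) and
fixed guessing constants (``g_B``, ``g_I``, both 0.5 for identifiability).

Models are defined as data in EQN-style text (one branch per line) and
compiled into :class:`MPTModel` objects; the two models of interest — the
*dependence* model (binding memory is conditional on item memory) and the
*independence* model (binding memory can succeed on its own) — ship as
``.eqn`` files under :mod:`bindmpt.models`, one per experiment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "ConditionKey",
    "conditions_for",
    "Branch",
    "MPTModel",
    "EQNParseError",
    "parse_eqn",
    "load_model",
    "category_probabilities",
    "log_likelihood",
    "validate_frequency_table",
    "counts_array",
]

#: Response categories, in canonical order.
CATEGORIES: tuple[str, str, str] = ("target", "lure", "new")

_EXPERIMENTS = ("E1", "E2")
_BINDINGS = ("intrinsic", "extrinsic")
_PROBES = ("shape", "colour")
_CONSISTENCIES = ("consistent", "inconsistent")


@dataclass(frozen=True)
class ConditionKey:
    """A within-subject condition cell.

    Experiment 1 crosses binding type (intrinsic/extrinsic) with probe type
    (shape/colour); Experiment 2 crosses binding type with prior-knowledge
    consistency (consistent/inconsistent) and uses shape probes only.
    """

    experiment: str
    binding: str
    probe: str = "shape"
    consistency: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.binding not in _BINDINGS:
            raise ValueError(f"unknown binding type {self.binding!r}")
        if self.experiment == "E1":
            if self.probe not in _PROBES:
                raise ValueError(f"unknown probe type {self.probe!r}")
            if self.consistency is not None:
                raise ValueError("Experiment 1 conditions carry no consistency factor")
        else:
            if self.probe != "shape":
                raise ValueError("Experiment 2 uses shape probes only")
            if self.consistency not in _CONSISTENCIES:
                raise ValueError(f"unknown consistency level {self.consistency!r}")

    @property
    def label(self) -> str:
        """Tree label used in EQN files and data tables."""
        if self.experiment == "E1":
            return f"{self.binding}_{self.probe}"
        return f"{self.binding}_{self.consistency}"


def conditions_for(experiment: str) -> tuple[ConditionKey, ...]:
    """The four condition cells of an experiment, in canonical order."""
    if experiment == "E1":
        return tuple(
            ConditionKey("E1", b, probe=p) for b in _BINDINGS for p in _PROBES
        )
    if experiment == "E2":
        return tuple(
            ConditionKey("E2", b, consistency=c)
            for b in _BINDINGS
            for c in _CONSISTENCIES
        )
    raise ValueError(f"unknown experiment {experiment!r}")


@dataclass(frozen=True)
class Branch:
    """One tree branch: a product of parameters / complements feeding a category.

    ``factors`` is an ordered tuple of ``(parameter_name, complement)`` pairs;
    the branch probability is the product of ``theta`` (complement False) or
    ``1 - theta`` (complement True) over the factors.
    """

    condition: str
    category: str
    factors: tuple[tuple[str, bool], ...]


class EQNParseError(ValueError):
    """Raised for malformed EQN model text; carries the offending line number."""


_TOKEN_RE = re.compile(r"^(?:(?P<name>[A-Za-z_][\w.]*)|\(1-(?P<cname>[A-Za-z_][\w.]*)\))$")
_CONST_RE = re.compile(r"^const\s+([A-Za-z_][\w.]*)\s*=\s*([0-9.eE+-]+)$")


def parse_eqn(text: str, name: str = "custom") -> "MPTModel":
    """Parse EQN-dialect model text into an :class:`MPTModel`.

    Grammar, one statement per line (``#`` starts a comment):

    * ``const NAME = VALUE`` declares a fixed-value parameter;
    * ``TREE CATEGORY EXPR`` declares a branch, where ``EXPR`` is a
      ``*``-separated product of ``NAME`` or ``(1-NAME)`` tokens.

    A condition may lack branches for some category (probability 0 there).
    Unknown category labels are rejected.
    """
    constants: dict[str, float] = {}
    branches: list[Branch] = []
    conditions: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _CONST_RE.match(line)
        if m:
            try:
                value = float(m.group(2))
            except ValueError:
                raise EQNParseError(f"line {lineno}: bad constant value {m.group(2)!r}")
            if not 0.0 <= value <= 1.0:
                raise EQNParseError(f"line {lineno}: constant outside [0, 1]")
            constants[m.group(1)] = value
            continue
        parts = line.split()
        if len(parts) != 3:
            raise EQNParseError(
                f"line {lineno}: expected 'tree category expression', got {raw!r}"
            )
        tree, category, expr = parts
        if category not in CATEGORIES:
            raise EQNParseError(
                f"line {lineno}: unknown category {category!r} "
                f"(expected one of {CATEGORIES})"
            )
        factors: list[tuple[str, bool]] = []
        for token in expr.split("*"):
            tm = _TOKEN_RE.match(token)
            if tm is None:
                raise EQNParseError(f"line {lineno}: malformed factor {token!r}")
            if tm.group("name"):
                factors.append((tm.group("name"), False))
            else:
                factors.append((tm.group("cname"), True))
        if tree not in conditions:
            conditions.append(tree)
        branches.append(Branch(tree, category, tuple(factors)))
    if not branches:
        raise EQNParseError("model text declares no branches")
    free = []
    for br in branches:
        for pname, _ in br.factors:
            if pname not in constants and pname not in free:
                free.append(pname)
    return MPTModel(
        name=name,
        conditions=tuple(conditions),
        branches=tuple(branches),
        constants=dict(constants),
        free_parameters=tuple(free),
    )


@dataclass(frozen=True)
class MPTModel:
    """A compiled MPT model: branches grouped by condition, plus parameter sets."""

    name: str
    conditions: tuple[str, ...]
    branches: tuple[Branch, ...]
    constants: dict[str, float]
    free_parameters: tuple[str, ...]
    experiment: str | None = None

    def branches_for(self, condition: str) -> tuple[Branch, ...]:
        return tuple(b for b in self.branches if b.condition == condition)

    def parameters_for(self, condition: str) -> tuple[str, ...]:
        """Free parameters appearing in a condition's branches."""
        seen: list[str] = []
        for b in self.branches_for(condition):
            for pname, _ in b.factors:
                if pname in self.free_parameters and pname not in seen:
                    seen.append(pname)
        return tuple(seen)

    def _resolve(self, params: Mapping[str, object], pname: str):
        if pname in self.constants:
            return self.constants[pname]
        if pname not in params:
            raise KeyError(
                f"parameter {pname!r} required by model {self.name!r} "
                "is missing from the parameter set"
            )
        return params[pname]

    def condition_probabilities(self, params: Mapping[str, object], condition: str) -> np.ndarray:
        """Category probabilities for one condition.

        Parameter values may be scalars or broadcastable arrays; the returned
        array has shape ``(*broadcast_shape, 3)`` in :data:`CATEGORIES` order.
        """
        if condition not in self.conditions:
            raise KeyError(f"condition {condition!r} not in model {self.name!r}")
        per_cat = {cat: None for cat in CATEGORIES}
        for br in self.branches_for(condition):
            prob = None
            for pname, complement in br.factors:
                val = np.asarray(self._resolve(params, pname), dtype=float)
                factor = 1.0 - val if complement else val
                prob = factor if prob is None else prob * factor
            acc = per_cat[br.category]
            per_cat[br.category] = prob if acc is None else acc + prob
        shape = np.broadcast_shapes(
            *(np.shape(v) for v in per_cat.values() if v is not None)
        )
        out = np.zeros(shape + (3,), dtype=float)
        for i, cat in enumerate(CATEGORIES):
            if per_cat[cat] is not None:
                out[..., i] = per_cat[cat]
        return out


def category_probabilities(
    model: MPTModel, params: Mapping[str, float], condition: str
) -> np.ndarray:
    """Probability triple over (target, lure, new) for one condition."""
    for pname in model.parameters_for(condition):
        if pname not in params:
            raise KeyError(
                f"parameter {pname!r} required by condition {condition!r} is missing"
            )
    probs = model.condition_probabilities(params, condition)
    return np.asarray(probs, dtype=float)


def validate_frequency_table(table: pd.DataFrame, model: MPTModel | None = None) -> pd.DataFrame:
    """Validate a per-participant, per-condition count table.

    Expected columns: ``participant``, ``condition``, ``target``, ``lure``,
    ``new``. Counts must be non-negative integers.
    """
    required = ["participant", "condition", *CATEGORIES]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"frequency table is missing columns {missing}")
    counts = table[list(CATEGORIES)].to_numpy()
    if (counts < 0).any():
        raise ValueError("frequency table contains negative counts")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("frequency table counts must be integers")
    if model is not None:
        unknown = set(table["condition"]) - set(model.conditions)
        if unknown:
            raise ValueError(
                f"frequency table conditions {sorted(unknown)} not in model "
                f"{model.name!r} (expected {list(model.conditions)})"
            )
    return table


def counts_array(table: pd.DataFrame, model: MPTModel) -> tuple[list, np.ndarray]:
    """Pivot a frequency table to ``(participants, counts[N, C, 3])`` arrays.

    Every participant must have a row for every model condition.
    """
    validate_frequency_table(table, model)
    participants = sorted(table["participant"].unique())
    n, c = len(participants), len(model.conditions)
    out = np.zeros((n, c, 3), dtype=np.int64)
    idx = {p: i for i, p in enumerate(participants)}
    cidx = {cond: j for j, cond in enumerate(model.conditions)}
    seen = np.zeros((n, c), dtype=bool)
    for row in table.itertuples(index=False):
        i, j = idx[row.participant], cidx[row.condition]
        if seen[i, j]:
            raise ValueError(
                f"duplicate counts for participant {row.participant!r}, "
                f"condition {row.condition!r}"
            )
        seen[i, j] = True
        out[i, j] = [getattr(row, cat) for cat in CATEGORIES]
    if not seen.all():
        i, j = np.argwhere(~seen)[0]
        raise ValueError(
            f"participant {participants[i]!r} has no counts for condition "
            f"{model.conditions[j]!r}"
        )
    return participants, out


def log_likelihood(
    model: MPTModel, params: Mapping[str, float], table: pd.DataFrame
) -> float:
    """Multinomial log-likelihood kernel ``sum n * log p``.

    The multinomial coefficient is omitted (constant in the parameters), and
    the convention ``0 * log 0 = 0`` applies; the result is ``-inf`` only if
    some positive count falls on a zero-probability category.
    """
    validate_frequency_table(table, model)
    total = 0.0
    for row in table.itertuples(index=False):
        probs = model.condition_probabilities(params, row.condition)
        for i, cat in enumerate(CATEGORIES):
            ncat = getattr(row, cat)
            if ncat == 0:
                continue
            p = probs[..., i]
            if np.any(p <= 0.0):
                return float("-inf")
            total += float(ncat * np.log(p))
    return total


def load_model(name: str, experiment: str = "E1") -> MPTModel:
    """Load a shipped model ('independence' or 'dependence') for an experiment."""
    if name not in ("independence", "dependence"):
        raise ValueError(f"unknown model {name!r}")
    if experiment not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    fname = f"{name}_{experiment.lower()}.eqn"
    text = resources.files("bindmpt.models").joinpath(fname).read_text()
    model = parse_eqn(text, name=name)
    object.__setattr__(model, "experiment", experiment)
    return model
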