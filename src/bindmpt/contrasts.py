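"""Posterior contrasts with 95% credibility intervals.

Three contrasts drive the study's inferences, all computed on the probability
scale from paired posterior draws (difference per draw, then mean and
equal-tailed 2.5%/97.5% quantiles):

* cultural difference — the same parameter across two independently fitted
  group posteriors (draws paired by chain and iteration index, valid because
  the two fits are independent);
* binding difference — extrinsic minus intrinsic within one fit;
* prior-knowledge benefit — consistent minus inconsistent within one
  Experiment-2 fit.

A 95% CI excluding zero is the evidence criterion for a difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hier_fit import PosteriorDraws

__all__ = [
    "ContrastResult",
    "posterior_difference",
    "cultural_difference",
    "binding_difference",
    "prior_knowledge_benefit",
    "contrast_table",
]

_LABELS = ("cultural_difference", "binding_difference", "prior_knowledge_benefit")


@dataclass(frozen=True)
class ContrastResult:
    """Posterior mean difference with its 95% equal-tailed credibility interval."""

    label: str
    mean_diff: float
    ci_low: float
    ci_high: float
    excludes_zero: bool

    def __post_init__(self):
        if self.label not in _LABELS:
            raise ValueError(f"unknown contrast label {self.label!r}")


def _summarise(diff: np.ndarray, label: str) -> ContrastResult:
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return ContrastResult(
        label=label,
        mean_diff=float(diff.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        excludes_zero=bool(hi < 0.0 or lo > 0.0),
    )


def posterior_difference(
    draws_a: PosteriorDraws,
    draws_b: PosteriorDraws,
    param_a: str,
    param_b: str,
    label: str,
) -> ContrastResult:
    """Per-draw difference ``a - b``; draws are paired by (chain, iteration)."""
    a = draws_a.group_posterior(param_a)
    b = draws_b.group_posterior(param_b)
    if a.shape != b.shape:
        raise ValueError(
            f"draw counts differ ({a.size} vs {b.size}); thin the longer fit "
            "to the common length before contrasting"
        )
    return _summarise(a - b, label)


def cultural_difference(
    draws_group_a: PosteriorDraws, draws_group_b: PosteriorDraws, param: str
) -> ContrastResult:
    """Group A minus group B for the same parameter of two separate fits."""
    return posterior_difference(
        draws_group_a, draws_group_b, param, param, "cultural_difference"
    )


def _param_name(kind: str, binding: str, cell: str) -> str:
    return f"{kind}_{binding}_{cell}"


def binding_difference(
    draws: PosteriorDraws, kind: str = "P_B", cell: str = "shape"
) -> ContrastResult:
    """Extrinsic minus intrinsic within one fit.

    ``cell`` is the probe type (Experiment 1) or consistency level
    (Experiment 2); ``kind`` is ``"P_B"`` or ``"P_I"``.
    """
    return posterior_difference(
        draws,
        draws,
        _param_name(kind, "extrinsic", cell),
        _param_name(kind, "intrinsic", cell),
        "binding_difference",
    )


def prior_knowledge_benefit(
    draws: PosteriorDraws, binding: str = "extrinsic", kind: str = "P_B"
) -> ContrastResult:
    """Consistent minus inconsistent within an Experiment-2 fit."""
    if draws.experiment != "E2":
        raise ValueError(
            "prior-knowledge benefit is defined for Experiment 2 fits only "
            f"(this fit is {draws.experiment!r})"
        )
    return posterior_difference(
        draws,
        draws,
        _param_name(kind, binding, "consistent"),
        _param_name(kind, binding, "inconsistent"),
        "prior_knowledge_benefit",
    )


def contrast_table(
    draws_by_group: dict[str, PosteriorDraws], kind: str = "P_B"
) -> pd.DataFrame:
    """Group means, CIs and contrasts in the layout of the study's result tables.

    One row per binding x probe/consistency cell with per-group posterior
    means and 95% CIs plus the cultural difference; binding-difference rows
    (and, for Experiment 2, prior-knowledge-benefit rows) follow.
    """
    groups = list(draws_by_group)
    if len(groups) != 2:
        raise ValueError("contrast_table expects exactly two groups")
    ga, gb = groups
    da, db = draws_by_group[ga], draws_by_group[gb]
    if da.experiment != db.experiment:
        raise ValueError("group fits come from different experiments")
    experiment = da.experiment
    cells = (
        ("shape", "colour") if experiment == "E1" else ("consistent", "inconsistent")
    )
    rows = []
    for binding in ("extrinsic", "intrinsic"):
        for cell in cells:
            param = _param_name(kind, binding, cell)
            row = {"row": "estimate", "binding": binding, "cell": cell}
            for gname, d in ((ga, da), (gb, db)):
                post = d.group_posterior(param)
                lo, hi = np.percentile(post, [2.5, 97.5])
                row[f"{gname}_mean"] = post.mean()
                row[f"{gname}_ci_low"] = lo
                row[f"{gname}_ci_high"] = hi
            cd = cultural_difference(da, db, param)
            row["diff_mean"] = cd.mean_diff
            row["diff_ci_low"] = cd.ci_low
            row["diff_ci_high"] = cd.ci_high
            rows.append(row)
        if experiment == "E2":
            for gname, d in ((ga, da), (gb, db)):
                pkb = prior_knowledge_benefit(d, binding=binding, kind=kind)
                rows.append(
                    {
                        "row": "prior_knowledge_benefit",
                        "binding": binding,
                        "cell": gname,
                        "diff_mean": pkb.mean_diff,
                        "diff_ci_low": pkb.ci_low,
                        "diff_ci_high": pkb.ci_high,
                    }
                )
    for cell in cells:
        for gname, d in ((ga, da), (gb, db)):
            bd = binding_difference(d, kind=kind, cell=cell)
            rows.append(
                {
                    "row": "binding_difference",
                    "binding": gname,
                    "cell": cell,
                    "diff_mean": bd.mean_diff,
                    "diff_ci_low": bd.ci_low,
                    "diff_ci_high": bd.ci_high,
                }
            )
    return pd.DataFrame(rows)
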