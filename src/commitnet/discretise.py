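"""Boolean discretisation of expression and trajectory constraints.

A gene is called ON in a sample iff its mean expression strictly exceeds
the average expression of all genes in that same sample; a gene at or below
the average is OFF.  Because the call depends only on within-sample ratios
it is invariant to uniform rescaling (e.g. the choice of housekeeping
reference).

An :class:`ExperimentConstraint` bundles partial expected Boolean states at
selected steps of a synchronous-update trajectory (one step = 1 hr, states
typically observed at 0/4/8/12 hr over a 12-step horizon), optional
network-at-step requirements for switching analyses, and a mandatory-switch
flag (the untreated differentiation trajectory must leave its starting
network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CONTROL = "siSCR"
TIME_POINTS = (0, 4, 8, 12)
DEFAULT_HORIZON = 12


class ConstraintError(ValueError):
    """Raised for ill-formed constraints or discretisation inputs."""


def discretise_states(
    table: pd.DataFrame,
    perturbation: str = CONTROL,
    reference: Mapping[int, float] | None = None,
    log_scale: bool = False,
) -> dict[int, dict[str, int]]:
    """Discretise an expression table into per-time Boolean states.

    Parameters
    ----------
    table:
        Long-format expression table with columns
        ``gene, time_hr, perturbation, replicate, rel_expr``.
    perturbation:
        Which condition to discretise (default: the scrambled-siRNA
        control series).
    reference:
        Optional externally supplied per-time reference averages.  By
        default the reference at each time is the mean over the table's own
        genes of their replicate-mean expression (the six network genes,
        when the table holds them).
    log_scale:
        Average on the log2 scale instead of the linear scale.

    Returns
    -------
    dict mapping ``time_hr -> {gene: 0/1}``; ON (1) iff the gene's mean
    expression strictly exceeds the reference average at that time.
    """
    sub = table[table["perturbation"] == perturbation]
    if sub.empty:
        raise ConstraintError(f"no rows for perturbation {perturbation!r}")
    if (sub["rel_expr"] <= 0).any():
        raise ConstraintError("expression must be strictly positive")
    values = np.log2(sub["rel_expr"]) if log_scale else sub["rel_expr"]
    sub = sub.assign(_val=values)
    states: dict[int, dict[str, int]] = {}
    for t, grp in sub.groupby("time_hr"):
        gene_means = grp.groupby("gene")["_val"].mean()
        if gene_means.empty:
            raise ConstraintError(f"empty gene set at {t} hr")
        ref = reference[int(t)] if reference is not None else gene_means.mean()
        states[int(t)] = {g: int(m > ref) for g, m in gene_means.items()}
    return states


@dataclass(frozen=True)
class ExperimentConstraint:
    """Partial expected states along a trajectory, plus switching demands.

    ``observations`` maps a step to a partial Boolean state expected there;
    ``network_requirements`` pins the index of the network representing the
    system at given steps (steps without an entry leave the network free);
    ``mandatory_switch`` demands that at least one step uses a network
    index greater than zero.
    """

    name: str
    horizon: int = DEFAULT_HORIZON
    observations: Mapping[int, Mapping[str, int]] = field(default_factory=dict)
    network_requirements: Mapping[int, int] = field(default_factory=dict)
    mandatory_switch: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ConstraintError("horizon must be >= 0")
        obs = {int(s): {g: int(v) for g, v in st.items()}
               for s, st in self.observations.items()}
        reqs = {int(s): int(i) for s, i in self.network_requirements.items()}
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "network_requirements", reqs)
        for s, st in obs.items():
            if not 0 <= s <= self.horizon:
                raise ConstraintError(f"observation step {s} outside horizon")
            if any(v not in (0, 1) for v in st.values()):
                raise ConstraintError("observed values must be 0/1")
        last = None
        for s in sorted(reqs):
            if not 0 <= s <= self.horizon:
                raise ConstraintError(f"network requirement step {s} outside horizon")
            if reqs[s] < 0:
                raise ConstraintError("network index must be >= 0")
            if last is not None and reqs[s] < last:
                raise ConstraintError("network requirements must be non-decreasing")
            last = reqs[s]

    @property
    def max_observed_step(self) -> int:
        steps = list(self.observations) + list(self.network_requirements)
        return max(steps) if steps else 0

    def genes(self) -> set[str]:
        out: set[str] = set()
        for st in self.observations.values():
            out.update(st)
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "horizon": self.horizon,
            "observations": {str(s): dict(st)
                             for s, st in sorted(self.observations.items())},
            "network_requirements": {str(s): i for s, i in
                                     sorted(self.network_requirements.items())},
            "mandatory_switch": self.mandatory_switch,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConstraint":
        return cls(
            name=d["name"],
            horizon=int(d.get("horizon", DEFAULT_HORIZON)),
            observations={int(s): st for s, st in d.get("observations", {}).items()},
            network_requirements={int(s): i for s, i in
                                  d.get("network_requirements", {}).items()},
            mandatory_switch=bool(d.get("mandatory_switch", False)),
        )


def build_experiment_constraints(
    states: Mapping[int, Mapping[str, int]],
    name: str = "experiment",
    horizon: int = DEFAULT_HORIZON,
    network_requirements: Mapping[int, int] | None = None,
    mandatory_switch: bool = False,
) -> ExperimentConstraint:
    """Place discretised states at their time steps (1 step = 1 hr)."""
    return ExperimentConstraint(
        name=name,
        horizon=horizon,
        observations=dict(states),
        network_requirements=dict(network_requirements or {}),
        mandatory_switch=mandatory_switch,
    )
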