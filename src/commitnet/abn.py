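"""Abstract Boolean Networks: counting, enumeration, and SAT reasoning.

An Abstract Boolean Network (ABN) carries *definite* interactions (present
in every concrete network) and *possible* interactions (each present or
absent).  A (source, target) pair listed with both signs in the possible
set is an exclusive choice — absent, activating or inhibiting (3 options);
a pair listed with a single sign contributes an independent present/absent
choice (2 options).  The ABN thereby implicitly defines a finite family of
concrete networks; for six genes with every ordered pair (including
self-loops) carrying an exclusive +/- possibility that family numbers
3^36 ~ 1.5e17 models.

Consistency of an ABN with an :class:`~commitnet.discretise.ExperimentConstraint`
is decided by complete explicit search: enumerate concrete networks (in a
deterministic lexicographic order, bounded by an enumeration limit),
enumerate completions of the partial initial observation, simulate the
synchronous trajectory and check every observation.  SAT results carry a
replayable witness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .boolean import (
    ACTIVATING,
    INHIBITING,
    BooleanState,
    ConcreteNetwork,
    Interaction,
    NetworkError,
    complete_states,
    simulate_trajectory,
    state_matches,
    update_state,
)
from .discretise import ExperimentConstraint

DEFAULT_ENUMERATION_LIMIT = 2 ** 20

REQUIRED = "required"
DISALLOWED = "disallowed"
OPTIONAL = "optional"


class EnumerationLimitError(RuntimeError):
    """The ABN defines more concrete networks than the caller allows."""


@dataclass(frozen=True)
class AbstractBooleanNetwork:
    """Definite + possible interactions over a shared gene list."""

    genes: tuple[str, ...]
    definite: frozenset[Interaction]
    possible: frozenset[Interaction]
    rule_choices: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for e in self.definite | self.possible:
            if e.source not in gene_set or e.target not in gene_set:
                raise NetworkError(f"interaction endpoint outside gene list: {e}")
        if self.definite & self.possible:
            raise NetworkError("definite and possible sets must be disjoint")
        definite_pairs = {e.pair for e in self.definite}
        for e in self.possible:
            if e.pair in definite_pairs:
                raise NetworkError(
                    f"pair {e.pair} is definite; the opposite sign cannot be possible"
                )
        for g, choices in self.rule_choices.items():
            if g not in gene_set:
                raise NetworkError(f"rule choice for unknown gene {g!r}")
            if not choices:
                raise NetworkError(f"empty rule choice set for {g!r}")

    def choice_groups(self) -> list[tuple[Interaction | None, ...]]:
        """Independent choices, lexicographic by (source, target).

        Exclusive +/- pairs yield ``(None, activating, inhibiting)``;
        single possibilities yield ``(None, interaction)``.
        """
        by_pair: dict[tuple[str, str], dict[int, Interaction]] = {}
        for e in self.possible:
            by_pair.setdefault(e.pair, {})[e.sign] = e
        groups: list[tuple[Interaction | None, ...]] = []
        for pair in sorted(by_pair):
            signs = by_pair[pair]
            if len(signs) == 2:
                groups.append((None, signs[ACTIVATING], signs[INHIBITING]))
            else:
                (e,) = signs.values()
                groups.append((None, e))
        return groups

    def _rule_groups(self) -> list[tuple[str, tuple[str, ...]]]:
        return [(g, tuple(self.rule_choices[g]))
                for g in self.genes if g in self.rule_choices]


def count_concrete_networks(abn: AbstractBooleanNetwork) -> int:
    """Exact model count: product over independent choices, no enumeration."""
    n = 1
    for group in abn.choice_groups():
        n *= len(group)
    for _, choices in abn._rule_groups():
        n *= len(choices)
    return n


def enumerate_concrete_networks(
    abn: AbstractBooleanNetwork,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> Iterator[ConcreteNetwork]:
    """Yield every concrete network exactly once, deterministically."""
    total = count_concrete_networks(abn)
    if total > limit:
        raise EnumerationLimitError(
            f"ABN defines {total} concrete networks, above the limit {limit}"
        )
    groups = abn.choice_groups()
    rule_groups = abn._rule_groups()
    rule_options = [
        [(g, r) for r in choices] for g, choices in rule_groups
    ] or [[]]
    for picks in itertools.product(*groups) if groups else iter([()]):
        edges = frozenset(abn.definite | {e for e in picks if e is not None})
        if rule_groups:
            for rule_picks in itertools.product(*rule_options):
                yield ConcreteNetwork(abn.genes, edges, dict(rule_picks))
        else:
            yield ConcreteNetwork(abn.genes, edges)


@dataclass(frozen=True)
class SatResult:
    """Outcome of a consistency check, with a replayable witness when SAT."""

    status: str  # "SAT" | "UNSAT"
    network: ConcreteNetwork | None = None
    initial: BooleanState | None = None
    trajectory: tuple | None = None
    networks_examined: int = 0

    @property
    def sat(self) -> bool:
        return self.status == "SAT"


def _trajectory_satisfies(network: ConcreteNetwork,
                          initial: BooleanState,
                          constraint: ExperimentConstraint) -> list[BooleanState] | None:
    """Simulate with early pruning; return the trajectory or None."""
    obs = constraint.observations
    if 0 in obs and not state_matches(obs[0], initial):
        return None
    traj = [initial]
    state = initial
    for k in range(1, constraint.horizon + 1):
        state = update_state(network, state)
        traj.append(state)
        if k in obs and not state_matches(obs[k], state):
            return None
    return traj


def check_consistency(
    abn: AbstractBooleanNetwork,
    constraint: ExperimentConstraint,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> SatResult:
    """Decide whether any concrete network admits a satisfying trajectory.

    Complete over the ABN's concrete networks and over all completions of
    the (possibly partial) step-0 observation; deterministic search order,
    so the returned witness is reproducible.
    """
    if constraint.horizon < constraint.max_observed_step:
        raise NetworkError("horizon shorter than the last observation")
    extra = constraint.genes() - set(abn.genes)
    if extra:
        raise NetworkError(f"constraint mentions unknown genes: {sorted(extra)}")
    initial_partial = constraint.observations.get(0, {})
    examined = 0
    for net in enumerate_concrete_networks(abn, limit=limit):
        examined += 1
        for init in complete_states(abn.genes, initial_partial):
            traj = _trajectory_satisfies(net, init, constraint)
            if traj is not None:
                return SatResult("SAT", net, init, tuple(traj), examined)
    return SatResult("UNSAT", networks_examined=examined)


def _force_absent(abn: AbstractBooleanNetwork,
                  e: Interaction) -> AbstractBooleanNetwork:
    return AbstractBooleanNetwork(
        abn.genes, abn.definite, abn.possible - {e}, abn.rule_choices
    )


def _force_present(abn: AbstractBooleanNetwork,
                   e: Interaction) -> AbstractBooleanNetwork:
    # promoting e removes both signs of its pair from the possible set
    dropped = frozenset(x for x in abn.possible if x.pair == e.pair)
    return AbstractBooleanNetwork(
        abn.genes, abn.definite | {e}, abn.possible - dropped, abn.rule_choices
    )


def classify_interactions(
    abn: AbstractBooleanNetwork,
    constraint: ExperimentConstraint,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> dict[Interaction, str]:
    """Label each possible interaction required / disallowed / optional.

    Required: forcing it absent makes the constraint UNSAT (it appears in
    every consistent solution, hence can be considered definite).
    Disallowed: forcing it present makes the constraint UNSAT.
    Only defined when the instance is SAT.
    """
    base = check_consistency(abn, constraint, limit=limit)
    if not base.sat:
        raise NetworkError("classify_interactions called on an UNSAT instance")
    labels: dict[Interaction, str] = {}
    for e in sorted(abn.possible):
        if not check_consistency(_force_absent(abn, e), constraint, limit=limit).sat:
            labels[e] = REQUIRED
        elif not check_consistency(_force_present(abn, e), constraint, limit=limit).sat:
            labels[e] = DISALLOWED
        else:
            labels[e] = OPTIONAL
    return labels


def promote_classified(abn: AbstractBooleanNetwork,
                       labels: Mapping[Interaction, str]) -> AbstractBooleanNetwork:
    """Promote required interactions to definite and drop disallowed ones."""
    required = {e for e, lab in labels.items() if lab == REQUIRED}
    disallowed = {e for e, lab in labels.items() if lab == DISALLOWED}
    return AbstractBooleanNetwork(
        abn.genes,
        abn.definite | required,
        abn.possible - required - disallowed,
        abn.rule_choices,
    )


def replay_witness(result: SatResult, constraint: ExperimentConstraint) -> bool:
    """Independently replay a SAT witness through the simulator."""
    if not result.sat or result.network is None or result.initial is None:
        return False
    traj = simulate_trajectory(
        [(result.network, 1, constraint.horizon)], result.initial, constraint.horizon
    )
    if list(result.trajectory or ()) != traj:
        return False
    return all(state_matches(obs, traj[k])
               for k, obs in constraint.observations.items())
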