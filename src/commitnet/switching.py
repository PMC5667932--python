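"""Reasoning over ordered sequences of ABNs with monotonic switching.

The differentiation trajectory is modelled as an ordered sequence of ABNs
(typically N0, N4, N8, N12, one per measured time point).  The system
starts in the first network and may only switch forwards (monotonic
switching: 0 hr -> 4 hr -> 8 hr ..., never backwards).  One concrete
network is chosen per ABN and reused across its whole span.  A constraint
may additionally pin the representative network at given steps and may
demand a mandatory switch (at least one step represented by a later
network than the first).

The solver enumerates monotone switch schedules explicitly (for a 12-step
horizon over four networks there are C(15,3) = 455 of them), combines them
with concrete-network choices per visited ABN and completions of the
partial initial observation, and simulates.  Complete and deterministic,
so witnesses are reproducible and checkable against brute force.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from .abn import (
    DEFAULT_ENUMERATION_LIMIT,
    AbstractBooleanNetwork,
    EnumerationLimitError,
    count_concrete_networks,
    enumerate_concrete_networks,
)
from .boolean import (
    BooleanState,
    ConcreteNetwork,
    NetworkError,
    all_states,
    complete_states,
    state_matches,
    update_state,
)
from .discretise import ExperimentConstraint


@dataclass(frozen=True)
class SwitchingProblem:
    """An ordered ABN sequence plus one experiment constraint."""

    abns: tuple[AbstractBooleanNetwork, ...]
    constraint: ExperimentConstraint

    def __post_init__(self) -> None:
        if not self.abns:
            raise NetworkError("need at least one ABN")
        genes = self.abns[0].genes
        if any(a.genes != genes for a in self.abns):
            raise NetworkError("all ABNs must share the same gene list")
        bad = [i for i in self.constraint.network_requirements.values()
               if not 0 <= i < len(self.abns)]
        if bad:
            raise NetworkError(f"network requirement indices out of range: {bad}")
        if self.constraint.horizon < self.constraint.max_observed_step:
            raise NetworkError("horizon shorter than the last observation")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.abns[0].genes


@dataclass(frozen=True)
class SwitchSolution:
    """A witness: schedule, per-ABN concrete choice, initial state, trajectory."""

    schedule: tuple[int, ...]          # network index at steps 0..horizon
    networks: Mapping[int, ConcreteNetwork]  # ABN index -> chosen concrete net
    initial: BooleanState
    trajectory: tuple

    @property
    def visited_path(self) -> tuple[int, ...]:
        path = [self.schedule[0]]
        for i in self.schedule[1:]:
            if i != path[-1]:
                path.append(i)
        return tuple(path)


def iter_schedules(problem: SwitchingProblem) -> Iterator[tuple[int, ...]]:
    """All admissible monotone schedules, deterministically ordered.

    A schedule assigns a network index to every step 0..horizon,
    non-decreasing, starting in the first ABN's stretch of the monotone
    map (index at step 0 may be pinned by a requirement).  Encoded by the
    switch steps t_1 <= ... <= t_{K-1} at which the index increments.
    """
    horizon = problem.constraint.horizon
    k = len(problem.abns)
    reqs = problem.constraint.network_requirements
    mandatory = problem.constraint.mandatory_switch
    for switches in itertools.combinations_with_replacement(
        range(horizon + 2), k - 1
    ):
        # index at step s = number of switch times <= s (horizon+1 = never)
        schedule = tuple(
            sum(1 for t in switches if t <= s) for s in range(horizon + 1)
        )
        if mandatory and schedule[-1] == 0:
            continue
        if any(schedule[s] != i for s, i in reqs.items()):
            continue
        yield schedule


def _concrete_choices(
    problem: SwitchingProblem, visited: Sequence[int], limit: int
) -> Iterator[dict[int, ConcreteNetwork]]:
    total = 1
    for i in visited:
        total *= count_concrete_networks(problem.abns[i])
    if total > limit:
        raise EnumerationLimitError(
            f"{total} concrete-network combinations exceed the limit {limit}"
        )
    streams = [list(enumerate_concrete_networks(problem.abns[i], limit=limit))
               for i in visited]
    for combo in itertools.product(*streams):
        yield dict(zip(visited, combo))


def _run_schedule(
    schedule: tuple[int, ...],
    networks: Mapping[int, ConcreteNetwork],
    initial: BooleanState,
    constraint: ExperimentConstraint,
) -> tuple | None:
    obs = constraint.observations
    if 0 in obs and not state_matches(obs[0], initial):
        return None
    traj = [initial]
    state = initial
    for k in range(1, constraint.horizon + 1):
        state = update_state(networks[schedule[k]], state)
        traj.append(state)
        if k in obs and not state_matches(obs[k], state):
            return None
    return tuple(traj)


def solve_switching(
    problem: SwitchingProblem,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> SwitchSolution | None:
    """First satisfying solution in deterministic order, or None (UNSAT)."""
    initial_partial = problem.constraint.observations.get(0, {})
    for schedule in iter_schedules(problem):
        visited = sorted(set(schedule))
        for networks in _concrete_choices(problem, visited, limit):
            for init in complete_states(problem.genes, initial_partial):
                traj = _run_schedule(schedule, networks, init,
                                     problem.constraint)
                if traj is not None:
                    return SwitchSolution(schedule, networks, init, traj)
    return None


def classify_switch_paths(
    problem: SwitchingProblem,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> set[tuple[int, ...]]:
    """The set of visited-ABN sequences over all solutions (empty iff UNSAT)."""
    initial_partial = problem.constraint.observations.get(0, {})
    feasible: set[tuple[int, ...]] = set()
    for schedule in iter_schedules(problem):
        visited = sorted(set(schedule))
        path = _dedupe(schedule)
        if path in feasible:
            continue
        found = False
        for networks in _concrete_choices(problem, visited, limit):
            for init in complete_states(problem.genes, initial_partial):
                if _run_schedule(schedule, networks, init,
                                 problem.constraint) is not None:
                    found = True
                    break
            if found:
                break
        if found:
            feasible.add(path)
    return feasible


def _dedupe(schedule: Sequence[int]) -> tuple[int, ...]:
    path = [schedule[0]]
    for i in schedule[1:]:
        if i != path[-1]:
            path.append(i)
    return tuple(path)


def is_pattern_compatible(
    abn: AbstractBooleanNetwork,
    target_state: Mapping[str, int],
    horizon: int,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> bool:
    """Can some concrete network reach ``target_state`` at step ``horizon``?

    Any total initial state is admissible; the target may be partial.
    Used to ask e.g. whether a drug-arrested expression pattern is
    compatible with the network inferred at a given stage.
    """
    extra = set(target_state) - set(abn.genes)
    if extra:
        raise NetworkError(f"target mentions unknown genes: {sorted(extra)}")
    for net in enumerate_concrete_networks(abn, limit=limit):
        for init in all_states(abn.genes):
            state = init
            for _ in range(horizon):
                state = update_state(net, state)
            if state_matches(target_state, state):
                return True
    return False
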