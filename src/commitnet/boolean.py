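"""Concrete Boolean networks with synchronous update semantics.

A concrete network is a fixed set of signed directed interactions over a
gene list plus one regulation rule per gene.  States are total assignments
``gene -> 0/1``; trajectories are produced by synchronous updates (every
gene reads the *same* input state), one step per hour of the differentiation
time course.

The default regulation rule is activator-disjunctive and inhibitor-dominant:
a gene switches ON iff at least one of its activators is ON and none of its
inhibitors is ON; a gene with no incoming activating interaction holds its
current value unless an inhibitor is ON.  Alternative rules live in a small
catalogue (:data:`RULES`); every rule must be monotone non-decreasing in
activator activity and non-increasing in inhibitor activity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

ACTIVATING = 1
INHIBITING = -1

SIGN_WORDS = {ACTIVATING: "activates", INHIBITING: "inhibits"}
WORD_SIGNS = {w: s for s, w in SIGN_WORDS.items()}

BooleanState = dict[str, int]


class NetworkError(ValueError):
    """Raised for ill-formed networks, states or schedules."""


@dataclass(frozen=True, order=True)
class Interaction:
    """A signed directed interaction ``source -> target``."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATING, INHIBITING):
            raise NetworkError(f"sign must be +1 or -1, got {self.sign!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)

    def __str__(self) -> str:  # SIF-style rendering, handy in error messages
        return f"{self.source} {SIGN_WORDS[self.sign]} {self.target}"


# A rule maps (has_activators, any_activator_on, all_activators_on,
#              any_inhibitor_on, current) -> next value.  all_activators_on
# is True vacuously when the gene has no activators.
RuleFn = Callable[[bool, bool, bool, bool, bool], bool]


def _rule_default(has_act: bool, any_act: bool, all_act: bool,
                  any_inh: bool, cur: bool) -> bool:
    return (any_act if has_act else cur) and not any_inh


def _rule_all_activators(has_act: bool, any_act: bool, all_act: bool,
                         any_inh: bool, cur: bool) -> bool:
    return (all_act if has_act else cur) and not any_inh


def _rule_activator_override(has_act: bool, any_act: bool, all_act: bool,
                             any_inh: bool, cur: bool) -> bool:
    # an active activator wins over inhibitors; otherwise hold unless inhibited
    return any_act or (cur and not any_inh)


#: Catalogue of named regulation rules.  ``default`` is used everywhere
#: unless a network explicitly selects another rule per gene.
RULES: dict[str, RuleFn] = {
    "default": _rule_default,
    "all_activators": _rule_all_activators,
    "activator_override": _rule_activator_override,
}


def rule_is_monotone(rule: RuleFn) -> bool:
    """Exhaustively check a rule's monotonicity over all predicate combos.

    Monotone non-decreasing in activator activity, non-increasing in
    inhibitor activity, for every current value and both with and without
    incoming activators.
    """
    for cur in (False, True):
        for has_act in (False, True):
            combos = (
                [(False, True)] if not has_act  # vacuous all_act, no any_act
                else [(False, False), (True, False), (True, True)]
            )
            for any_inh in (False, True):
                # activator monotonicity: increasing (any_act, all_act)
                vals = [rule(has_act, a, al, any_inh, cur) for a, al in combos]
                if any(v0 > v1 for v0, v1 in zip(vals, vals[1:])):
                    return False
            for a, al in combos:
                v_off = rule(has_act, a, al, False, cur)
                v_on = rule(has_act, a, al, True, cur)
                if v_on > v_off:
                    return False
    return True


@dataclass(frozen=True)
class ConcreteNetwork:
    """A fixed topology (signed interactions) plus one rule per gene."""

    genes: tuple[str, ...]
    interactions: frozenset[Interaction]
    rules: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise NetworkError("duplicate gene names")
        seen_pairs: dict[tuple[str, str], int] = {}
        for e in self.interactions:
            if e.source not in gene_set or e.target not in gene_set:
                raise NetworkError(f"interaction endpoint outside gene list: {e}")
            if seen_pairs.setdefault(e.pair, e.sign) != e.sign:
                raise NetworkError(f"pair {e.pair} carries both signs")
        for g, r in self.rules.items():
            if g not in gene_set:
                raise NetworkError(f"rule for unknown gene {g!r}")
            if r not in RULES:
                raise NetworkError(f"unknown rule {r!r}")
        # precomputed regulator lists (frozen dataclass: set via object)
        acts: dict[str, tuple[str, ...]] = {g: () for g in self.genes}
        inhs: dict[str, tuple[str, ...]] = {g: () for g in self.genes}
        for e in sorted(self.interactions):
            if e.sign == ACTIVATING:
                acts[e.target] = acts[e.target] + (e.source,)
            else:
                inhs[e.target] = inhs[e.target] + (e.source,)
        object.__setattr__(self, "_activators", acts)
        object.__setattr__(self, "_inhibitors", inhs)

    def rule_for(self, gene: str) -> str:
        return self.rules.get(gene, "default")

    def activators_of(self, gene: str) -> tuple[str, ...]:
        return self._activators[gene]  # type: ignore[attr-defined]

    def inhibitors_of(self, gene: str) -> tuple[str, ...]:
        return self._inhibitors[gene]  # type: ignore[attr-defined]


def _check_total(network: ConcreteNetwork, state: Mapping[str, int]) -> None:
    missing = [g for g in network.genes if g not in state]
    if missing:
        raise NetworkError(f"state missing genes: {missing}")


def update_state(network: ConcreteNetwork, state: Mapping[str, int]) -> BooleanState:
    """One synchronous step: every gene updates from the same input state."""
    _check_total(network, state)
    nxt: BooleanState = {}
    for g in network.genes:
        acts = network.activators_of(g)
        inhs = network.inhibitors_of(g)
        has_act = bool(acts)
        any_act = any(state[a] for a in acts)
        all_act = all(state[a] for a in acts)
        any_inh = any(state[i] for i in inhs)
        fn = RULES[network.rule_for(g)]
        nxt[g] = int(fn(has_act, any_act, all_act, any_inh, bool(state[g])))
    return nxt


Schedule = Sequence[tuple[ConcreteNetwork, int, int]]


def simulate_trajectory(schedule: Schedule, initial: Mapping[str, int],
                        horizon: int) -> list[BooleanState]:
    """Simulate steps ``1..horizon``; returns states at steps ``0..horizon``.

    ``schedule`` is a list of ``(network, first_step, last_step)`` spans:
    the transition *into* step ``k`` uses the network whose span contains
    ``k``.  Spans must tile ``1..horizon`` contiguously without overlap.
    With ``horizon == 0`` the trajectory is just ``[initial]``.
    """
    if horizon < 0:
        raise NetworkError("horizon must be >= 0")
    per_step: dict[int, ConcreteNetwork] = {}
    for net, first, last in schedule:
        for k in range(first, last + 1):
            if k in per_step:
                raise NetworkError(f"overlapping schedule at step {k}")
            per_step[k] = net
    if horizon > 0:
        missing = [k for k in range(1, horizon + 1) if k not in per_step]
        if missing:
            raise NetworkError(f"schedule gap at steps {missing}")
    traj = [dict(initial)]
    for k in range(1, horizon + 1):
        traj.append(update_state(per_step[k], traj[-1]))
    return traj


def state_matches(partial: Mapping[str, int], total: Mapping[str, int]) -> bool:
    """Does a total state agree with a partial observation?"""
    return all(total[g] == v for g, v in partial.items())


def all_states(genes: Sequence[str]) -> Iterable[BooleanState]:
    """All 2^n total states over ``genes``, in lexicographic bit order."""
    for bits in itertools.product((0, 1), repeat=len(genes)):
        yield dict(zip(genes, bits))


def complete_states(genes: Sequence[str],
                    partial: Mapping[str, int]) -> Iterable[BooleanState]:
    """All total states over ``genes`` consistent with ``partial``."""
    free = [g for g in genes if g not in partial]
    base = {g: int(v) for g, v in partial.items() if g in set(genes)}
    for bits in itertools.product((0, 1), repeat=len(free)):
        s = dict(base)
        s.update(zip(free, bits))
        yield {g: s[g] for g in genes}
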