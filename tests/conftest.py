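"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately re-derive results by brute force (exhaustive
enumeration of concrete networks, initial-state completions and switch
schedules followed by plain simulation) so that the solvers' pruned,
structured searches are checked against an implementation that shares as
little code with them as possible.
"""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from commitnet.boolean import (
    ACTIVATING,
    INHIBITING,
    ConcreteNetwork,
    Interaction,
    update_state,
)
from commitnet.abn import AbstractBooleanNetwork
from commitnet.discretise import ExperimentConstraint
from commitnet.synthetic import GroundTruthSeries, SimulationParams, default_ground_truth


# ------------------------------------------------------------- oracles

def sidak_stepdown_oracle(pvalues: list[float]) -> list[float]:
    """Closed-form Holm-Sidak step-down adjustment.

    Sort ascending; the i-th smallest (0-based) is adjusted to
    ``1 - (1 - p)^(m - i)``; enforce monotonicity by running maximum;
    return in the original order.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        adj = 1.0 - (1.0 - pvalues[idx]) ** (m - rank)
        running = max(running, adj)
        adjusted[idx] = min(1.0, running)
    return adjusted


def enumerate_networks_oracle(abn: AbstractBooleanNetwork):
    """Naive concrete-network enumeration: direct product over pairs."""
    by_pair: dict[tuple[str, str], list[Interaction]] = {}
    for e in abn.possible:
        by_pair.setdefault(e.pair, []).append(e)
    options = []
    for pair in sorted(by_pair):
        group = sorted(by_pair[pair])
        options.append([frozenset()] + [frozenset([e]) for e in group])
    for picks in itertools.product(*options):
        edges = frozenset(abn.definite) | frozenset().union(*picks) \
            if picks else frozenset(abn.definite)
        yield ConcreteNetwork(abn.genes, edges)


def satisfies_oracle(net: ConcreteNetwork, initial: dict,
                     constraint: ExperimentConstraint) -> bool:
    """Plain simulate-and-check, no pruning."""
    traj = [dict(initial)]
    for _ in range(constraint.horizon):
        traj.append(update_state(net, traj[-1]))
    return all(
        all(traj[step][g] == v for g, v in obs.items())
        for step, obs in constraint.observations.items()
    )


def check_consistency_oracle(abn: AbstractBooleanNetwork,
                             constraint: ExperimentConstraint) -> bool:
    """Exhaustive single-ABN SAT decision."""
    partial0 = constraint.observations.get(0, {})
    free = [g for g in abn.genes if g not in partial0]
    for net in enumerate_networks_oracle(abn):
        for bits in itertools.product((0, 1), repeat=len(free)):
            init = {**{g: int(v) for g, v in partial0.items()},
                    **dict(zip(free, bits))}
            init = {g: init[g] for g in abn.genes}
            if satisfies_oracle(net, init, constraint):
                return True
    return False


def solve_switching_oracle(abns, constraint: ExperimentConstraint) -> bool:
    """Exhaustive switching SAT decision over all monotone schedules."""
    horizon = constraint.horizon
    k = len(abns)
    genes = abns[0].genes
    partial0 = constraint.observations.get(0, {})
    free = [g for g in genes if g not in partial0]
    concretes = [list(enumerate_networks_oracle(a)) for a in abns]
    for switches in itertools.combinations_with_replacement(
            range(horizon + 2), k - 1):
        schedule = [sum(1 for t in switches if t <= s)
                    for s in range(horizon + 1)]
        if constraint.mandatory_switch and schedule[-1] == 0:
            continue
        if any(schedule[s] != i
               for s, i in constraint.network_requirements.items()):
            continue
        for combo in itertools.product(*concretes):
            for bits in itertools.product((0, 1), repeat=len(free)):
                init = {**{g: int(v) for g, v in partial0.items()},
                        **dict(zip(free, bits))}
                init = {g: init[g] for g in genes}
                traj = [init]
                for step in range(1, horizon + 1):
                    traj.append(update_state(combo[schedule[step]], traj[-1]))
                if all(all(traj[s][g] == v for g, v in obs.items())
                       for s, obs in constraint.observations.items()):
                    return True
    return False


# ------------------------------------------------- random instance makers

def random_abn(rng: random.Random, max_genes: int = 3,
               max_possible: int = 6) -> AbstractBooleanNetwork:
    n = rng.randint(1, max_genes)
    genes = tuple(f"g{i}" for i in range(n))
    pairs = [(a, b) for a in genes for b in genes]
    definite: set[Interaction] = set()
    possible: set[Interaction] = set()
    for pair in pairs:
        roll = rng.random()
        if roll < 0.25:
            definite.add(Interaction(*pair, rng.choice((ACTIVATING, INHIBITING))))
        elif roll < 0.55 and len(possible) < max_possible:
            if rng.random() < 0.3:
                possible.add(Interaction(*pair, ACTIVATING))
                possible.add(Interaction(*pair, INHIBITING))
            else:
                possible.add(Interaction(*pair, rng.choice((ACTIVATING,
                                                            INHIBITING))))
    return AbstractBooleanNetwork(genes, frozenset(definite),
                                  frozenset(possible))


def random_constraint(rng: random.Random, genes: tuple[str, ...],
                      max_horizon: int = 6,
                      allow_requirements: bool = False,
                      n_abns: int = 1) -> ExperimentConstraint:
    horizon = rng.randint(1, max_horizon)
    observations = {}
    for step in rng.sample(range(horizon + 1), rng.randint(1, horizon + 1)):
        obs = {g: rng.randint(0, 1) for g in genes if rng.random() < 0.6}
        if obs:
            observations[step] = obs
    reqs = {}
    if allow_requirements and n_abns > 1 and rng.random() < 0.5:
        steps = sorted(rng.sample(range(horizon + 1),
                                  rng.randint(1, min(3, horizon + 1))))
        level = 0
        for s in steps:
            level = rng.randint(level, n_abns - 1)
            reqs[s] = level
    return ExperimentConstraint(
        name="random", horizon=horizon, observations=observations,
        network_requirements=reqs,
        mandatory_switch=(n_abns > 1 and rng.random() < 0.3),
    )


# ------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def truth() -> GroundTruthSeries:
    return default_ground_truth()


@pytest.fixture(scope="session")
def noisefree_table(truth):
    from commitnet.synthetic import simulate_perturbation_table
    return simulate_perturbation_table(
        truth, SimulationParams(noise_sd=0.0, seed=0)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230914)
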