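"""Monotonic switching search, path classification, pattern compatibility."""

import itertools
import random

import pytest

from conftest import (
    check_consistency_oracle,
    enumerate_networks_oracle,
    random_abn,
    random_constraint,
    solve_switching_oracle,
)
from commitnet.abn import AbstractBooleanNetwork, check_consistency
from commitnet.boolean import Interaction, all_states, update_state
from commitnet.discretise import ExperimentConstraint
from commitnet.io import verify_witness
from commitnet.switching import (
    SwitchingProblem,
    classify_switch_paths,
    is_pattern_compatible,
    iter_schedules,
    solve_switching,
)


def abn(genes, definite=(), possible=()):
    return AbstractBooleanNetwork(
        tuple(genes),
        frozenset(Interaction(*e) for e in definite),
        frozenset(Interaction(*e) for e in possible),
    )


class TestSchedules:
    def test_all_schedules_monotone_and_requirements_honoured(self):
        problem = SwitchingProblem(
            (abn("A"),) * 4,
            ExperimentConstraint("x", horizon=12,
                                 network_requirements={0: 0, 8: 2}),
        )
        schedules = list(iter_schedules(problem))
        assert schedules
        for s in schedules:
            assert all(a <= b for a, b in zip(s, s[1:]))
            assert s[0] == 0 and s[8] == 2

    def test_mandatory_switch_excludes_constant_zero(self):
        problem = SwitchingProblem(
            (abn("A"),) * 2,
            ExperimentConstraint("x", horizon=4, mandatory_switch=True),
        )
        assert all(max(s) > 0 for s in iter_schedules(problem))


class TestSolveSwitching:
    def test_identical_abns_reduce_to_single_abn_problem(self):
        a = abn("AB", definite=[("A", "A", 1), ("A", "B", 1)])
        c = ExperimentConstraint("x", horizon=4,
                                 observations={0: {"A": 1, "B": 0},
                                               4: {"B": 1}})
        single = check_consistency(a, c)
        sol = solve_switching(SwitchingProblem((a, a, a, a), c))
        assert single.sat and sol is not None
        ok, reason = verify_witness(sol, SwitchingProblem((a, a, a, a), c))
        assert ok, reason

    def test_switching_reaches_states_no_single_network_can(self):
        # stage 1 turns B on from A; stage 2 then turns A off.  The
        # two-phase observation is unreachable under either stage alone.
        n1 = abn("AB", definite=[("A", "A", 1), ("A", "B", 1),
                                 ("B", "B", 1)])
        n2 = abn("AB", definite=[("B", "A", -1), ("B", "B", 1)])
        c = ExperimentConstraint(
            "x", horizon=6,
            observations={0: {"A": 1, "B": 0}, 3: {"A": 1, "B": 1},
                          6: {"A": 0, "B": 1}},
        )
        assert not check_consistency(n1, c).sat
        assert not check_consistency(n2, c).sat
        assert not check_consistency_oracle(n1, c)
        sol = solve_switching(SwitchingProblem((n1, n2), c))
        assert sol is not None
        ok, reason = verify_witness(sol, SwitchingProblem((n1, n2), c))
        assert ok, reason

    def test_status_matches_exhaustive_oracle_on_random_problems(self):
        rng = random.Random(314)
        sat = unsat = 0
        for _ in range(100):
            base = random_abn(rng, max_genes=3, max_possible=4)
            second = random_abn(rng, max_genes=3, max_possible=4)
            second = AbstractBooleanNetwork(
                base.genes,
                frozenset(e for e in second.definite
                          if e.source in base.genes and e.target in base.genes),
                frozenset(e for e in second.possible
                          if e.source in base.genes and e.target in base.genes),
            )
            c = random_constraint(rng, base.genes, max_horizon=5,
                                  allow_requirements=True, n_abns=2)
            problem = SwitchingProblem((base, second), c)
            sol = solve_switching(problem)
            oracle = solve_switching_oracle((base, second), c)
            assert (sol is not None) == oracle
            if sol is not None:
                sat += 1
                ok, reason = verify_witness(sol, problem)
                assert ok, reason
                assert all(a <= b for a, b in
                           zip(sol.schedule, sol.schedule[1:]))
            else:
                unsat += 1
        assert sat > 10 and unsat > 10

    def test_relaxing_mandatory_switch_never_loses_sat(self):
        rng = random.Random(2718)
        for _ in range(40):
            a1 = random_abn(rng, max_genes=2, max_possible=3)
            a2 = random_abn(rng, max_genes=2, max_possible=3)
            a2 = AbstractBooleanNetwork(
                a1.genes,
                frozenset(e for e in a2.definite
                          if e.source in a1.genes and e.target in a1.genes),
                frozenset(e for e in a2.possible
                          if e.source in a1.genes and e.target in a1.genes),
            )
            c = random_constraint(rng, a1.genes, max_horizon=4, n_abns=2)
            strict = ExperimentConstraint("s", horizon=c.horizon,
                                          observations=c.observations,
                                          mandatory_switch=True)
            relaxed = ExperimentConstraint("r", horizon=c.horizon,
                                           observations=c.observations)
            if solve_switching(SwitchingProblem((a1, a2), strict)):
                assert solve_switching(SwitchingProblem((a1, a2), relaxed))


class TestSwitchPaths:
    def test_single_abn_problem_yields_constant_path(self):
        a = abn("A", definite=[("A", "A", 1)])
        c = ExperimentConstraint("x", horizon=3,
                                 observations={0: {"A": 1}, 3: {"A": 1}})
        assert classify_switch_paths(SwitchingProblem((a,), c)) == {(0,)}

    def test_paths_empty_iff_unsat(self):
        a = abn("A")
        c = ExperimentConstraint("x", horizon=3,
                                 observations={0: {"A": 0}, 3: {"A": 1}})
        assert solve_switching(SwitchingProblem((a, a), c)) is None
        assert classify_switch_paths(SwitchingProblem((a, a), c)) == set()


class TestPatternCompatibility:
    def test_fixed_point_of_definite_network_is_compatible(self):
        a = abn("AB", definite=[("A", "A", 1)])
        assert is_pattern_compatible(a, {"A": 1, "B": 0}, horizon=6)

    def test_unreachable_activation_is_incompatible(self):
        # isolated gene with no possible activator: OFF stays OFF, and ON
        # at the horizon requires ON all along — but B must start ON too?
        a = abn("AB", definite=[("A", "B", -1), ("A", "A", 1)])
        assert not is_pattern_compatible(a, {"B": 1, "A": 1}, horizon=3)

    def test_agreement_with_enumeration_oracle(self):
        rng = random.Random(1618)
        agree_true = agree_false = 0
        for _ in range(100):
            a = random_abn(rng, max_genes=3, max_possible=4)
            target = {g: rng.randint(0, 1) for g in a.genes
                      if rng.random() < 0.7}
            horizon = rng.randint(0, 4)
            got = is_pattern_compatible(a, target, horizon)
            oracle = False
            for net in enumerate_networks_oracle(a):
                for init in all_states(a.genes):
                    s = init
                    for _ in range(horizon):
                        s = update_state(net, s)
                    if all(s[g] == v for g, v in target.items()):
                        oracle = True
                        break
                if oracle:
                    break
            assert got == oracle
            agree_true += got
            agree_false += not got
        assert agree_true > 5 and agree_false >= 0
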