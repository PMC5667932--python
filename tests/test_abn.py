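"""ABN counting, enumeration, consistency and interaction classification."""

import math
import random

import pytest

from conftest import (
    check_consistency_oracle,
    enumerate_networks_oracle,
    random_abn,
    random_constraint,
)
from commitnet.abn import (
    DISALLOWED,
    OPTIONAL,
    REQUIRED,
    AbstractBooleanNetwork,
    EnumerationLimitError,
    check_consistency,
    classify_interactions,
    count_concrete_networks,
    enumerate_concrete_networks,
    promote_classified,
    replay_witness,
)
from commitnet.boolean import Interaction, NetworkError
from commitnet.discretise import ExperimentConstraint
from commitnet.io import verify_witness
from commitnet.synthetic import DEFAULT_GENES


def exclusive_abn(genes):
    """Every ordered pair (incl. self) carries an exclusive +/- possibility."""
    possible = frozenset(
        Interaction(a, b, s) for a in genes for b in genes for s in (1, -1)
    )
    return AbstractBooleanNetwork(tuple(genes), frozenset(), possible)


class TestCounting:
    def test_no_possibilities_counts_one(self):
        abn = AbstractBooleanNetwork(("A", "B"), frozenset(
            {Interaction("A", "B", 1)}), frozenset())
        assert count_concrete_networks(abn) == 1

    def test_two_gene_exclusive_pairs_count_81(self):
        abn = exclusive_abn(("A", "B"))
        assert count_concrete_networks(abn) == 3 ** 4 == 81
        nets = list(enumerate_concrete_networks(abn, limit=100))
        assert len(nets) == 81
        assert len({n.interactions for n in nets}) == 81

    def test_six_gene_family_has_magnitude_ten_to_the_17(self):
        abn = exclusive_abn(DEFAULT_GENES)
        count = count_concrete_networks(abn)
        assert count == 3 ** 36
        assert math.floor(math.log10(count)) == 17

    def test_count_matches_enumeration_on_random_abns(self):
        rng = random.Random(7)
        for _ in range(30):
            abn = random_abn(rng)
            nets = list(enumerate_concrete_networks(abn, limit=2 ** 12))
            assert len(nets) == count_concrete_networks(abn)
            assert len({(n.interactions, tuple(sorted(n.rules.items())))
                        for n in nets}) == len(nets)
            oracle = {n.interactions for n in enumerate_networks_oracle(abn)}
            assert {n.interactions for n in nets} == oracle

    def test_rule_choices_multiply_count(self):
        abn = AbstractBooleanNetwork(
            ("A",), frozenset(), frozenset({Interaction("A", "A", 1)}),
            rule_choices={"A": ("default", "activator_override")},
        )
        assert count_concrete_networks(abn) == 4
        assert len(list(enumerate_concrete_networks(abn))) == 4

    def test_limit_refuses_large_enumerations(self):
        abn = exclusive_abn(DEFAULT_GENES)
        with pytest.raises(EnumerationLimitError):
            next(enumerate_concrete_networks(abn, limit=2 ** 20))

    def test_definite_pair_cannot_reappear_as_possible(self):
        with pytest.raises(NetworkError, match="definite"):
            AbstractBooleanNetwork(
                ("A", "B"),
                frozenset({Interaction("A", "B", 1)}),
                frozenset({Interaction("A", "B", -1)}),
            )


class TestConsistency:
    def test_unreachable_on_state_is_unsat(self):
        # no possible incoming activator: an OFF gene can never switch ON
        abn = AbstractBooleanNetwork(("A", "B"), frozenset(
            {Interaction("A", "B", -1)}), frozenset())
        c = ExperimentConstraint("x", horizon=5,
                                 observations={0: {"B": 0}, 5: {"B": 1}})
        assert not check_consistency(abn, c).sat

    def test_definite_self_loop_holds_state(self):
        abn = AbstractBooleanNetwork(("A",), frozenset(
            {Interaction("A", "A", 1)}), frozenset())
        c = ExperimentConstraint("x", horizon=5,
                                 observations={0: {"A": 1}, 5: {"A": 1}})
        res = check_consistency(abn, c)
        assert res.sat and replay_witness(res, c)

    def test_horizon_shorter_than_observation_rejected(self):
        from commitnet.discretise import ConstraintError
        abn = AbstractBooleanNetwork(("A",), frozenset(), frozenset())
        with pytest.raises(ConstraintError, match="horizon"):
            ExperimentConstraint("x", horizon=2, observations={4: {"A": 1}})
        with pytest.raises(NetworkError, match="unknown genes"):
            check_consistency(abn, ExperimentConstraint(
                "x", horizon=2, observations={1: {"Z": 1}}))

    def test_status_matches_bruteforce_oracle_on_random_instances(self):
        rng = random.Random(42)
        agree_sat = agree_unsat = 0
        for _ in range(200):
            abn = random_abn(rng)
            c = random_constraint(rng, abn.genes)
            res = check_consistency(abn, c)
            oracle = check_consistency_oracle(abn, c)
            assert res.sat == oracle
            if res.sat:
                assert replay_witness(res, c)
                ok, reason = verify_witness(res, (abn, c))
                assert ok, reason
                agree_sat += 1
            else:
                agree_unsat += 1
        assert agree_sat > 10 and agree_unsat > 10  # both outcomes exercised

    def test_adding_observations_never_turns_unsat_into_sat(self):
        rng = random.Random(99)
        for _ in range(50):
            abn = random_abn(rng)
            c = random_constraint(rng, abn.genes)
            extra_step = rng.randint(0, c.horizon)
            gene = rng.choice(abn.genes)
            obs = {s: dict(st) for s, st in c.observations.items()}
            obs.setdefault(extra_step, {}).setdefault(gene, rng.randint(0, 1))
            stronger = ExperimentConstraint("x", horizon=c.horizon,
                                            observations=obs)
            weaker = ExperimentConstraint("x", horizon=c.horizon,
                                          observations=c.observations)
            if check_consistency(abn, stronger).sat:
                assert check_consistency(abn, weaker).sat


class TestClassification:
    def two_path_abn(self):
        # B reachable only through the possible edge A->B: that edge is
        # required; the inhibiting alternative is disallowed.
        return AbstractBooleanNetwork(
            ("A", "B"),
            frozenset({Interaction("A", "A", 1)}),
            frozenset({Interaction("A", "B", 1), Interaction("A", "B", -1),
                       Interaction("B", "B", 1)}),
        )

    def test_required_and_disallowed_labels(self):
        c = ExperimentConstraint(
            "x", horizon=3,
            observations={0: {"A": 1, "B": 0}, 3: {"B": 1}})
        labels = classify_interactions(self.two_path_abn(), c)
        assert labels[Interaction("A", "B", 1)] == REQUIRED
        assert labels[Interaction("A", "B", -1)] == DISALLOWED
        assert labels[Interaction("B", "B", 1)] == OPTIONAL

    def test_untouched_interaction_is_optional(self):
        abn = AbstractBooleanNetwork(
            ("A", "B", "C"),
            frozenset({Interaction("A", "A", 1)}),
            frozenset({Interaction("B", "C", 1)}),
        )
        c = ExperimentConstraint("x", horizon=2,
                                 observations={0: {"A": 1}, 2: {"A": 1}})
        labels = classify_interactions(abn, c)
        assert labels[Interaction("B", "C", 1)] == OPTIONAL

    def test_unsat_instance_rejected(self):
        abn = AbstractBooleanNetwork(("A",), frozenset(), frozenset())
        c = ExperimentConstraint("x", horizon=2,
                                 observations={0: {"A": 0}, 2: {"A": 1}})
        with pytest.raises(NetworkError, match="UNSAT"):
            classify_interactions(abn, c)

    def test_labels_match_bruteforce_definition(self):
        """Required = in every consistent solution; disallowed = in none."""
        from conftest import enumerate_networks_oracle, satisfies_oracle
        import itertools
        rng = random.Random(2024)
        checked = 0
        while checked < 60:
            abn = random_abn(rng)
            c = random_constraint(rng, abn.genes)
            if not check_consistency(abn, c).sat or not abn.possible:
                continue
            checked += 1
            labels = classify_interactions(abn, c)
            partial0 = c.observations.get(0, {})
            free = [g for g in abn.genes if g not in partial0]
            consistent = []
            for net in enumerate_networks_oracle(abn):
                for bits in itertools.product((0, 1), repeat=len(free)):
                    init = {**{g: v for g, v in partial0.items()},
                            **dict(zip(free, bits))}
                    init = {g: init[g] for g in abn.genes}
                    if satisfies_oracle(net, init, c):
                        consistent.append(net.interactions)
                        break
            for e in abn.possible:
                present = [e in edges for edges in consistent]
                expected = (REQUIRED if all(present)
                            else DISALLOWED if not any(present)
                            else OPTIONAL)
                assert labels[e] == expected, (e, labels[e], expected)

    def test_promotion_preserves_sat_status(self):
        rng = random.Random(5)
        done = 0
        while done < 30:
            abn = random_abn(rng)
            c = random_constraint(rng, abn.genes)
            if not check_consistency(abn, c).sat:
                continue
            done += 1
            labels = classify_interactions(abn, c)
            promoted = promote_classified(abn, labels)
            assert check_consistency(promoted, c).sat
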