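"""A synthetic six-gene, four-stage commitment model.

This module ships a constructed stand-in for the study's discretised
observation vectors and stage networks (which are not distributed with the
package): a family of four stage ABNs (N0, N4, N8, N12) over the six
commitment phosphatases, together with untreated, PKCi and TSA
constraints, engineered so that the qualitative reasoning chain of the
commitment analysis holds and is exhaustively checkable:

* no single network — neither any stage ABN alone nor any concrete network
  drawn from the pooled ABN of all stage interactions — satisfies the
  untreated trajectory (UNSAT);
* monotonic switching through the stage networks does satisfy it (SAT),
  and the untreated constraint carries a mandatory switch;
* the PKCi-arrested 12 hr pattern is reachable without ever leaving N0
  (stem-state arrest);
* the TSA constraint forces the system out of N0 and admits exactly the
  visited paths N0 -> N4 -> N8 and N0 -> N8;
* neither drug pattern is compatible with the 12 hr network N12.

The stage dynamics are simple relay motifs under the default regulation
rule: each stage's network hands the activity token to the next marker
gene (DUSP10 -> DUSP6 -> PPTC7 -> PPP3CA) and shuts the previous one off.
"""

from __future__ import annotations

from .abn import AbstractBooleanNetwork
from .boolean import Interaction
from .discretise import ExperimentConstraint
from .switching import SwitchingProblem
from .synthetic import DEFAULT_GENES

GENES = DEFAULT_GENES

# stage marker genes: the single ON gene of each stage's target state
_STEM = "DUSP10"      # stem state marker (0 hr)
_COMMIT = "DUSP6"     # commitment marker (4 hr)
_EARLY = "PPTC7"      # early differentiation marker (8 hr)
_LATE = "PPP3CA"      # differentiated marker (12 hr)


def _state(on: tuple[str, ...]) -> dict[str, int]:
    return {g: int(g in on) for g in GENES}


#: Full discretised states expected on the untreated trajectory.
STATE_0HR = _state((_STEM,))
STATE_4HR = _state((_COMMIT,))
STATE_8HR = _state((_EARLY,))
STATE_12HR = _state((_LATE,))

#: Partial drug-arrest patterns at 12 hr.
PKCI_PATTERN_12HR = dict(STATE_0HR)                     # full stem pattern
TSA_PATTERN_12HR = {_EARLY: 1, _COMMIT: 0, _LATE: 0}    # stalled before N12


def build_stage_abns() -> tuple[AbstractBooleanNetwork, ...]:
    """The four stage ABNs N0, N4, N8, N12."""
    n0 = AbstractBooleanNetwork(
        GENES,
        definite=frozenset({Interaction(_STEM, _STEM, 1)}),
        possible=frozenset(),
    )
    # N4: the stem marker hands over to the commitment marker, which is
    # self-sustaining and silences the stem marker.  The hand-over edge is
    # itself only a possibility (either sign), and one further activator
    # of the commitment marker is optional.
    n4 = AbstractBooleanNetwork(
        GENES,
        definite=frozenset({
            Interaction(_COMMIT, _COMMIT, 1),
            Interaction(_COMMIT, _STEM, -1),
        }),
        possible=frozenset({
            Interaction(_STEM, _COMMIT, 1),
            Interaction(_STEM, _COMMIT, -1),
            Interaction("PTPN1", _COMMIT, 1),
        }),
    )
    # N8: relay from the commitment marker to the early-differentiation
    # marker; the stem marker can also feed it directly (the short-cut the
    # TSA analysis exercises).
    n8 = AbstractBooleanNetwork(
        GENES,
        definite=frozenset({
            Interaction(_COMMIT, _EARLY, 1),
            Interaction(_STEM, _EARLY, 1),
            Interaction(_EARLY, _EARLY, 1),
            Interaction(_EARLY, _COMMIT, -1),
        }),
        possible=frozenset(),
    )
    # N12: relay into the differentiated state; the stem marker, if still
    # on, also triggers it, which makes lingering stem patterns
    # incompatible with this network.
    n12 = AbstractBooleanNetwork(
        GENES,
        definite=frozenset({
            Interaction(_EARLY, _LATE, 1),
            Interaction(_STEM, _LATE, 1),
            Interaction(_LATE, _LATE, 1),
            Interaction(_LATE, _EARLY, -1),
        }),
        possible=frozenset(),
    )
    return (n0, n4, n8, n12)


def combined_single_abn() -> AbstractBooleanNetwork:
    """All stage interactions pooled as possibilities in one ABN.

    The single-network test asks whether any fixed topology drawn from the
    union of every stage's interactions can satisfy the untreated
    trajectory on its own.  Opposite signs of one pair collapse into an
    exclusive choice; the family stays small enough (3 * 2^12 networks)
    for exhaustive search.
    """
    edges: dict[tuple[str, str], set[Interaction]] = {}
    for stage in build_stage_abns():
        for e in stage.definite | stage.possible:
            edges.setdefault(e.pair, set()).add(e)
    possible = frozenset(e for group in edges.values() for e in group)
    return AbstractBooleanNetwork(GENES, frozenset(), possible)


def untreated_constraint() -> ExperimentConstraint:
    """Suspension-induced differentiation: full states at 0/4/8/12 hr."""
    return ExperimentConstraint(
        name="untreated",
        horizon=12,
        observations={0: STATE_0HR, 4: STATE_4HR, 8: STATE_8HR, 12: STATE_12HR},
        network_requirements={0: 0},
        mandatory_switch=True,
    )


def pkci_constraint() -> ExperimentConstraint:
    """PKC inhibition: the 12 hr pattern is still the stem pattern."""
    return ExperimentConstraint(
        name="PKCi",
        horizon=12,
        observations={0: STATE_0HR, 12: PKCI_PATTERN_12HR},
        network_requirements={0: 0},
    )


def tsa_constraint() -> ExperimentConstraint:
    """TSA treatment: committed-then-stalled pattern at 12 hr."""
    return ExperimentConstraint(
        name="TSA",
        horizon=12,
        observations={0: STATE_0HR, 12: TSA_PATTERN_12HR},
        network_requirements={0: 0},
    )


def untreated_problem() -> SwitchingProblem:
    return SwitchingProblem(build_stage_abns(), untreated_constraint())


def pkci_problem() -> SwitchingProblem:
    return SwitchingProblem(build_stage_abns(), pkci_constraint())


def tsa_problem() -> SwitchingProblem:
    return SwitchingProblem(build_stage_abns(), tsa_constraint())
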