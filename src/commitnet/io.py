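"""Readers/writers for networks, ABNs, constraints and tables; witness checks.

Formats
-------
* expression tables: TSV with header ``gene time_hr perturbation replicate
  rel_expr``; SILAC tables: TSV ``site_id protein d_phospho_log2
  d_total_log2``.
* networks: Cytoscape SIF (``source<TAB>activates|inhibits<TAB>target``),
  JSON, or GraphML (via networkx, with sign/weight edge attributes).
* ABNs and constraints: JSON.

:func:`verify_witness` independently replays any solver output through the
simulator and is the acceptance gate for all SAT results.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .abn import AbstractBooleanNetwork, SatResult
from .boolean import (
    ConcreteNetwork,
    Interaction,
    NetworkError,
    SIGN_WORDS,
    WORD_SIGNS,
    simulate_trajectory,
    state_matches,
)
from .discretise import ExperimentConstraint
from .switching import SwitchingProblem, SwitchSolution
from .synthetic import EXPRESSION_COLUMNS, SILAC_COLUMNS


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------- tables

def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df["rel_expr"] <= 0).any():
        raise FormatError(f"{path}: rel_expr must be strictly positive")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(EXPRESSION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_silac_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SILAC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_silac_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in df.columns if c in SILAC_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- networks

def write_sif(network: ConcreteNetwork | Iterable[Interaction],
              path: str | Path) -> None:
    edges = (network.interactions if isinstance(network, ConcreteNetwork)
             else network)
    lines = [f"{e.source}\t{SIGN_WORDS[e.sign]}\t{e.target}"
             for e in sorted(edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sif(path: str | Path,
             genes: tuple[str, ...] | None = None) -> ConcreteNetwork:
    interactions = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated "
                              f"fields, got {len(parts)}")
        source, word, target = parts
        if word not in WORD_SIGNS:
            raise FormatError(f"{path}:{lineno}: unknown sign token {word!r}")
        interactions.add(Interaction(source, target, WORD_SIGNS[word]))
    if genes is None:
        genes = tuple(sorted({g for e in interactions
                              for g in (e.source, e.target)}))
    return ConcreteNetwork(genes, frozenset(interactions))


def network_to_dict(network: ConcreteNetwork) -> dict:
    return {
        "genes": list(network.genes),
        "interactions": [
            {"source": e.source, "target": e.target, "sign": e.sign}
            for e in sorted(network.interactions)
        ],
        "rules": dict(network.rules),
    }


def network_from_dict(d: Mapping) -> ConcreteNetwork:
    return ConcreteNetwork(
        tuple(d["genes"]),
        frozenset(Interaction(e["source"], e["target"], int(e["sign"]))
                  for e in d.get("interactions", [])),
        dict(d.get("rules", {})),
    )


def write_network(network: ConcreteNetwork, path: str | Path,
                  fmt: str | None = None) -> None:
    fmt = fmt or _guess_format(path)
    if fmt == "sif":
        write_sif(network, path)
    elif fmt == "json":
        Path(path).write_text(json.dumps(network_to_dict(network), indent=2))
    elif fmt == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(network.genes)
        for e in sorted(network.interactions):
            g.add_edge(e.source, e.target, sign=e.sign,
                       interaction=SIGN_WORDS[e.sign])
        nx.write_graphml(g, path)
    else:
        raise FormatError(f"unrecognised network format {fmt!r}")


def read_network(path: str | Path, fmt: str | None = None) -> ConcreteNetwork:
    fmt = fmt or _guess_format(path)
    if fmt == "sif":
        return read_sif(path)
    if fmt == "json":
        return network_from_dict(json.loads(Path(path).read_text()))
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return ConcreteNetwork(
            tuple(sorted(g.nodes)),
            frozenset(Interaction(u, v, int(d["sign"]))
                      for u, v, d in g.edges(data=True)),
        )
    raise FormatError(f"unrecognised network format {fmt!r}")


def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"sif": "sif", "json": "json", "graphml": "graphml",
            "xml": "graphml"}.get(suffix, suffix)


# -------------------------------------------------------------------- ABNs

def abn_to_dict(abn: AbstractBooleanNetwork) -> dict:
    def edges(es: Iterable[Interaction]) -> list[dict]:
        return [{"source": e.source, "target": e.target, "sign": e.sign}
                for e in sorted(es)]

    return {
        "genes": list(abn.genes),
        "definite": edges(abn.definite),
        "possible": edges(abn.possible),
        "rule_choices": {g: list(c) for g, c in abn.rule_choices.items()},
    }


def abn_from_dict(d: Mapping) -> AbstractBooleanNetwork:
    def edges(key: str) -> frozenset[Interaction]:
        return frozenset(Interaction(e["source"], e["target"], int(e["sign"]))
                         for e in d.get(key, []))

    return AbstractBooleanNetwork(
        tuple(d["genes"]), edges("definite"), edges("possible"),
        {g: tuple(c) for g, c in d.get("rule_choices", {}).items()},
    )


def write_abn(abn: AbstractBooleanNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(abn_to_dict(abn), indent=2))


def read_abn(path: str | Path) -> AbstractBooleanNetwork:
    return abn_from_dict(json.loads(Path(path).read_text()))


def write_constraint(constraint: ExperimentConstraint, path: str | Path) -> None:
    Path(path).write_text(json.dumps(constraint.to_dict(), indent=2))


def read_constraint(path: str | Path) -> ExperimentConstraint:
    return ExperimentConstraint.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------- witness

def verify_witness(
    solution: SatResult | SwitchSolution,
    problem: SwitchingProblem | tuple[AbstractBooleanNetwork, ExperimentConstraint],
) -> tuple[bool, str]:
    """Replay a claimed SAT witness; returns (ok, reason).

    For a single-ABN :class:`SatResult` the schedule is the constant
    network; for a :class:`SwitchSolution` the schedule, the per-stage
    concrete choices and all network-at-step requirements are checked.
    The trajectory is re-simulated from the witness's initial state and
    every observation compared; the first violation is reported.
    """
    if isinstance(problem, SwitchingProblem):
        constraint = problem.constraint
    else:
        _, constraint = problem

    if isinstance(solution, SatResult):
        # single-ABN witness: constant network, no switching policy to check
        if not solution.sat or solution.network is None:
            return False, "not a SAT result"
        schedule = [(solution.network, 1, constraint.horizon)]
        per_step_index = None
        initial = solution.initial
        claimed = list(solution.trajectory or ())
    else:
        sched = solution.schedule
        if len(sched) != constraint.horizon + 1:
            return False, "schedule length does not match horizon"
        if any(a > b for a, b in zip(sched, sched[1:])):
            return False, "schedule is not monotone non-decreasing"
        try:
            schedule = [(solution.networks[sched[k]], k, k)
                        for k in range(1, constraint.horizon + 1)]
        except KeyError as exc:
            return False, f"no concrete network for stage {exc}"
        per_step_index = list(sched)
        initial = solution.initial
        claimed = list(solution.trajectory)

    if per_step_index is not None:
        for step, idx in constraint.network_requirements.items():
            if per_step_index[step] != idx:
                return False, f"network requirement violated at step {step}"
        if constraint.mandatory_switch and max(per_step_index) == 0:
            return False, "mandatory switch not performed"

    try:
        traj = simulate_trajectory(schedule, initial, constraint.horizon)
    except NetworkError as exc:
        return False, f"replay failed: {exc}"
    if claimed and claimed != traj:
        return False, "claimed trajectory does not replay"
    for step in sorted(constraint.observations):
        if not state_matches(constraint.observations[step], traj[step]):
            return False, f"observation violated at step {step}"
    return True, "ok"
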