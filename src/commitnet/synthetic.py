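"""Synthetic study inputs with known ground truth.

Generates the three kinds of tables the pipeline consumes, so every
downstream stage is testable without the study's wet-lab data:

* knockdown RT-qPCR-like time courses (relative expression vs. a
  housekeeping reference, replicate-level, log-normal noise),
* drug-treatment expression profiles (per-gene log2 shifts on top of the
  control baseline), and
* SILAC phospho-site tables with a controlled fraction of dephosphorylated
  sites and of protein-abundance-confounded sites.

The generative model for knockdowns is deliberately one-step: silencing
gene *i* scales *i* itself by the knockdown efficiency and shifts each
direct target *j* of a ground-truth edge *i -> j* (sign *s*, strength
*beta* in log2 units) by ``-s * beta``; no transitive propagation, so the
inference ground truth is unambiguous.  Noise is Gaussian on the log2
scale (log-normal on the linear scale), the standard qPCR error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .discretise import CONTROL, TIME_POINTS

#: The six commitment-associated phosphatases.
DEFAULT_GENES = ("DUSP6", "PPTC7", "PTPN1", "PTPN13", "PPP3CA", "DUSP10")

EXPRESSION_COLUMNS = ("gene", "time_hr", "perturbation", "replicate", "rel_expr")
SILAC_COLUMNS = ("site_id", "protein", "d_phospho_log2", "d_total_log2")


class SimulationError(ValueError):
    """Raised for invalid ground truth or simulation parameters."""


@dataclass(frozen=True, order=True)
class SignedEdge:
    """A ground-truth regulatory edge with log2-scale effect strength."""

    source: str
    target: str
    sign: int
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise SimulationError(f"sign must be +1/-1, got {self.sign!r}")
        if not np.isfinite(self.strength) or self.strength < 0:
            raise SimulationError("strength must be finite and >= 0")


@dataclass(frozen=True)
class GroundTruthSeries:
    """Per-time-point signed networks plus baseline expression profiles.

    ``networks`` maps each time point to the set of edges active there;
    ``baselines`` maps ``(gene, time_hr)`` to baseline log2 relative
    expression (missing entries default to 0, i.e. equal to the
    housekeeping reference).
    """

    genes: tuple[str, ...] = DEFAULT_GENES
    networks: Mapping[int, frozenset[SignedEdge]] = field(default_factory=dict)
    baselines: Mapping[tuple[str, int], float] = field(default_factory=dict)
    times: tuple[int, ...] = TIME_POINTS

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        nets = {int(t): frozenset(self.networks.get(t, frozenset()))
                for t in self.times}
        for t, edges in nets.items():
            for e in edges:
                if e.source not in gene_set or e.target not in gene_set:
                    raise SimulationError(
                        f"edge endpoint outside gene list at {t} hr: {e}"
                    )
        object.__setattr__(self, "networks", nets)
        for (g, t), b in self.baselines.items():
            if g not in gene_set:
                raise SimulationError(f"baseline for unknown gene {g!r}")
            if not np.isfinite(b):
                raise SimulationError("baselines must be finite")

    def baseline(self, gene: str, time_hr: int) -> float:
        return float(self.baselines.get((gene, time_hr), 0.0))

    def edges_at(self, time_hr: int) -> frozenset[SignedEdge]:
        return self.networks[time_hr]


@dataclass(frozen=True)
class SimulationParams:
    """Knockdown efficiency, measurement noise and replication."""

    knockdown_efficiency: float = 0.2  # residual fraction of target mRNA
    noise_sd: float = 0.2              # Gaussian sd on the log2 scale
    n_replicates: int = 3              # independent transfections
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.knockdown_efficiency < 1:
            raise SimulationError("knockdown_efficiency must be in (0, 1)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")


def default_ground_truth() -> GroundTruthSeries:
    """An eight-edge signed network over the six phosphatases.

    A fixed synthetic truth (no self-edges, one sign per ordered pair)
    used as the standard recovery benchmark; the same edge set is active
    at every time point so each per-time inference sees the full network.
    Baselines sketch the qualitative expression kinetics of the system
    (the five pro-commitment phosphatases peak at 4 hr and decline, the
    antagonist rises late).
    """
    edges = frozenset({
        SignedEdge("DUSP6", "PTPN1", +1),
        SignedEdge("DUSP6", "DUSP10", -1),
        SignedEdge("PPTC7", "PPP3CA", -1),
        SignedEdge("PTPN1", "DUSP10", +1),
        SignedEdge("PTPN13", "DUSP6", +1),
        SignedEdge("PPP3CA", "DUSP6", +1),
        SignedEdge("DUSP10", "PTPN13", -1),
        SignedEdge("PPP3CA", "PTPN13", +1),
    })
    profiles = {
        "DUSP6": (0.0, 1.5, 0.5, -0.5),
        "PPTC7": (0.0, 1.0, -0.5, -1.0),
        "PTPN1": (0.0, 0.8, -0.3, -0.8),
        "PTPN13": (0.0, 0.5, -0.5, -1.0),
        "PPP3CA": (0.0, 0.7, -0.4, -0.9),
        "DUSP10": (0.0, -0.5, 0.5, 1.0),
    }
    baselines = {(g, t): v for g, prof in profiles.items()
                 for t, v in zip(TIME_POINTS, prof)}
    return GroundTruthSeries(
        networks={t: edges for t in TIME_POINTS}, baselines=baselines
    )


def _finalise(rows: list[dict], noise_sd: float,
              rng: np.random.Generator) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(EXPRESSION_COLUMNS[:-1]) + ["_log2"])
    if noise_sd > 0:
        df["_log2"] = df["_log2"] + rng.normal(0.0, noise_sd, size=len(df))
    df["rel_expr"] = np.power(2.0, df.pop("_log2"))
    return df[list(EXPRESSION_COLUMNS)]


def simulate_perturbation_table(
    truth: GroundTruthSeries,
    params: SimulationParams,
    perturbations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate a replicate-level knockdown/overexpression time course.

    Rows cover the control series plus, by default, ``kd:<gene>`` for every
    gene; ``perturbations`` may select a subset or add ``oe:<gene>``
    entries (modelled as the sign-flipped knockdown shift).  Deterministic
    given ``params.seed``.
    """
    if perturbations is None:
        perturbations = [f"kd:{g}" for g in truth.genes]
    kd_shift = float(np.log2(params.knockdown_efficiency))
    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []

    def emit(pert: str, direction: int, focal: str | None) -> None:
        for t in truth.times:
            shifts = {g: 0.0 for g in truth.genes}
            if focal is not None:
                if focal not in set(truth.genes):
                    raise SimulationError(f"unknown gene in perturbation: {focal}")
                shifts[focal] += direction * kd_shift
                for e in truth.edges_at(t):
                    if e.source == focal:
                        shifts[e.target] += -direction * e.sign * e.strength
            for g in truth.genes:
                for r in range(params.n_replicates):
                    rows.append({
                        "gene": g, "time_hr": t, "perturbation": pert,
                        "replicate": r,
                        "_log2": truth.baseline(g, t) + shifts[g],
                    })

    emit(CONTROL, 0, None)
    for pert in perturbations:
        if pert.startswith("kd:"):
            emit(pert, +1, pert[3:])
        elif pert.startswith("oe:"):
            emit(pert, -1, pert[3:])
        else:
            raise SimulationError(f"unrecognised perturbation {pert!r}")
    return _finalise(rows, params.noise_sd, rng)


def simulate_drug_profiles(
    truth: GroundTruthSeries,
    drug_shifts: Mapping[tuple[str, str], float],
    params: SimulationParams,
    drugs: Iterable[str] = ("PKCi", "TSA"),
) -> pd.DataFrame:
    """Simulate drug-treatment profiles: baseline plus per-gene log2 shift.

    ``drug_shifts`` maps ``(drug, gene)`` to a log2 shift and must cover
    every gene for every requested drug.  A control series is always
    included.  Deterministic given ``params.seed``.
    """
    drugs = tuple(drugs)
    for d in drugs:
        missing = [g for g in truth.genes if (d, g) not in drug_shifts]
        if missing:
            raise SimulationError(f"missing shift for drug {d!r}, genes {missing}")
    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []
    for pert, shift_of in [(CONTROL, None)] + [(f"drug:{d}", d) for d in drugs]:
        for t in truth.times:
            for g in truth.genes:
                shift = 0.0 if shift_of is None else float(drug_shifts[(shift_of, g)])
                for r in range(params.n_replicates):
                    rows.append({
                        "gene": g, "time_hr": t, "perturbation": pert,
                        "replicate": r,
                        "_log2": truth.baseline(g, t) + shift,
                    })
    return _finalise(rows, params.noise_sd, rng)


def simulate_silac_table(
    n_sites: int,
    frac_dephospho: float = 2.0 / 3.0,
    frac_confounded: float = 0.05,
    effect_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a SILAC phospho-site table (one time point vs 0 hr).

    Each site is independently *confounded* with probability
    ``frac_confounded``: its phospho ratio sits in the constant band
    (|d_phospho| <= 0.1) while total protein rises by > +0.5 log2, the
    situation the ranking's exclusion rule removes.  Every other site is a
    changed site with |d_phospho| = 0.3 + |N(0, effect_sd)| (safely above
    typical change thresholds), negative with probability
    ``frac_dephospho``, and an uncorrelated small total-protein change.
    The ground-truth ``confounded`` flag is included for benchmarking and
    is ignored by the analysis functions.
    """
    if n_sites < 1:
        raise SimulationError("n_sites must be >= 1")
    for name, frac in [("frac_dephospho", frac_dephospho),
                       ("frac_confounded", frac_confounded)]:
        if not 0.0 <= frac <= 1.0:
            raise SimulationError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    confounded = rng.random(n_sites) < frac_confounded
    n_conf = int(confounded.sum())
    n_changed = n_sites - n_conf

    d_phospho = np.empty(n_sites)
    d_total = np.empty(n_sites)
    d_phospho[confounded] = rng.uniform(-0.1, 0.1, size=n_conf)
    d_total[confounded] = 0.6 + np.abs(rng.normal(0.0, 0.2, size=n_conf))
    magnitude = 0.3 + np.abs(rng.normal(0.0, effect_sd, size=n_changed))
    sign = np.where(rng.random(n_changed) < frac_dephospho, -1.0, 1.0)
    d_phospho[~confounded] = sign * magnitude
    d_total[~confounded] = rng.normal(0.0, 0.15, size=n_changed)

    return pd.DataFrame({
        "site_id": [f"site{i:05d}" for i in range(n_sites)],
        "protein": [f"PROT{i // 3:04d}" for i in range(n_sites)],
        "d_phospho_log2": d_phospho,
        "d_total_log2": d_total,
        "confounded": confounded,
    })
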