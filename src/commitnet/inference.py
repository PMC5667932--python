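"""Signed mechanistic network inference from knockdown time courses.

For each measured (target) gene, the knockdown series are analysed on the
log2 scale with a two-way ANOVA (factors: perturbation and time, with
interaction).  The effect of each single knockdown at each time point is a
cell-mean contrast against the control condition at the same time, using
the pooled within-cell residual variance of the ANOVA; the resulting
p-values are adjusted by the Holm-Sidak step-down procedure within the
target gene's comparison family (all knockdown x time contrasts for that
gene).

An edge ``i -> j`` at time *t* is called iff the adjusted p-value is below
alpha; its sign is read off the fold-change direction (knocking down an
activator *lowers* its target, so a negative log2 fold-change means an
activating edge) and its weight is the inverse adjusted p-value,
``w_ij = 1 / p_ij``.  Self-edges are not inferable from knockdown data
(silencing *i* trivially lowers *i*) and are never called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .boolean import Interaction
from .discretise import CONTROL

#: Smallest representable p-value; zero-residual contrasts are clamped here
#: so that weights 1/p stay finite.
P_FLOOR = float(np.finfo(float).tiny)

_VAR_FLOOR = 1e-24


class InferenceError(ValueError):
    """Raised for degenerate designs or ambiguous edge calls."""


@dataclass(frozen=True)
class EdgeCall:
    """A significant knockdown effect, interpreted as a signed edge."""

    source: str
    target: str
    time_hr: int
    p_value: float
    sign: int
    log2fc: float
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise InferenceError("p-value must be in (0, 1]")
        if self.sign not in (1, -1):
            raise InferenceError("sign must be +1/-1")
        object.__setattr__(self, "weight", 1.0 / self.p_value)


@dataclass(frozen=True)
class MechanisticNetwork:
    """Significant signed, weighted edges at one time point."""

    time_hr: int
    edges: tuple[EdgeCall, ...]
    node_log2fc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(e.source, e.target) for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise InferenceError("duplicate (source, target) pairs at one time")

    def to_interactions(self) -> frozenset[Interaction]:
        return frozenset(Interaction(e.source, e.target, e.sign)
                         for e in self.edges)


def _knockdown_of(pert: str) -> str | None:
    return pert[3:] if pert.startswith("kd:") else None


def fit_knockdown_anova(
    table: pd.DataFrame,
    target_gene: str,
    control: str = CONTROL,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way ANOVA contrasts of each knockdown vs control, per time point.

    Returns one row per (knockdown, time_hr) with columns ``log2fc`` (cell
    mean difference vs control on the log2 scale), ``t``, ``df``,
    ``p_raw`` and ``p_adj`` (Holm-Sidak within this target's family).
    Knockdowns of the target itself are excluded.
    """
    sub = table[(table["gene"] == target_gene)].copy()
    keep = [control] + sorted(
        p for p in sub["perturbation"].unique()
        if _knockdown_of(p) not in (None, target_gene)
    )
    if control not in set(sub["perturbation"]):
        raise InferenceError(f"no control ({control!r}) rows for {target_gene!r}")
    sub = sub[sub["perturbation"].isin(keep)]
    sub["_log2"] = np.log2(sub["rel_expr"])

    cells = sub.groupby(["perturbation", "time_hr"])["_log2"].agg(
        ["mean", "var", "count"]
    )
    if (cells["count"] < 2).any():
        bad = cells.index[cells["count"] < 2].tolist()
        raise InferenceError(f"fewer than 2 replicates in cells {bad}")
    # pooled within-cell variance == residual MS of the interaction ANOVA
    ss_within = (cells["var"] * (cells["count"] - 1)).sum()
    df_resid = int(cells["count"].sum() - len(cells))
    mse = ss_within / df_resid

    rows = []
    for (pert, t), cell in cells.iterrows():
        kd = _knockdown_of(pert)
        if kd is None:
            continue
        if (control, t) not in cells.index:
            raise InferenceError(f"missing control stratum at {t} hr")
        ctrl = cells.loc[(control, t)]
        diff = cell["mean"] - ctrl["mean"]
        if mse < _VAR_FLOOR:
            # noise-free data: any non-zero difference is unequivocal
            t_stat = np.inf if abs(diff) > 1e-9 else 0.0
            p_raw = P_FLOOR if abs(diff) > 1e-9 else 1.0
        else:
            se = np.sqrt(mse * (1.0 / cell["count"] + 1.0 / ctrl["count"]))
            t_stat = diff / se
            p_raw = 2.0 * stats.t.sf(abs(t_stat), df_resid)
        rows.append({
            "target": target_gene, "knockdown": kd, "time_hr": int(t),
            "log2fc": float(diff), "t": float(t_stat), "df": df_resid,
            "p_raw": float(p_raw),
        })
    out = pd.DataFrame(rows).sort_values(["knockdown", "time_hr"],
                                         ignore_index=True)
    if out.empty:
        raise InferenceError(f"no knockdown strata for target {target_gene!r}")
    with np.errstate(divide="ignore"):  # p_raw == 1 is legitimate input
        adjusted = multipletests(out["p_raw"], alpha=alpha,
                                 method="holm-sidak")[1]
    out["p_adj"] = np.clip(adjusted, P_FLOOR, 1.0)
    return out


def fit_all_targets(table: pd.DataFrame, control: str = CONTROL,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Run :func:`fit_knockdown_anova` for every measured gene."""
    genes = sorted(table["gene"].unique())
    return pd.concat(
        [fit_knockdown_anova(table, g, control=control, alpha=alpha)
         for g in genes],
        ignore_index=True,
    )


def compute_node_foldchanges(
    table: pd.DataFrame, control: str = CONTROL
) -> dict[tuple[str, int], float]:
    """Mean log2 fold-change of each gene vs its own 0 hr control level."""
    sub = table[table["perturbation"] == control]
    if sub.empty:
        raise InferenceError("no control rows")
    means = np.log2(sub["rel_expr"]).groupby(
        [sub["gene"], sub["time_hr"]]
    ).mean()
    out: dict[tuple[str, int], float] = {}
    for (g, t), m in means.items():
        if (g, 0) not in means.index:
            raise InferenceError(f"missing 0 hr data for gene {g!r}")
        out[(g, int(t))] = float(m - means[(g, 0)])
    return out


def call_edges(
    results: pd.DataFrame,
    node_log2fc: Mapping[tuple[str, int], float] | None = None,
    alpha: float = 0.05,
) -> dict[int, MechanisticNetwork]:
    """Threshold adjusted p-values into per-time mechanistic networks.

    ``results`` is the output of :func:`fit_all_targets` (or a
    concatenation of per-target fits).  An edge is emitted iff
    ``p_adj < alpha``; sign +1 iff the knockdown lowered the target.
    A significant contrast with a fold-change of exactly zero has no
    defined sign and raises.
    """
    if not 0.0 < alpha < 1.0:
        raise InferenceError("alpha must be in (0, 1)")
    node_log2fc = node_log2fc or {}
    networks: dict[int, MechanisticNetwork] = {}
    for t, grp in results.groupby("time_hr"):
        edges = []
        for row in grp.itertuples():
            if row.p_adj >= alpha:
                continue
            if row.log2fc == 0.0:
                raise InferenceError(
                    f"significant effect with zero fold-change: "
                    f"{row.knockdown} -> {row.target} at {t} hr"
                )
            edges.append(EdgeCall(
                source=row.knockdown, target=row.target, time_hr=int(t),
                p_value=float(row.p_adj),
                sign=1 if row.log2fc < 0 else -1,
                log2fc=float(row.log2fc),
            ))
        networks[int(t)] = MechanisticNetwork(
            time_hr=int(t),
            edges=tuple(sorted(edges, key=lambda e: (e.source, e.target))),
            node_log2fc={g: fc for (g, tt), fc in node_log2fc.items()
                         if tt == int(t)},
        )
    return networks


def infer_networks(table: pd.DataFrame, control: str = CONTROL,
                   alpha: float = 0.05) -> dict[int, MechanisticNetwork]:
    """Full pipeline: ANOVA contrasts, Holm-Sidak, edge calls, node FCs."""
    results = fit_all_targets(table, control=control, alpha=alpha)
    fcs = compute_node_foldchanges(table, control=control)
    return call_edges(results, node_log2fc=fcs, alpha=alpha)
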