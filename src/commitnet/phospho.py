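"""SILAC phospho-site summarisation and ranking.

Works on tables of per-site log2 SILAC ratios: ``d_phospho_log2`` for the
phosphopeptide (time *t* vs 0 hr) and ``d_total_log2`` for the parent
protein's total abundance.  The *discordance* ``d_phospho - d_total`` (the
log2 ratio of ratios) isolates phosphorylation-level regulation from bulk
protein-abundance change.

The ranking targets dephosphorylation events: sites are ordered by
ascending phospho log2 change (largest decrease first), after excluding
sites whose phosphorylation remained constant while total protein rose by
more than +0.5 log2 — for such sites an unchanged phospho ratio actually
means stoichiometric dephosphorylation is confounded with synthesis, so
they cannot be ranked on the phospho ratio alone.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("site_id", "d_phospho_log2", "d_total_log2")


class PhosphoError(ValueError):
    """Raised for empty or malformed site tables."""


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise PhosphoError("empty site table")
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise PhosphoError(f"missing columns: {missing}")
    for c in ("d_phospho_log2", "d_total_log2"):
        if not records[c].map(lambda v: v == v and abs(v) != float("inf")).all():
            raise PhosphoError(f"non-finite values in {c}")
    return records


def dephospho_fraction(records: pd.DataFrame,
                       change_threshold: float = 0.2) -> float:
    """Fraction of changed sites that are dephosphorylated.

    A site counts as changed iff ``|d_phospho_log2| > change_threshold``;
    among those, the returned fraction has a negative phospho ratio.
    """
    records = _validate(records)
    changed = records[records["d_phospho_log2"].abs() > change_threshold]
    if len(changed) == 0:
        raise PhosphoError("no changed sites at this threshold")
    return float((changed["d_phospho_log2"] < 0).mean())


def exclusion_mask(records: pd.DataFrame,
                   constant_band: float = 0.2,
                   total_increase_threshold: float = 0.5) -> pd.Series:
    """True where the confound-exclusion rule fires.

    A site is excluded iff its phosphorylation remained constant
    (``|d_phospho_log2| <= constant_band``) while total protein abundance
    increased by more than ``total_increase_threshold`` in log2.
    """
    records = _validate(records)
    return (records["d_phospho_log2"].abs() <= constant_band) & (
        records["d_total_log2"] > total_increase_threshold
    )


def filter_and_rank_sites(
    records: pd.DataFrame,
    k: int = 15,
    constant_band: float = 0.2,
    total_increase_threshold: float = 0.5,
) -> pd.DataFrame:
    """Top-k most-dephosphorylated sites after the confound exclusion.

    Surviving sites are ranked by ascending ``d_phospho_log2`` (ties broken
    by ``site_id`` so the output is invariant to input row order) and
    annotated with ``discordance`` (phospho change minus total change) and
    ``rank`` (1 = largest decrease).  If fewer than ``k`` sites survive,
    all of them are returned and the frame's ``attrs['truncated']`` flag is
    set.
    """
    if k < 1:
        raise PhosphoError("k must be >= 1")
    records = _validate(records)
    survivors = records[~exclusion_mask(records, constant_band,
                                        total_increase_threshold)].copy()
    survivors["discordance"] = (
        survivors["d_phospho_log2"] - survivors["d_total_log2"]
    )
    survivors = survivors.sort_values(
        ["d_phospho_log2", "site_id"], ignore_index=True
    )
    truncated = len(survivors) < k
    top = survivors.head(k).copy()
    top["rank"] = range(1, len(top) + 1)
    top.attrs["truncated"] = truncated
    return top
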