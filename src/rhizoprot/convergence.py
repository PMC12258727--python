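"""Orthogroup-level fold-change aggregation and cross-species convergence.

Protein log2 fold changes are averaged within each (orthogroup, species
group) to a single orthogroup-level fold change; convergence is then read
off Spearman correlations between species groups, exclusive-class
co-occurrence counts of differentially abundant orthogroups, and sharing
fractions.  A species group is a species label, optionally suffixed by
sampling year (e.g. ``Tripsacum_2019``), so within-species year contrasts
enter the comparison on the same footing as between-species contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import UNASSIGNED, OrthogroupTable

__all__ = [
    "aggregate_orthogroup_lfc",
    "pairwise_spearman",
    "spearman_matrix",
    "cooccurrence",
    "CooccurrenceSummary",
    "top_n_up",
]


def aggregate_orthogroup_lfc(results_by_group: dict[str, pd.DataFrame],
                             og: OrthogroupTable) -> pd.DataFrame:
    """One row per (orthogroup, species_group): arithmetic-mean log2fc over
    that group's member proteins, member count, and any-member DAP flags.

    Proteins without an orthogroup assignment and proteins without a fold
    change (untested) are excluded.
    """
    frames = []
    for group, res in results_by_group.items():
        sub = res[res["log2fc"].notna()].copy()
        sub["orthogroup_id"] = [og.orthogroup_of(p) for p in sub["protein_id"]]
        sub = sub[sub["orthogroup_id"] != UNASSIGNED]
        if sub.empty:
            continue
        agg = sub.groupby("orthogroup_id").agg(
            mean_log2fc=("log2fc", "mean"),
            n_proteins=("log2fc", "size"),
            any_dap_up=("call", lambda c: bool((c == "up").any())),
            any_dap_down=("call", lambda c: bool((c == "down").any())),
        ).reset_index()
        agg.insert(1, "species_group", group)
        frames.append(agg)
    if not frames:
        return pd.DataFrame(columns=["orthogroup_id", "species_group", "mean_log2fc",
                                     "n_proteins", "any_dap_up", "any_dap_down"])
    return pd.concat(frames, ignore_index=True)


def pairwise_spearman(fc: pd.DataFrame, group_a: str, group_b: str) -> tuple[float, int]:
    """Spearman rho (average-rank ties) between orthogroup-level fold changes
    of two species groups, over orthogroups quantified in both."""
    a = fc[fc["species_group"] == group_a].set_index("orthogroup_id")["mean_log2fc"]
    b = fc[fc["species_group"] == group_b].set_index("orthogroup_id")["mean_log2fc"]
    shared = a.index.intersection(b.index)
    n = len(shared)
    if n < 3:
        raise ValueError(
            f"only {n} orthogroups shared between {group_a!r} and {group_b!r}; "
            "Spearman correlation undefined"
        )
    rho = stats.spearmanr(a.loc[shared].to_numpy(), b.loc[shared].to_numpy()).statistic
    return float(rho), n


def spearman_matrix(fc: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise Spearman rhos across all species groups."""
    groups = sorted(fc["species_group"].unique())
    mat = pd.DataFrame(np.eye(len(groups)), index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        rho, _ = pairwise_spearman(fc, a, b)
        mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


@dataclass
class CooccurrenceSummary:
    """Exclusive-class co-occurrence of DAP orthogroups in one direction.

    ``class_counts`` maps a sorted tuple of species groups (the exact set of
    groups in which an orthogroup is differentially abundant in the given
    direction) to the number of such orthogroups.  Counts over the exclusive
    classes sum to ``total``.
    """

    direction: str
    class_counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    total: int = 0
    frac_shared_ge1: float = 0.0  # shared with at least one other group
    frac_shared_ge2: float = 0.0  # shared with at least two other groups

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"direction": self.direction, "species_groups": "+".join(cls),
             "n_groups": len(cls), "n_orthogroups": n}
            for cls, n in sorted(self.class_counts.items(),
                                 key=lambda kv: (-len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows)


def cooccurrence(fc: pd.DataFrame, direction: str) -> CooccurrenceSummary:
    """Count DAP orthogroups by the exact subset of species groups calling
    them in ``direction`` ('up' or 'down'), with sharing fractions."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    flag = "any_dap_up" if direction == "up" else "any_dap_down"
    hit = fc[fc[flag]]
    classes: dict[str, set[str]] = {}
    for og_id, grp in zip(hit["orthogroup_id"], hit["species_group"]):
        classes.setdefault(og_id, set()).add(grp)
    counts: dict[tuple[str, ...], int] = {}
    for groups in classes.values():
        key = tuple(sorted(groups))
        counts[key] = counts.get(key, 0) + 1
    total = len(classes)
    ge1 = sum(1 for g in classes.values() if len(g) >= 2)
    ge2 = sum(1 for g in classes.values() if len(g) >= 3)
    return CooccurrenceSummary(
        direction=direction,
        class_counts=counts,
        total=total,
        frac_shared_ge1=ge1 / total if total else 0.0,
        frac_shared_ge2=ge2 / total if total else 0.0,
    )


def top_n_up(results: pd.DataFrame, n: int = 50) -> list[str]:
    """The n proteins with call=up and the largest log2fc; ties broken by
    smaller p_adj, then lexicographic protein_id.  Shorter if fewer exist."""
    ups = results[results["call"] == "up"].copy()
    ups = ups.sort_values(["log2fc", "p_adj", "protein_id"],
                          ascending=[False, True, True], kind="mergesort")
    return ups["protein_id"].head(n).tolist()
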