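"""Cold-related functional categorization and cross-species homogeneity test.

Differentially abundant proteins are binned into nine cold-tolerance
categories (membrane stability, chaperones, osmoregulation, ROS
scavenging, lipid metabolism, antifreeze/cell wall, cold signalling,
cytoskeleton, other) by a keyword/GO-term map applied in priority order.
The map ships as an editable TSV so the curation is reproducible and
auditable; it is a documented approximation of manual curation, not an
attempt to recover any particular curator's judgment.  Category-count
tables across species groups are compared with a plain Pearson chi-square
test of homogeneity (no continuity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy import stats

__all__ = ["CategoryMap", "OTHER_CATEGORY", "assign_categories", "count_table",
           "chi_square_homogeneity"]

OTHER_CATEGORY = "other/uncategorized"


@dataclass
class CategoryMap:
    """Ordered (category, keyword-list) pairs; first match in priority order
    wins, no match falls through to :data:`OTHER_CATEGORY`.

    Keywords are matched case-insensitively as substrings of the protein
    description concatenated with its GO terms.
    """

    entries: list[tuple[str, list[str]]]

    @property
    def categories(self) -> list[str]:
        return [name for name, _ in self.entries] + [OTHER_CATEGORY]

    @classmethod
    def from_file(cls, path) -> "CategoryMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["category", "keywords"]:
            raise ValueError(f"{path}: expected columns 'category' and 'keywords'")
        entries = [(row["category"], [k for k in row["keywords"].split("|") if k])
                   for _, row in df.iterrows()]
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "CategoryMap":
        ref = resources.files("rhizoprot.data").joinpath("categories_default.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def to_file(self, path) -> None:
        pd.DataFrame(
            [(name, "|".join(kws)) for name, kws in self.entries],
            columns=["category", "keywords"],
        ).to_csv(path, sep="\t", index=False)


def assign_categories(annotations: pd.DataFrame,
                      cmap: CategoryMap | None = None) -> pd.Series:
    """Map each protein to its first matching category.

    ``annotations`` needs columns ``protein_id`` and ``description``; an
    optional ``go_terms`` column (semicolon- or comma-separated GO IDs) is
    searched too.  Returns a Series indexed by protein_id.
    """
    cmap = cmap or CategoryMap.default()
    has_go = "go_terms" in annotations.columns
    out = {}
    for _, row in annotations.iterrows():
        text = str(row.get("description", "") or "")
        if has_go:
            text += " " + str(row.get("go_terms", "") or "")
        low = text.lower()
        assigned = OTHER_CATEGORY
        for name, keywords in cmap.entries:
            if any(k.lower() in low for k in keywords):
                assigned = name
                break
        out[row["protein_id"]] = assigned
    return pd.Series(out, name="category")


def count_table(assignments: pd.Series, group_of: pd.Series,
                cmap: CategoryMap | None = None,
                drop_other: bool = False) -> pd.DataFrame:
    """Species-group x category count table.

    ``group_of`` maps protein_id -> species group.  All map categories
    appear as columns (zero-filled); ``drop_other`` removes the fall-through
    column, as done when testing only the nine focused categories.
    """
    cmap = cmap or CategoryMap.default()
    df = pd.DataFrame({"category": assignments, "group": group_of.loc[assignments.index]})
    tab = pd.crosstab(df["group"], df["category"])
    for cat in cmap.categories:
        if cat not in tab.columns:
            tab[cat] = 0
    tab = tab[cmap.categories]
    if drop_other:
        tab = tab.drop(columns=[OTHER_CATEGORY])
    return tab


def chi_square_homogeneity(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on a group x category table.

    Returns ``(chi2, df, p)`` with df = (r-1)(c-1).  Columns or rows with a
    zero margin are rejected; a warning is emitted when more than 20% of
    expected counts fall below 5.
    """
    tab = pd.DataFrame(table).astype(float)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("table needs at least 2 rows and 2 columns")
    if (tab.sum(axis=1) == 0).any():
        bad = tab.index[tab.sum(axis=1) == 0][0]
        raise ValueError(f"row margin of {bad!r} is zero")
    if (tab.sum(axis=0) == 0).any():
        bad = tab.columns[tab.sum(axis=0) == 0][0]
        raise ValueError(f"column margin of {bad!r} is zero")
    chi2, p, df, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    small = (expected < 5).mean()
    if small > 0.20:
        warnings.warn(
            f"{small:.0%} of expected counts are below 5; the chi-square "
            "approximation may be poor", stacklevel=2)
    return float(chi2), int(df), float(p)
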