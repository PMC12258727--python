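"""Cross-reference-proteome reassignment by tiered tie-breaking.

When samples were originally searched against a mismatched reference
proteome, each originally-assigned protein is re-homed to its best-matching
protein in the correct proteome using aggregated peptide evidence: candidate
targets are ranked by (1) number of distinct peptides mapped, then (2) sum
of alignment bitscores, then (3) median percent identity, with a final
(4) lexicographic fallback so the output is a total order.  Protein-level
intensity rows are then re-keyed to the chosen targets, preserving the
original normalized intensities (rows colliding on one target are summed).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix, PeptideHit

__all__ = ["ReassignmentResult", "map_peptides_exact", "reassign",
           "regenerate_summaries", "UNASSIGNED_TARGET"]

UNASSIGNED_TARGET = "unassigned"


@dataclass(frozen=True)
class ReassignmentResult:
    """Winner of the tie-break ladder for one source protein.

    ``decided_at_tier`` is the first ladder level at which the winner was
    uniquely ranked (tier 4 = lexicographic fallback); single-candidate
    sources decide at tier 1.
    """

    source_protein: str
    chosen_target: str
    n_distinct_peptides: int
    bitscore_sum: float
    median_pident: float
    decided_at_tier: int


def map_peptides_exact(peptides: dict[str, str] | list[str],
                       proteome) -> list[PeptideHit]:
    """Exact-substring peptide mapper (internal stand-in for an external
    aligner): one hit per occurrence of a peptide in a target protein, with
    pident = 100 and bitscore = 2 * peptide length.  Leu and Ile distinct.

    ``peptides`` is either a mapping peptide_id -> sequence or a plain list
    of sequences (then each sequence is its own id).
    """
    if not isinstance(peptides, dict):
        peptides = {p: p for p in peptides}
    hits: list[PeptideHit] = []
    for pep_id, seq in peptides.items():
        L = len(seq)
        for prot in proteome:
            start = prot.sequence.find(seq)
            while start != -1:
                hits.append(PeptideHit(
                    peptide_id=pep_id, source_protein=pep_id,
                    target_protein=prot.protein_id,
                    pident=100.0, length=L, mismatch=0, gapopen=0,
                    qstart=1, qend=L, sstart=start + 1, send=start + L,
                    evalue=0.0, bitscore=2.0 * L,
                ))
                start = prot.sequence.find(seq, start + 1)
    return hits


def _candidate_stats(hits: list[PeptideHit]) -> dict[str, tuple[int, float, float]]:
    by_target: dict[str, list[PeptideHit]] = {}
    for h in hits:
        by_target.setdefault(h.target_protein, []).append(h)
    return {
        t: (len({h.peptide_id for h in hs}),
            sum(h.bitscore for h in hs),
            float(median(h.pident for h in hs)))
        for t, hs in by_target.items()
    }


def _decide_tier(stats: dict[str, tuple[int, float, float]], winner: str) -> int:
    """First ladder level at which the winner is uniquely ranked."""
    others = [s for t, s in stats.items() if t != winner]
    if not others:
        return 1
    w = stats[winner]
    for tier in (1, 2, 3):
        rivals = [s for s in others if s[:tier - 1] == w[:tier - 1]]
        if all(s[tier - 1] < w[tier - 1] for s in rivals):
            return tier
    return 4


def reassign(hits: list[PeptideHit],
             min_pident: float | None = None,
             max_evalue: float | None = None) -> list[ReassignmentResult]:
    """Choose the best target per source protein by the tie-break ladder.

    A pure function of the hit multiset (input order irrelevant).  Optional
    ``min_pident`` / ``max_evalue`` pre-filters are off by default.
    """
    if min_pident is not None:
        hits = [h for h in hits if h.pident >= min_pident]
    if max_evalue is not None:
        hits = [h for h in hits if h.evalue <= max_evalue]
    by_source: dict[str, list[PeptideHit]] = {}
    for h in hits:
        by_source.setdefault(h.source_protein, []).append(h)
    results = []
    for src in sorted(by_source):
        stats = _candidate_stats(by_source[src])
        winner = min(stats, key=lambda t: (-stats[t][0], -stats[t][1], -stats[t][2], t))
        n, bsum, mpi = stats[winner]
        results.append(ReassignmentResult(
            source_protein=src, chosen_target=winner,
            n_distinct_peptides=n, bitscore_sum=bsum, median_pident=mpi,
            decided_at_tier=_decide_tier(stats, winner),
        ))
    return results


def regenerate_summaries(matrix: AbundanceMatrix,
                         reassignments: list[ReassignmentResult],
                         ) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Re-key intensity rows from source proteins to chosen targets.

    Sources sharing a target have their rows summed per sample (missing +
    value = value; all-missing stays missing), so total intensity is
    conserved.  Rows whose source has no reassignment record are returned in
    the second (unassigned) matrix, never silently dropped.
    """
    target_of = {r.source_protein: r.chosen_target for r in reassignments
                 if r.chosen_target != UNASSIGNED_TARGET}
    assigned_rows = [p for p in matrix.protein_ids if p in target_of]
    lost_rows = [p for p in matrix.protein_ids if p not in target_of]
    assigned = matrix.data.loc[assigned_rows]
    grouped = assigned.groupby(
        pd.Index([target_of[p] for p in assigned_rows], name="protein_id")
    ).sum(min_count=1)
    lost = matrix.data.loc[lost_rows]
    return (AbundanceMatrix(data=grouped, species=matrix.species),
            AbundanceMatrix(data=lost, species=matrix.species))
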