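"""Dure 11-mer motif detection and hydropathy profiling for LEA3 proteins.

Group-3 late embryogenesis abundant (LEA3) proteins carry a repeating
11-residue motif: apolar residues at motif positions 1, 2, 5 and 9 form the
hydrophobic face of an amphipathic alpha-helix, while positions 6-8 carry a
charged "+ - +" or "+ Q +" arrangement.  This module detects such motifs
under a configurable grammar, characterizes consecutive-motif architecture
(runs and inter-motif insertions), computes sliding-window hydropathy
profiles (Kyte-Doolittle by default, window 11 = the motif length), and
quantitatively compares amphipathic patterns between aligned orthologs
(mean paired difference "delta hydro" and Pearson pattern correlation).

All residue coordinates in this module are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "MotifRule", "DEFAULT_RULE", "LENIENT_POS1_RULE", "MotifChain",
    "window_matches", "detect_motifs", "HydropathyProfile", "hydropathy",
    "HYDROPATHY_SCALES", "position_class_stats", "compare_profiles",
    "align_pair",
]

MOTIF_LEN = 11

# Kyte & Doolittle (1982) hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Eisenberg consensus hydrophobicity scale.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}

HYDROPATHY_SCALES = {"kyte_doolittle": KYTE_DOOLITTLE, "eisenberg": EISENBERG}


@dataclass(frozen=True)
class MotifRule:
    """Grammar of the 11-mer motif.

    Positions 1, 2, 5, 9 must be apolar; positions 6-8 must read
    (+, -, +) or (+, Q, +).  Up to ``mismatch_allowance`` violations are
    tolerated, but only at ``allowed_mismatch_positions``.  The apolar set
    includes T (the grammar admits threonine in place of alanine) but is an
    interpretation and fully configurable; histidine is excluded from the
    charge sets by default (ambiguous protonation).
    """

    apolar_set: frozenset = frozenset("ATVLIMF")
    pos_charge_set: frozenset = frozenset("KR")
    neg_charge_set: frozenset = frozenset("DE")
    q_set: frozenset = frozenset("Q")
    mismatch_allowance: int = 0
    allowed_mismatch_positions: frozenset = frozenset({1})


DEFAULT_RULE = MotifRule()

#: Preset tolerating one deviation at motif position 1, for sequences whose
#: first repeat deviates from the strict grammar there.
LENIENT_POS1_RULE = MotifRule(mismatch_allowance=1,
                               allowed_mismatch_positions=frozenset({1}))

_APOLAR_POSITIONS = (1, 2, 5, 9)


def _violations(window: str, rule: MotifRule) -> set[int] | None:
    """Motif positions (1-based) violating the grammar, or None if the
    window cannot match under any middle pattern even with mismatches."""
    bad_apolar = {p for p in _APOLAR_POSITIONS if window[p - 1] not in rule.apolar_set}
    best: set[int] | None = None
    for mid_sets in ((rule.pos_charge_set, rule.neg_charge_set, rule.pos_charge_set),
                     (rule.pos_charge_set, rule.q_set, rule.pos_charge_set)):
        bad_mid = {p for p, s in zip((6, 7, 8), mid_sets) if window[p - 1] not in s}
        cand = bad_apolar | bad_mid
        if best is None or len(cand) < len(best):
            best = cand
    return best


def window_matches(window: str, rule: MotifRule = DEFAULT_RULE) -> bool:
    """Does an 11-residue window satisfy the motif grammar?"""
    if len(window) != MOTIF_LEN:
        raise ValueError(f"window must have length {MOTIF_LEN}, got {len(window)}")
    bad = _violations(window, rule)
    return (len(bad) <= rule.mismatch_allowance
            and bad <= rule.allowed_mismatch_positions)


@dataclass
class MotifChain:
    """Detected motifs on one protein: 1-based start positions (strictly
    increasing, non-overlapping), residue gaps between consecutive motifs,
    and the length of the longest run of back-to-back (gap 0) motifs."""

    protein_id: str = ""
    starts: list[int] = field(default_factory=list)
    gaps: list[int] = field(default_factory=list)
    max_consecutive_run: int = 0

    @property
    def n_motifs(self) -> int:
        return len(self.starts)


def detect_motifs(sequence: str, rule: MotifRule = DEFAULT_RULE,
                  protein_id: str = "") -> MotifChain:
    """Greedy left-to-right non-overlapping scan for 11-mer motifs.

    Every matching window is reported subject to non-overlap: after a match
    at position i the scan resumes at i + 11.  Sequences shorter than 11
    residues yield an empty chain with a warning.
    """
    seq = sequence.upper()
    if len(seq) < MOTIF_LEN:
        warnings.warn(f"sequence {protein_id!r} shorter than {MOTIF_LEN} residues; "
                      "no motif possible", stacklevel=2)
        return MotifChain(protein_id=protein_id)
    starts: list[int] = []
    i = 0
    while i <= len(seq) - MOTIF_LEN:
        if window_matches(seq[i:i + MOTIF_LEN], rule):
            starts.append(i + 1)  # 1-based
            i += MOTIF_LEN
        else:
            i += 1
    gaps = [starts[j + 1] - (starts[j] + MOTIF_LEN) for j in range(len(starts) - 1)]
    run = best = 1 if starts else 0
    for g in gaps:
        run = run + 1 if g == 0 else 1
        best = max(best, run)
    return MotifChain(protein_id=protein_id, starts=starts, gaps=gaps,
                      max_consecutive_run=best)


@dataclass
class HydropathyProfile:
    """Sliding-window mean hydropathy, aligned to 1-based residue positions.

    ``scores[i-1]`` is the mean scale value over the window centred on
    residue i; positions where the window does not fit are NaN.
    """

    protein_id: str
    scale_name: str
    window: int
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


def hydropathy(sequence: str, scale: str = "kyte_doolittle",
               window: int = 11, on_unknown: str = "error",
               protein_id: str = "") -> HydropathyProfile:
    """Windowed-mean hydropathy profile of a sequence.

    ``window`` must be odd and >= 1 (window 1 returns raw per-residue scale
    values).  Residues absent from the scale (e.g. X) raise by default;
    ``on_unknown='skip'`` leaves NaN at every window containing one.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    table = HYDROPATHY_SCALES.get(scale)
    if table is None:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(HYDROPATHY_SCALES)}")
    seq = sequence.upper()
    raw = np.empty(len(seq))
    for i, aa in enumerate(seq):
        if aa in table:
            raw[i] = table[aa]
        elif on_unknown == "skip":
            raw[i] = np.nan
        else:
            raise ValueError(f"residue {aa!r} at position {i + 1} absent from scale {scale!r}")
    half = (window - 1) // 2
    scores = np.full(len(seq), np.nan)
    for c in range(half, len(seq) - half):
        scores[c] = raw[c - half:c + half + 1].mean()
    return HydropathyProfile(protein_id=protein_id, scale_name=scale,
                             window=window, scores=scores)


def position_class_stats(profile: HydropathyProfile,
                         region: tuple[int, int],
                         frame_start: int,
                         positions=range(1, MOTIF_LEN + 1)) -> dict[int, float]:
    """Mean profile score per motif position class within a region.

    ``frame_start`` is the residue where motif position 1 falls; residue r
    belongs to class ((r - frame_start) mod 11) + 1.  Classes with no
    defined scores in the region map to NaN.
    """
    lo, hi = region
    if lo < 1 or hi > len(profile) or lo > hi:
        raise ValueError(f"region {region} outside profile support 1..{len(profile)}")
    out: dict[int, float] = {}
    for p in positions:
        vals = [profile.scores[r - 1] for r in range(lo, hi + 1)
                if (r - frame_start) % MOTIF_LEN == (p - 1)
                and not np.isnan(profile.scores[r - 1])]
        out[p] = float(np.mean(vals)) if vals else float("nan")
    return out


def compare_profiles(a: HydropathyProfile, b: HydropathyProfile,
                     pairing: dict[int, int],
                     region: tuple[int, int]) -> tuple[float, float]:
    """Mean paired score difference and Pearson pattern correlation.

    ``pairing`` maps 1-based positions of ``a`` to positions of ``b`` (from
    a pairwise alignment; gapped columns absent).  ``region`` is given in
    ``a``'s coordinates.  Returns ``(delta_hydro, pattern_r)`` where
    delta_hydro = mean(score_a - score_b) over paired in-region positions.
    """
    lo, hi = region
    xs, ys = [], []
    for pa, pb in pairing.items():
        if lo <= pa <= hi:
            sa, sb = a.scores[pa - 1], b.scores[pb - 1]
            if not (np.isnan(sa) or np.isnan(sb)):
                xs.append(sa)
                ys.append(sb)
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} paired positions in region {region}; "
                         "pattern correlation undefined")
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    if np.ptp(xs_a) == 0 or np.ptp(ys_a) == 0:
        raise ValueError("zero variance in a profile over the region; "
                         "correlation undefined")
    delta = float(np.mean(xs_a - ys_a))
    r = float(np.corrcoef(xs_a, ys_a)[0, 1])
    return delta, r


def align_pair(a: str, b: str) -> dict[int, int]:
    """Global pairwise alignment of two sequences; returns the 1-based
    position pairing of aligned (ungapped) columns.

    Needleman-Wunsch with BLOSUM62; a gap of length L costs 10 + (L - 1).
    Of the optimal alignments the aligner's first is used (deterministic).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    pairing: dict[int, int] = {}
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            pairing[a0 + off + 1] = b0 + off + 1
    return pairing
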