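"""Synthetic inputs with the statistical and sequence structure the
analysis assumes, so every downstream stage is testable without downloads.

Three generators cover the pipeline's input space:

* :func:`gen_abundance_dataset` - multi-species log-normal protein
  intensities (log2-scale Gaussian baselines) with planted seasonal
  effects, additive per-batch offsets, orthogroup structure with shared and
  species-specific regulation, and injected missingness;
* :func:`gen_motif_proteome` - protein sequences carrying planted runs of
  valid 11-mer motifs (optionally split by a motif-free insertion), with
  motif-free filler built from residues outside the grammar's apolar and
  charge alphabets so negatives are negatives by construction;
* :func:`gen_peptide_scenario` - peptide hit tables with known true source
  proteins and decoys engineered to exercise each tier of the reassignment
  tie-break ladder.

Every generator is a pure function of its config and seed: the same seed
yields identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix, OrthogroupTable, PeptideHit, ProteinRecord

__all__ = ["SimulationConfig", "GroundTruth", "gen_abundance_dataset",
           "gen_motif_proteome", "gen_peptide_scenario", "gen_annotations"]


@dataclass
class SimulationConfig:
    """Study-design parameters for the abundance simulator.

    Defaults emulate a five-species two-season TMT design: log-normal
    intensities (log2 baselines N(20, 2)), planted |log2FC| of 3 for
    regulated proteins, within-group noise SD 0.3 on the log2 scale, and
    4 replicates per season.
    """

    n_species: int = 5
    n_orthogroups: int = 400
    proteins_per_orthogroup: int | tuple[int, int] = 1
    n_replicates_per_season: int = 4
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_size_log2: float = 3.0
    shared_frac: float = 0.2
    noise_sd_log2: float = 0.3
    batch_sd_log2: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    baseline_mean_log2: float = 20.0
    baseline_sd_log2: float = 2.0
    n_batches: int = 2
    year: int = 2022
    n_unassigned_per_species: int = 0

    def validate(self) -> None:
        for name in ("frac_up", "frac_down", "shared_frac", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be non-negative")
        if self.n_replicates_per_season < 2:
            raise ValueError("need at least 2 replicates per season to test")
        if self.n_species < 1 or self.n_orthogroups < 1:
            raise ValueError("n_species and n_orthogroups must be positive")


@dataclass
class GroundTruth:
    """Planted truth for test assertions; JSON-serializable via ``asdict``.

    Populated fields depend on the generator: the abundance generator fills
    ``true_effect`` (species -> protein -> signed log2 effect) and
    ``og_status`` (species -> orthogroup -> +1/-1/0) plus
    ``shared_orthogroups``; the motif generator fills ``motif_starts`` and
    ``motif_gaps`` (1-based, per protein); the peptide generator fills
    ``true_target`` and ``scenario_tier`` (0 = no decoy competition).
    """

    true_effect: dict = field(default_factory=dict)
    og_status: dict = field(default_factory=dict)
    shared_orthogroups: list = field(default_factory=list)
    motif_starts: dict = field(default_factory=dict)
    motif_gaps: dict = field(default_factory=dict)
    true_target: dict = field(default_factory=dict)
    scenario_tier: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _species_name(i: int) -> str:
    return f"Species{i + 1:02d}"


def gen_abundance_dataset(config: SimulationConfig):
    """Simulate per-species abundance matrices with planted effects.

    Returns ``(matrices, meta, orthogroups, truth)`` where ``matrices`` maps
    species name -> :class:`AbundanceMatrix`, ``meta`` is one metadata table
    covering all samples, ``orthogroups`` the generated partition, and
    ``truth`` the planted ground truth.

    Intensity model (log2 scale): baseline_p + effect * I[winter] +
    batch_offset + noise, exponentiated to intensities.  A ``shared_frac``
    subset of regulated orthogroups is regulated with the same sign in
    every species; the remainder are regulated in one species each.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = [_species_name(i) for i in range(config.n_species)]
    og_ids = [f"OG{j:05d}" for j in range(config.n_orthogroups)]

    # --- regulation plan at the orthogroup level
    frac_reg = config.frac_up + config.frac_down
    n_reg = int(round(frac_reg * config.n_orthogroups))
    reg_ogs = list(rng.choice(og_ids, size=n_reg, replace=False))
    n_shared = int(round(config.shared_frac * n_reg))
    shared = reg_ogs[:n_shared]
    specific = reg_ogs[n_shared:]
    p_up = config.frac_up / frac_reg if frac_reg > 0 else 0.0
    signs = {og: (1 if rng.random() < p_up else -1) for og in reg_ogs}

    og_status: dict[str, dict[str, int]] = {sp: {og: 0 for og in og_ids} for sp in species}
    for og in shared:
        for sp in species:
            og_status[sp][og] = signs[og]
    for og in specific:
        sp = species[rng.integers(config.n_species)]
        og_status[sp][og] = signs[og]

    # --- proteins per orthogroup per species
    members: dict[str, set[str]] = {og: set() for og in og_ids}
    protein_ids: dict[str, list[str]] = {}
    protein_og: dict[str, dict[str, str]] = {}
    for sp in species:
        prots, owner = [], {}
        for og in og_ids:
            if isinstance(config.proteins_per_orthogroup, tuple):
                lo, hi = config.proteins_per_orthogroup
                k = int(rng.integers(lo, hi + 1))
            else:
                k = config.proteins_per_orthogroup
            for m in range(k):
                pid = f"{sp}_{og}_p{m + 1}"
                prots.append(pid)
                owner[pid] = og
                members[og].add(pid)
        for u in range(config.n_unassigned_per_species):
            prots.append(f"{sp}_orphan_p{u + 1}")
        protein_ids[sp] = prots
        protein_og[sp] = owner
    orthogroups = OrthogroupTable(members=members, species_names=species)

    # --- samples + intensities
    nrep = config.n_replicates_per_season
    meta_rows = []
    matrices: dict[str, AbundanceMatrix] = {}
    true_effect: dict[str, dict[str, float]] = {}
    for sp in species:
        samples, winter_flags, batches = [], [], []
        for season, tag in (("winter", "w"), ("summer", "s")):
            for r in range(nrep):
                sid = f"{sp}_{tag}{r + 1}"
                samples.append(sid)
                winter_flags.append(season == "winter")
                batches.append(f"b{r % config.n_batches + 1}")
                meta_rows.append({"sample_id": sid, "species": sp, "season": season,
                                  "year": config.year, "batch": batches[-1]})
        winter = np.array(winter_flags)
        batch_offset_of = {f"b{b + 1}": rng.normal(0.0, config.batch_sd_log2)
                           for b in range(config.n_batches)}
        offsets = np.array([batch_offset_of[b] for b in batches])

        prots = protein_ids[sp]
        effects = np.zeros(len(prots))
        for i, pid in enumerate(prots):
            og = protein_og[sp].get(pid)
            if og is not None and og_status[sp][og] != 0:
                effects[i] = og_status[sp][og] * config.effect_size_log2
        baselines = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2,
                               size=len(prots))
        noise = rng.normal(0.0, config.noise_sd_log2, size=(len(prots), len(samples)))
        log2 = (baselines[:, None] + effects[:, None] * winter[None, :]
                + offsets[None, :] + noise)
        values = np.exp2(log2)
        if config.missing_rate > 0:
            mask = rng.random(values.shape) < config.missing_rate
            values = np.where(mask, np.nan, values)
        matrices[sp] = AbundanceMatrix(
            data=pd.DataFrame(values, index=prots, columns=samples), species=sp)
        true_effect[sp] = dict(zip(prots, effects.tolist()))

    meta = pd.DataFrame(meta_rows)
    truth = GroundTruth(true_effect=true_effect, og_status=og_status,
                        shared_orthogroups=list(shared))
    return matrices, meta, orthogroups, truth


# ---------------------------------------------------------------------------
# Motif-bearing proteomes

_APOLAR = "ATVLIMF"
_POS = "KR"
_NEG = "DE"
#: Filler residues outside every grammar alphabet: any window with its first
#: position on a filler residue fails the apolar constraint, so filler
#: stretches are motif-free by construction.
_FILLER = "GSNP"


def _random_motif(rng: np.random.Generator) -> str:
    m = list(rng.choice(list(_FILLER), size=11))
    for p in (1, 2, 5, 9):
        m[p - 1] = rng.choice(list(_APOLAR))
    m[5] = rng.choice(list(_POS))
    m[6] = rng.choice(list(_NEG + "Q"))
    m[7] = rng.choice(list(_POS))
    return "".join(m)


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_FILLER), size=n)) if n > 0 else ""


def gen_motif_proteome(n_proteins: int, n_with_chain: int, chain_length: int,
                       insertion_len: int = 0, seed: int = 0,
                       flank: int = 10):
    """Plant runs of valid 11-mer motifs in otherwise motif-free sequences.

    The first ``n_with_chain`` proteins carry ``chain_length`` motifs; with
    ``insertion_len > 0`` one insertion of that many motif-free residues is
    placed between two consecutive motifs (after the first half of the
    chain), splitting the run.  Remaining proteins are motif-free filler.
    Returns ``(records, truth)`` with planted 1-based starts and gaps.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    if not 0 <= n_with_chain <= n_proteins:
        raise ValueError("need 0 <= n_with_chain <= n_proteins")
    rng = np.random.default_rng(seed)
    records, truth = [], GroundTruth()
    insert_after = max(1, chain_length // 2)  # motif index preceding the insertion
    for i in range(n_proteins):
        pid = f"synth{i + 1:04d}"
        if i < n_with_chain:
            parts, starts, gaps = [], [], []
            pos = flank + 1
            parts.append(_filler(rng, flank))
            for j in range(chain_length):
                if j > 0:
                    gap = insertion_len if (insertion_len > 0 and j == insert_after) else 0
                    if gap:
                        parts.append(_filler(rng, gap))
                        pos += gap
                    gaps.append(gap)
                parts.append(_random_motif(rng))
                starts.append(pos)
                pos += 11
            parts.append(_filler(rng, flank))
            seq = "".join(parts)
            truth.motif_starts[pid] = starts
            truth.motif_gaps[pid] = gaps
        else:
            seq = _filler(rng, 60)
            truth.motif_starts[pid] = []
            truth.motif_gaps[pid] = []
        records.append(ProteinRecord(protein_id=pid, sequence=seq))
    return records, truth


# ---------------------------------------------------------------------------
# Peptide reassignment scenarios

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def gen_peptide_scenario(n_proteins: int, peptides_per_protein: int = 4,
                         decoy_similarity: float = 0.0, seed: int = 0,
                         peptide_len: int = 9):
    """Cross-proteome mapping scenario with a known true target per source.

    Each source protein's peptides hit its true target (pident 100,
    bitscore 2 x peptide length).  With probability ``decoy_similarity`` a
    source also gets a competing decoy target whose aggregated evidence is
    engineered to be resolved at ladder tier 1, 2, 3 or 4 in rotation:

    * tier 1 - decoy has one fewer distinct peptide (with inflated
      bitscores, so peptide count must decide);
    * tier 2 - equal distinct-peptide counts, lower decoy bitscore sum;
    * tier 3 - equal counts and sums, lower decoy median identity;
    * tier 4 - all three statistics tie; the lexicographic fallback decides
      and the decoy id is drawn to sort before or after the true target, so
      roughly half of tier-4 scenarios are unrecoverable by design.

    Returns ``(hits, source_proteome, target_proteome, truth)``.
    """
    if not 0.0 <= decoy_similarity <= 1.0:
        raise ValueError("decoy_similarity must be in [0, 1]")
    if peptides_per_protein < 2:
        raise ValueError("need at least 2 peptides per protein")
    rng = np.random.default_rng(seed)
    hits: list[PeptideHit] = []
    sources, targets = [], []
    truth = GroundTruth()
    base_score = 2.0 * peptide_len
    tier_cycle = 0
    for i in range(n_proteins):
        src = f"S{i:04d}"
        tgt = f"T{i:04d}"
        tseq = "".join(rng.choice(list(_AA20), size=80))
        targets.append(ProteinRecord(protein_id=tgt, sequence=tseq))
        cut = rng.choice(len(tseq) - peptide_len, size=peptides_per_protein,
                         replace=False)
        peptides = [(f"{src}_pep{j + 1}", tseq[c:c + peptide_len])
                    for j, c in enumerate(sorted(cut))]
        sources.append(ProteinRecord(protein_id=src,
                                     sequence="".join(p for _, p in peptides)))
        truth.true_target[src] = tgt

        def _hit(pep_id, target, pident, bitscore, sstart=1):
            return PeptideHit(peptide_id=pep_id, source_protein=src,
                              target_protein=target, pident=pident,
                              length=peptide_len, mismatch=0, gapopen=0,
                              qstart=1, qend=peptide_len,
                              sstart=sstart, send=sstart + peptide_len - 1,
                              evalue=1e-6, bitscore=bitscore)

        for j, (pep_id, _) in enumerate(peptides):
            hits.append(_hit(pep_id, tgt, 100.0, base_score, sstart=int(sorted(cut)[j]) + 1))

        if rng.random() < decoy_similarity:
            tier = tier_cycle % 4 + 1
            tier_cycle += 1
            if tier == 4:
                decoy = (f"A{i:04d}" if rng.random() < 0.5 else f"Z{i:04d}")
            else:
                decoy = f"D{i:04d}"
            targets.append(ProteinRecord(
                protein_id=decoy,
                sequence="".join(rng.choice(list(_AA20), size=80))))
            if tier == 1:
                for pep_id, _ in peptides[:-1]:
                    hits.append(_hit(pep_id, decoy, 100.0, base_score * 3))
            elif tier == 2:
                for pep_id, _ in peptides:
                    hits.append(_hit(pep_id, decoy, 100.0, base_score - 2.0))
            elif tier == 3:
                for pep_id, _ in peptides:
                    hits.append(_hit(pep_id, decoy, 95.0, base_score))
            else:
                for pep_id, _ in peptides:
                    hits.append(_hit(pep_id, decoy, 100.0, base_score))
            truth.scenario_tier[src] = tier
        else:
            truth.scenario_tier[src] = 0
    return hits, sources, targets, truth


# ---------------------------------------------------------------------------
# Functional annotations

_CATEGORY_DESCRIPTIONS = {
    "protein aggregation & membrane stability": [
        "dehydrin DHN1", "late embryogenesis abundant protein, group 3", "remorin family protein"],
    "protein folding & chaperone activity": [
        "heat shock protein 70", "small heat shock protein 22", "peptidyl-prolyl isomerase"],
    "metabolism & osmoregulation": [
        "aldose reductase", "malate synthase, glyoxysomal", "sucrose synthase 2"],
    "detoxification & ROS scavenging": [
        "glutathione transferase", "L-ascorbate peroxidase", "catalase isozyme 1"],
    "lipid metabolism": [
        "non-specific lipid transfer protein", "phosphatidylethanolamine-binding protein",
        "omega-3 fatty acid desaturase"],
    "antifreeze & cell wall modification": [
        "chitinase class I", "thaumatin-like protein zeamatin", "expansin B3"],
    "cold signal transduction": [
        "calmodulin-like protein", "39 kDa EF-hand containing protein",
        "serine/threonine protein kinase"],
    "cytoskeletal organization": [
        "actin-depolymerizing factor", "tubulin beta chain", "kinesin-like protein"],
    "other/uncategorized": [
        "hypothetical protein", "60S ribosomal protein L3", "uncharacterized protein"],
}


def gen_annotations(protein_ids, seed: int = 0,
                    category_probs: dict[str, float] | None = None) -> pd.DataFrame:
    """Assign each protein a description drawn from per-category exemplar
    pools; returns columns protein_id, description, go_terms,
    true_category.  By default categories are drawn uniformly."""
    rng = np.random.default_rng(seed)
    cats = list(_CATEGORY_DESCRIPTIONS)
    if category_probs:
        probs = np.array([category_probs.get(c, 0.0) for c in cats])
        probs = probs / probs.sum()
    else:
        probs = np.full(len(cats), 1.0 / len(cats))
    rows = []
    for pid in protein_ids:
        cat = cats[rng.choice(len(cats), p=probs)]
        desc = _CATEGORY_DESCRIPTIONS[cat][rng.integers(len(_CATEGORY_DESCRIPTIONS[cat]))]
        rows.append({"protein_id": pid, "description": desc, "go_terms": "",
                     "true_category": cat})
    return pd.DataFrame(rows)
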