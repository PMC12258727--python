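"""Readers and writers for every external format the pipeline touches.

All tables are tab-separated with a mandatory header row and "." as the
decimal point, matching common Proteome Discoverer / OrthoFinder exports.
Missing abundance values are accepted as empty cells or ``NA`` on read and
always written back as ``NA``.  Readers validate and raise
:class:`FormatError` / :class:`ValidationError` with a located message
rather than silently coercing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ValidationError",
    "UNASSIGNED",
    "ProteinRecord",
    "AbundanceMatrix",
    "OrthogroupTable",
    "PeptideHit",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "validate_metadata",
    "read_fasta",
    "write_fasta",
    "read_orthogroups",
    "write_orthogroups",
    "read_hit_table",
    "write_hit_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A file parses but violates a dataset-level invariant."""


#: Sentinel orthogroup label for proteins absent from every orthogroup.
UNASSIGNED = "unassigned"

SEASONS = ("winter", "summer")

METADATA_COLUMNS = ["sample_id", "species", "season", "year", "batch"]

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: 20 standard residues plus X, upper-case."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity table for one species.

    ``data`` is a float DataFrame indexed by protein_id with sample_id
    columns; missing intensities are NaN.  Intensities are non-negative.
    """

    data: pd.DataFrame
    species: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate protein ID {dup!r} in abundance matrix")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r} in abundance matrix")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            bad = self.data.columns[(vals < 0).any(axis=0)][0]
            raise ValidationError(f"negative intensity in sample {bad!r}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class OrthogroupTable:
    """Bidirectional orthogroup <-> protein mapping (a partition).

    Proteins never listed belong to the :data:`UNASSIGNED` sentinel.
    """

    members: dict[str, set[str]] = field(default_factory=dict)
    species_names: list[str] = field(default_factory=list)
    _protein_to_og: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._protein_to_og:
            for og, prots in self.members.items():
                for p in prots:
                    if p in self._protein_to_og:
                        raise ValidationError(
                            f"protein {p!r} listed in both {self._protein_to_og[p]!r} and {og!r}"
                        )
                    self._protein_to_og[p] = og

    def orthogroup_of(self, protein_id: str) -> str:
        return self._protein_to_og.get(protein_id, UNASSIGNED)

    def proteins_of(self, orthogroup_id: str) -> set[str]:
        return set(self.members.get(orthogroup_id, set()))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PeptideHit:
    """One peptide-to-candidate-protein alignment record (tabular hit).

    The query field of the tabular file encodes ``peptideID|sourceProteinID``;
    a query without ``|`` is its own source protein.
    """

    peptide_id: str
    source_protein: str
    target_protein: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValidationError(
                f"pident {self.pident} out of [0, 100] for peptide {self.peptide_id!r}"
            )


# ---------------------------------------------------------------------------
# Abundance matrix + metadata


def read_abundance_tsv(path, meta_path=None, species: str = "") -> AbundanceMatrix | tuple:
    """Read a proteins x samples TSV; first column protein IDs.

    With ``meta_path`` given, also reads the companion metadata table,
    validates that every sample column has a metadata row, and returns
    ``(matrix, metadata)``.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, na_values=["NA", ""],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity value ({exc})") from None
    matrix = AbundanceMatrix(data=df, species=species)
    if meta_path is None:
        return matrix
    meta = read_metadata_tsv(meta_path)
    validate_metadata(matrix, meta)
    return matrix, meta


def write_abundance_tsv(matrix: AbundanceMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: metadata lacks required column(s) {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r} in metadata")
    bad = set(meta["season"]) - set(SEASONS)
    if bad:
        raise ValidationError(f"season must be one of {SEASONS}; got {sorted(bad)}")
    meta["year"] = meta["year"].astype(int)
    return meta[METADATA_COLUMNS + [c for c in meta.columns if c not in METADATA_COLUMNS]]


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def validate_metadata(matrix: AbundanceMatrix, meta: pd.DataFrame) -> None:
    """Every sample column of the matrix must have a metadata row."""
    known = set(meta["sample_id"])
    for s in matrix.sample_ids:
        if s not in known:
            raise ValidationError(f"sample {s!r} in abundance matrix has no metadata row")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein FASTA; ID is the header token up to the first whitespace.

    Sequences are upper-cased and a single trailing ``*`` stop is stripped.
    FASTA IDs are case-sensitive.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate protein ID {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(protein_id=rec.id, sequence=seq))
    if not records:
        warnings.warn(f"{path}: FASTA file contains no records", stacklevel=2)
    return records


def write_fasta(records, path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Orthogroups (OrthoFinder "Orthogroups.tsv" dialect)


def read_orthogroups(path) -> OrthogroupTable:
    """Parse the wide OrthoFinder table: one row per orthogroup, one column
    per species, cells holding comma-separated protein IDs (possibly empty)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: orthogroup table needs an ID column and >=1 species column")
    species = list(df.columns[1:])
    members: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        og = row.iloc[0]
        prots: set[str] = set()
        for cell in row.iloc[1:]:
            if cell.strip():
                prots.update(p.strip() for p in cell.split(",") if p.strip())
        members[og] = prots
    return OrthogroupTable(members=members, species_names=species)


def write_orthogroups(table: OrthogroupTable, path,
                      species_of=None) -> None:
    """Write the wide dialect back.  ``species_of`` maps protein -> species
    column; proteins with unknown species go to the first column."""
    species = table.species_names or ["species_1"]
    rows = []
    for og in sorted(table.members):
        cells = {sp: [] for sp in species}
        for p in sorted(table.members[og]):
            sp = species_of(p) if species_of else species[0]
            cells.setdefault(sp, []).append(p)
        rows.append([og] + [", ".join(cells.get(sp, [])) for sp in species])
    pd.DataFrame(rows, columns=["Orthogroup"] + species).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tabular alignment hits (12-column BLAST/DIAMOND outfmt-6 dialect)


def _split_query(query: str) -> tuple[str, str]:
    if "|" in query:
        pep, src = query.split("|", 1)
        return pep, src
    return query, query


def read_hit_table(path) -> list[PeptideHit]:
    """Parse 12-column tab-separated alignment hits.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  A header line repeating the
    column names is tolerated.
    """
    hits: list[PeptideHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "query" and lineno == 1:
                continue
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, found {len(fields)}"
                )
            try:
                pep, src = _split_query(fields[0])
                hit = PeptideHit(
                    peptide_id=pep,
                    source_protein=src,
                    target_protein=fields[1],
                    pident=float(fields[2]),
                    length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


def write_hit_table(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            query = h.peptide_id if h.peptide_id == h.source_protein else f"{h.peptide_id}|{h.source_protein}"
            fh.write("\t".join(str(x) for x in (
                query, h.target_protein, f"{h.pident:g}", h.length, h.mismatch,
                h.gapopen, h.qstart, h.qend, h.sstart, h.send,
                f"{h.evalue:g}", f"{h.bitscore:g}",
            )) + "\n")
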