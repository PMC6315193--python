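"""Reading and writing the formats the pipeline touches, plus base statistics.

Genome and proteome FASTA parsing is delegated to Biopython's SeqIO; this
module adds validation (alphabets, empty records), the in-memory containers
the rest of the pipeline consumes, the sample-sheet convention that supplies
genome identifiers and strain metadata, and G+C content statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes (unambiguous + ambiguity + N), uppercase.
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
# 20 amino acids plus X (unknown); B/Z/J/U/O accepted as rare extended codes.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO")

_GC = frozenset("GC")
_UNAMBIGUOUS = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed or empty input file."""


class UndefinedValueError(ValueError):
    """A statistic is undefined for the given input (e.g. all-N genome)."""


@dataclass
class StrainMetadata:
    """Nomenclatural metadata for one genome/strain.

    ``page_rank`` orders names within a single publication (lower = earlier
    page = senior); it is meaningful only when ``publication_year`` is set.
    """

    name: str = ""
    is_type_strain: bool = False
    is_type_species: bool = False
    validly_published: bool = False
    publication_year: int | None = None
    page_rank: int | None = None
    is_mag: bool = False

    def __post_init__(self) -> None:
        if self.page_rank is not None and self.publication_year is None:
            raise ValueError("page_rank requires publication_year")


@dataclass
class GenomeRecord:
    """A named nucleotide assembly: one or more contigs plus metadata."""

    id: str
    contigs: list[str]
    metadata: StrainMetadata | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def sequence(self) -> str:
        """All contigs concatenated (no separator); convenience accessor."""
        return "".join(self.contigs)


@dataclass
class ProteomeRecord:
    """The protein complement of one genome."""

    genome_id: str
    proteins: list[tuple[str, str]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.proteins)


def read_genome_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read a (possibly multi-contig) nucleotide FASTA into a GenomeRecord.

    Contigs keep file order and are uppercased.  The record id is
    ``genome_id`` if given, else the first header token of the first record.
    Raises :class:`FormatError` for empty files, records without sequence,
    or characters outside the IUPAC nucleotide alphabet.
    """
    path = Path(path)
    contigs: list[str] = []
    first_id: str | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        bad = set(seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )
        if first_id is None:
            first_id = rec.id
        contigs.append(seq)
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeRecord(id=genome_id or first_id, contigs=contigs)


def write_genome_fasta(genome: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, contig in enumerate(genome.contigs):
            fh.write(f">{genome.id}_contig{i + 1}\n")
            for j in range(0, len(contig), width):
                fh.write(contig[j : j + width] + "\n")


def read_proteome_fasta(path: str | Path, genome_id: str) -> ProteomeRecord:
    """Read an amino-acid FASTA; trailing stop symbols (*) are stripped.

    Records whose sequences look nucleotide-only (ACGT[N] and >=50 aa) are
    accepted with a logged warning: such proteins are legal in principle,
    but the pattern usually means a nucleotide file was passed by mistake.
    """
    path = Path(path)
    proteins: list[tuple[str, str]] = []
    suspicious = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        bad = set(seq) - PROTEIN_ALPHABET - {"*"}
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid residues {sorted(bad)}"
            )
        if len(seq) >= 50 and set(seq) <= set("ACGTN"):
            suspicious += 1
        proteins.append((rec.id, seq))
    if not proteins:
        raise FormatError(f"{path}: no FASTA records found")
    if suspicious:
        logger.warning(
            "%s: %d of %d records look nucleotide-only; accepting, but check "
            "that this is really a proteome",
            path,
            suspicious,
            len(proteins),
        )
    return ProteomeRecord(genome_id=genome_id, proteins=proteins)


def write_proteome_fasta(prot: ProteomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for pid, seq in prot.proteins:
            fh.write(f">{pid}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")


def gc_content(genome: GenomeRecord) -> float:
    """G+C content in mol%: 100*(G+C)/(A+C+G+T).

    Ambiguity codes and N are excluded from both numerator and denominator,
    keeping the statistic a pure base-composition measure.  Raises
    :class:`UndefinedValueError` when no unambiguous base remains.
    """
    gc = 0
    total = 0
    for contig in genome.contigs:
        for base in contig:
            if base in _UNAMBIGUOUS:
                total += 1
                if base in _GC:
                    gc += 1
    if total == 0:
        raise UndefinedValueError(
            f"genome {genome.id!r}: G+C content undefined (no unambiguous bases)"
        )
    return 100.0 * gc / total


def gc_difference(a: GenomeRecord, b: GenomeRecord) -> float:
    """Absolute difference in G+C content, in percentage points (symmetric)."""
    return abs(gc_content(a) - gc_content(b))


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

#: Required sample-sheet columns; metadata columns are optional.
SAMPLE_SHEET_REQUIRED = ("id", "genome_path")
SAMPLE_SHEET_OPTIONAL = (
    "proteome_path",
    "name",
    "is_type_strain",
    "is_type_species",
    "validly_published",
    "publication_year",
    "page_rank",
    "is_mag",
)

_BOOL_TRUE = {"1", "true", "yes", "y", "t"}


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return False
    return str(v).strip().lower() in _BOOL_TRUE


def _as_int(v) -> int | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
        return None
    return int(float(v))


@dataclass
class SampleSheetEntry:
    id: str
    genome_path: Path
    proteome_path: Path | None
    metadata: StrainMetadata


def read_sample_sheet(path: str | Path) -> list[SampleSheetEntry]:
    """Read the tab-separated sample sheet driving a pipeline run.

    Genome identifiers come from this sheet, never from FASTA headers
    (strain names routinely contain characters unsafe for file-derived IDs).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in SAMPLE_SHEET_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    entries: list[SampleSheetEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gid = str(row["id"]).strip()
        if not gid:
            raise FormatError(f"{path}: empty genome id")
        if gid in seen:
            raise FormatError(f"{path}: duplicate genome id {gid!r}")
        seen.add(gid)
        md = StrainMetadata(
            name=str(row.get("name", "") or ""),
            is_type_strain=_as_bool(row.get("is_type_strain")),
            is_type_species=_as_bool(row.get("is_type_species")),
            validly_published=_as_bool(row.get("validly_published")),
            publication_year=_as_int(row.get("publication_year")),
            page_rank=_as_int(row.get("page_rank")),
            is_mag=_as_bool(row.get("is_mag")),
        )
        prot = str(row.get("proteome_path", "") or "").strip()
        entries.append(
            SampleSheetEntry(
                id=gid,
                genome_path=path.parent / str(row["genome_path"]).strip(),
                proteome_path=(path.parent / prot) if prot else None,
                metadata=md,
            )
        )
    if not entries:
        raise FormatError(f"{path}: sample sheet has no rows")
    return entries


def write_sample_sheet(entries: Sequence[SampleSheetEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        md = e.metadata
        rows.append(
            {
                "id": e.id,
                "genome_path": str(e.genome_path.name),
                "proteome_path": str(e.proteome_path.name) if e.proteome_path else "",
                "name": md.name,
                "is_type_strain": int(md.is_type_strain),
                "is_type_species": int(md.is_type_species),
                "validly_published": int(md.validly_published),
                "publication_year": md.publication_year if md.publication_year is not None else "",
                "page_rank": md.page_rank if md.page_rank is not None else "",
                "is_mag": int(md.is_mag),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
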