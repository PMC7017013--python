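"""Sequence, alignment, and registry I/O.

Canonical record types used by every pipeline stage.  Residue positions are
1-based inclusive throughout the package; alignment columns are 1-based.
FASTA and Clustal parsing is delegated to Biopython; the thin ``Alignment``
wrapper exists so downstream code has a stable rectangular-matrix contract.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

logger = logging.getLogger("prodomainkit")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Ambiguity/rare letters normalised to X on ingest so scoring stays total.
NONSTANDARD = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}

SPECIES_CODES = ("Ce", "Dm", "Mm", "other")
SUBFAMILY_LABELS = ("Activin", "TGFB", "BMP", "outgroup", "unassigned")


class SeqIOError(ValueError):
    """Malformed sequence/alignment/registry input."""


def clean_sequence(seq: str) -> str:
    """Uppercase, strip '*' stop characters, map non-standard letters to X."""
    s = seq.upper().replace("*", "").replace(".", "")
    out = []
    warned = set()
    for ch in s:
        if ch in NONSTANDARD:
            if ch not in warned:
                logger.warning("non-standard residue %r mapped to X", ch)
                warned.add(ch)
            ch = NONSTANDARD[ch]
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with species/subfamily/accession metadata."""

    id: str
    sequence: str
    species: str = "other"
    subfamily_label: str = "unassigned"
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        if GAP in self.sequence:
            raise SeqIOError(f"record {self.id!r}: sequence contains gap characters")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise SeqIOError(f"record {self.id!r}: invalid residues {sorted(bad)}")
        if self.species not in SPECIES_CODES:
            raise SeqIOError(f"record {self.id!r}: unknown species code {self.species!r}")
        if self.subfamily_label not in SUBFAMILY_LABELS:
            raise SeqIOError(
                f"record {self.id!r}: unknown subfamily {self.subfamily_label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Registry:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SeqIOError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.species] = counts.get(rec.species, 0) + 1
        return counts

    def subset(self, ids: Iterable[str]) -> "Registry":
        wanted = list(ids)
        by_id = {r.id: r for r in self.records}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise KeyError(f"ids not in registry: {missing}")
        return Registry([by_id[i] for i in wanted], provenance=self.provenance)


@dataclass
class Alignment:
    """Rectangular gapped character matrix with row ids (columns 1-based)."""

    row_ids: list[str]
    matrix: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.matrix):
            raise SeqIOError("row_ids and matrix length mismatch")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise SeqIOError("duplicate row ids in alignment")
        if self.matrix:
            lens = {len(r) for r in self.matrix}
            if len(lens) > 1:
                detail = ", ".join(
                    f"{i}:{len(r)}" for i, r in zip(self.row_ids, self.matrix)
                )
                raise SeqIOError(f"ragged alignment rows ({detail})")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    def row(self, rec_id: str) -> str:
        try:
            return self.matrix[self.row_ids.index(rec_id)]
        except ValueError:
            raise KeyError(rec_id) from None

    def ungapped(self, rec_id: str) -> str:
        return self.row(rec_id).replace(GAP, "")

    def column(self, col: int) -> str:
        """1-based column."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")
        return "".join(row[col - 1] for row in self.matrix)

    def subset_rows(self, ids: Sequence[str]) -> "Alignment":
        return Alignment(list(ids), [self.row(i) for i in ids])


# ---------------------------------------------------------------------------
# FASTA / Clustal / TSV I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into records (ids = first header token)."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id = entry.id.strip()
        if not rec_id:
            raise SeqIOError(f"{path}: malformed empty FASTA header")
        if rec_id in seen:
            raise SeqIOError(f"{path}: duplicate id {rec_id!r}")
        seen.add(rec_id)
        records.append(ProteinRecord(id=rec_id, sequence=clean_sequence(str(entry.seq))))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an alignment from FASTA or Clustal format, preserving row order."""
    if fmt not in ("fasta", "clustal"):
        raise SeqIOError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise SeqIOError(f"{path}: {exc}") from exc
    row_ids = [rec.id for rec in aln]
    matrix = [str(rec.seq).upper() for rec in aln]
    return Alignment(row_ids, matrix)


def write_alignment(aln: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    if fmt == "fasta":
        with open(path, "w") as fh:
            for rid, row in zip(aln.row_ids, aln.matrix):
                fh.write(f">{rid}\n{row}\n")
    elif fmt == "clustal":
        buf = io.StringIO()
        buf.write("CLUSTAL W multiple sequence alignment\n\n")
        width = 60
        for start in range(0, aln.n_cols, width):
            for rid, row in zip(aln.row_ids, aln.matrix):
                buf.write(f"{rid:<20} {row[start:start + width]}\n")
            buf.write("\n")
        Path(path).write_text(buf.getvalue())
    else:
        raise SeqIOError(f"unsupported alignment format {fmt!r}")


REGISTRY_COLUMNS = ("id", "species", "subfamily", "accession")


def read_registry(tsv_path: str | Path, fasta_path: str | Path) -> Registry:
    """Assemble a Registry from a metadata TSV plus the matching FASTA.

    TSV columns are fixed as id, species, subfamily, accession; lines starting
    with '#' are comments.  Every TSV id must be present in the FASTA.
    """
    seqs = {r.id: r.sequence for r in read_fasta(fasta_path)}
    records: list[ProteinRecord] = []
    for lineno, line in enumerate(Path(tsv_path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise SeqIOError(
                f"{tsv_path}:{lineno}: expected 4 tab-separated fields "
                f"(id, species, subfamily, accession), got {len(parts)}"
            )
        rec_id, species, subfamily, accession = (p.strip() for p in parts)
        if rec_id not in seqs:
            raise SeqIOError(f"{tsv_path}:{lineno}: id {rec_id!r} not in FASTA")
        records.append(
            ProteinRecord(
                id=rec_id,
                sequence=seqs[rec_id],
                species=species,
                subfamily_label=subfamily,
                accession=accession,
            )
        )
    return Registry(records, provenance=f"{tsv_path} + {fasta_path}")


def write_registry(reg: Registry, tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("# id\tspecies\tsubfamily\taccession\n")
        for rec in reg:
            fh.write(f"{rec.id}\t{rec.species}\t{rec.subfamily_label}\t{rec.accession}\n")


def check_consistency(reg: Registry, aln: Alignment) -> None:
    """Assert every alignment row ungaps to its registry sequence."""
    for rid in aln.row_ids:
        if aln.ungapped(rid) != reg[rid].sequence:
            raise SeqIOError(f"alignment row {rid!r} does not ungap to its sequence")
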