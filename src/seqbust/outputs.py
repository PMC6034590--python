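"""Serialize extraction results: per-locus FASTA, accession table, longest-seq.

FASTA files are named ``{locus}.fasta`` with 80-column sequence wrap.
The accession table is a species-by-locus grid whose cells name the
accession each extracted sequence came from; it serializes to CSV with
header ``Species,{locus1},{locus2},...``.
"""

from __future__ import annotations

import csv
import logging
import os
import re
from dataclasses import dataclass, field

from seqbust.extraction import (
    STATUS_FOUND,
    ExtractedSequence,
    ExtractionReport,
)
from seqbust.genbank_records import GenBankRecord

logger = logging.getLogger(__name__)

FASTA_WRAP = 80

HEADER_STYLES = ("accession", "organism_accession")


def _safe_stem(locus: str) -> str:
    """Locus name as a filesystem-safe file stem."""
    return re.sub(r"[^\w.\-()]", "_", locus)


def fasta_header(entry: ExtractedSequence, header_style: str) -> str:
    if header_style == "accession":
        name = entry.accession
    elif header_style == "organism_accession":
        organism = entry.organism.replace(" ", "_") if entry.organism else ""
        name = f"{organism}_{entry.accession}" if organism else entry.accession
    else:
        raise ValueError(f"unknown header style {header_style!r}")
    if entry.copy_index > 1:
        name = f"{name}_copy{entry.copy_index}"
    return name


def write_fasta(
    extracted: list[ExtractedSequence],
    out_dir: str,
    header_style: str = "organism_accession",
) -> list[str]:
    """Write one FASTA file per locus present; return the paths written."""
    if header_style not in HEADER_STYLES:
        raise ValueError(
            f"unknown header style {header_style!r}; valid: "
            + ", ".join(HEADER_STYLES)
        )
    if extracted and not os.path.isdir(out_dir):
        raise NotADirectoryError(f"output directory {out_dir!r} does not exist")
    if extracted and not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir!r} is not writable")
    by_locus: dict[str, list[ExtractedSequence]] = {}
    for entry in extracted:
        by_locus.setdefault(entry.locus, []).append(entry)
    paths: list[str] = []
    for locus, entries in by_locus.items():
        path = os.path.join(out_dir, f"{_safe_stem(locus)}.fasta")
        with open(path, "w", encoding="utf-8") as fh:
            for entry in entries:
                fh.write(f">{fasta_header(entry, header_style)}\n")
                seq = entry.sequence
                for i in range(0, len(seq), FASTA_WRAP):
                    fh.write(seq[i : i + FASTA_WRAP] + "\n")
        paths.append(path)
    return paths


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Parse a FASTA file into (header, sequence) pairs."""
    entries: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    entries.append((header, "".join(chunks)))
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    if header is not None:
        entries.append((header, "".join(chunks)))
    return entries


# ---------------------------------------------------------------------------
# accession table

@dataclass
class AccessionTable:
    """Species-by-locus grid of source accessions (empty cell = missing)."""

    loci: list[str]
    rows: dict[str, dict[str, str]] = field(default_factory=dict)

    def cell(self, species: str, locus: str) -> str:
        return self.rows.get(species, {}).get(locus, "")

    def to_csv(self, path_or_stream) -> None:
        if isinstance(path_or_stream, str):
            with open(path_or_stream, "w", encoding="utf-8", newline="") as fh:
                self.to_csv(fh)
            return
        writer = csv.writer(path_or_stream)
        writer.writerow(["Species"] + self.loci)
        for species in self.rows:
            row = self.rows[species]
            writer.writerow([species] + [row.get(l, "") for l in self.loci])

    @classmethod
    def from_csv(cls, path_or_stream) -> "AccessionTable":
        if isinstance(path_or_stream, str):
            with open(path_or_stream, encoding="utf-8", newline="") as fh:
                return cls.from_csv(fh)
        reader = csv.reader(path_or_stream)
        header = next(reader)
        if not header or header[0] != "Species":
            raise ValueError("accession-table CSV must start with a Species column")
        loci = header[1:]
        table = cls(loci=loci)
        for row in reader:
            species = row[0]
            table.rows[species] = {
                l: v for l, v in zip(loci, row[1:]) if v
            }
        return table


def build_accession_table(
    report: ExtractionReport,
    records: list[GenBankRecord],
    requested_loci: list[str] | None = None,
) -> AccessionTable:
    """Build the species-by-locus accession grid from a merged report.

    Rows are keyed by organism name (accession when the record has no
    organism); one organism spanning several accessions collapses into a
    single row, first-found winning on conflict.
    """
    by_accession = {rec.label: rec for rec in records}
    if requested_loci is None:
        seen: dict[str, None] = {}
        for _, locus in report.statuses:
            seen.setdefault(locus, None)
        requested_loci = list(seen)
    table = AccessionTable(loci=list(requested_loci))
    for rec in records:
        species = rec.organism or rec.label
        table.rows.setdefault(species, {})
    for (accession, locus), status in report.statuses.items():
        if status != STATUS_FOUND:
            continue
        rec = by_accession.get(accession)
        species = (rec.organism if rec and rec.organism else accession)
        row = table.rows.setdefault(species, {})
        if locus in row and row[locus] != accession:
            logger.warning(
                "species %s locus %s already sourced from %s; ignoring %s",
                species, locus, row[locus], accession,
            )
            continue
        row[locus] = accession
    return table


# ---------------------------------------------------------------------------
# longest sequence per species

@dataclass
class LongestSelection:
    """Per-species choice of the longest available accession."""

    selection: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selection)

    def to_csv(self, path_or_stream) -> None:
        if isinstance(path_or_stream, str):
            with open(path_or_stream, "w", encoding="utf-8", newline="") as fh:
                self.to_csv(fh)
            return
        writer = csv.writer(path_or_stream)
        writer.writerow(["Species", "Accession", "Length"])
        for species in self.selection:
            accession, length = self.selection[species]
            writer.writerow([species, accession, length])


def find_longest_seq(
    entries: list[tuple[str, str, int]]
) -> LongestSelection:
    """Pick, per species, the longest (species, accession, length) entry.

    Length ties break to the lexicographically least accession, making
    the result independent of input order.
    """
    best: dict[str, tuple[str, int]] = {}
    for species, accession, length in entries:
        if length <= 0:
            raise ValueError(
                f"non-positive length {length} for accession {accession}"
            )
        cur = best.get(species)
        if (
            cur is None
            or length > cur[1]
            or (length == cur[1] and accession < cur[0])
        ):
            best[species] = (accession, length)
    return LongestSelection(selection=best)


def find_longest_from_records(records: list[GenBankRecord]) -> LongestSelection:
    """FindLongestSeq over parsed records, using organism and sequence length."""
    return find_longest_seq(
        [
            (rec.organism or rec.label, rec.label, len(rec.sequence))
            for rec in records
            if rec.sequence
        ]
    )
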