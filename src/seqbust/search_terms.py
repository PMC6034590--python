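"""Synonym search-term tables: schema, CSV I/O, bundled sets, merging.

A search-term table has rows of (Locus, Type, Name, IntronExonNumber):
``Locus`` is the output group (and FASTA file stem), ``Type`` the feature
key to match (CDS, tRNA, rRNA, misc_RNA, D-loop, intron, exon,
misc_feature), ``Name`` one synonym under which the locus may be
annotated, and ``IntronExonNumber`` the intron/exon ordinal for rows of
those two types.  Row order defines match priority.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources

from seqbust.genbank_records import ParseIssue

#: Feature types a search-term row may carry, canonical capitalization.
VALID_FEATURE_TYPES = (
    "CDS",
    "tRNA",
    "rRNA",
    "misc_RNA",
    "D-loop",
    "intron",
    "exon",
    "misc_feature",
)
_TYPE_BY_FOLD = {t.lower(): t for t in VALID_FEATURE_TYPES}

CSV_HEADER = ["Locus", "Type", "Name", "IntronExonNumber"]

#: Bundled dictionary names mapped to their packaged CSV files.
BUNDLED_SETS = {
    "mtDNA-animal": "mtdna_animal_terms.csv",
    "mtDNA-plant": "mtdna_plant_terms.csv",
    "cpDNA": "cpdna_terms.csv",
    "rDNA": "rdna_terms.csv",
}


@dataclass(frozen=True)
class SearchTerm:
    locus: str
    feature_type: str
    name: str = ""
    intron_exon_number: int | None = None


@dataclass
class SearchTermTable:
    rows: list[SearchTerm] = field(default_factory=list)
    source_names: list[str] = field(default_factory=list)

    def loci(self) -> list[str]:
        """Distinct locus names in first-appearance order."""
        seen: dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.locus, None)
        return list(seen)

    def rows_for_locus(self, locus: str) -> list[SearchTerm]:
        return [r for r in self.rows if r.locus == locus]

    def __len__(self) -> int:
        return len(self.rows)


def validate_terms(table: SearchTermTable) -> list[ParseIssue]:
    """Return one issue per schema violation; empty list iff valid."""
    issues: list[ParseIssue] = []
    for i, row in enumerate(table.rows, start=1):
        if not row.locus:
            issues.append(ParseIssue("error", f"row {i}: empty Locus", i))
        if not row.feature_type:
            issues.append(ParseIssue("error", f"row {i}: empty Type", i))
        elif row.feature_type.lower() not in _TYPE_BY_FOLD:
            issues.append(
                ParseIssue(
                    "error",
                    f"row {i}: unknown feature type {row.feature_type!r} "
                    f"(expected one of {', '.join(VALID_FEATURE_TYPES)})",
                    i,
                )
            )
        is_intron_exon = row.feature_type.lower() in ("intron", "exon")
        if is_intron_exon and row.intron_exon_number is None:
            issues.append(
                ParseIssue(
                    "error",
                    f"row {i}: {row.feature_type} row lacks IntronExonNumber",
                    i,
                )
            )
        if not is_intron_exon and row.intron_exon_number is not None:
            issues.append(
                ParseIssue(
                    "error",
                    f"row {i}: IntronExonNumber set on {row.feature_type} row",
                    i,
                )
            )
        if row.intron_exon_number is not None and row.intron_exon_number < 1:
            issues.append(
                ParseIssue("error", f"row {i}: IntronExonNumber must be >= 1", i)
            )
        if not row.name and row.feature_type.lower() != "d-loop":
            issues.append(
                ParseIssue(
                    "error",
                    f"row {i}: empty Name only allowed for D-loop rows",
                    i,
                )
            )
    return issues


def _require_valid(table: SearchTermTable, label: str) -> None:
    issues = validate_terms(table)
    if issues:
        msgs = "; ".join(i.message for i in issues[:5])
        raise ValueError(f"invalid search-term table {label}: {msgs}")


def load_bundled(name: str) -> SearchTermTable:
    """Load one of the bundled synonym dictionaries by set name."""
    if name not in BUNDLED_SETS:
        raise ValueError(
            f"unknown bundled set {name!r}; valid names: "
            + ", ".join(sorted(BUNDLED_SETS))
        )
    path = resources.files("seqbust").joinpath("data", BUNDLED_SETS[name])
    table = read_csv(io.StringIO(path.read_text(encoding="utf-8")), source=name)
    _require_valid(table, name)
    return table


def read_csv(stream, source: str = "csv") -> SearchTermTable:
    """Read a search-term table from CSV text (path or file object).

    The header must start with ``Locus,Type,Name``; the
    ``IntronExonNumber`` column is optional.
    """
    if isinstance(stream, str):
        with open(stream, encoding="utf-8", newline="") as fh:
            return read_csv(fh, source=source)
    reader = csv.DictReader(stream)
    fields = reader.fieldnames or []
    for col in ("Locus", "Type", "Name"):
        if col not in fields:
            raise ValueError(f"search-term CSV missing column {col!r}")
    rows: list[SearchTerm] = []
    for rec in reader:
        raw_num = (rec.get("IntronExonNumber") or "").strip()
        if raw_num:
            try:
                num: int | None = int(raw_num)
            except ValueError as exc:
                raise ValueError(
                    f"bad IntronExonNumber {raw_num!r} in search-term CSV"
                ) from exc
        else:
            num = None
        rows.append(
            SearchTerm(
                locus=(rec.get("Locus") or "").strip(),
                feature_type=(rec.get("Type") or "").strip(),
                name=(rec.get("Name") or "").strip(),
                intron_exon_number=num,
            )
        )
    return SearchTermTable(rows=rows, source_names=[source])


def write_csv(table: SearchTermTable, path_or_stream) -> None:
    """Write a table as ``Locus,Type,Name,IntronExonNumber`` CSV."""
    if isinstance(path_or_stream, str):
        with open(path_or_stream, "w", encoding="utf-8", newline="") as fh:
            write_csv(table, fh)
        return
    writer = csv.writer(path_or_stream)
    writer.writerow(CSV_HEADER)
    for row in table.rows:
        writer.writerow(
            [
                row.locus,
                row.feature_type,
                row.name,
                "" if row.intron_exon_number is None else row.intron_exon_number,
            ]
        )


def merge_terms(
    *tables: SearchTermTable, sort_by_locus: bool = False
) -> SearchTermTable:
    """Concatenate tables, dropping exact-duplicate rows (first kept).

    With ``sort_by_locus`` the result is grouped into alphabetical locus
    blocks, preserving within-locus relative order.
    """
    if not tables:
        return SearchTermTable()
    for i, table in enumerate(tables):
        _require_valid(table, table.source_names[0] if table.source_names else f"#{i}")
    seen: set[SearchTerm] = set()
    rows: list[SearchTerm] = []
    sources: list[str] = []
    for table in tables:
        sources.extend(table.source_names)
        for row in table.rows:
            if row not in seen:
                seen.add(row)
                rows.append(row)
    if sort_by_locus:
        rows = sorted(rows, key=lambda r: r.locus)  # stable: keeps row order
    return SearchTermTable(rows=rows, source_names=sources)
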