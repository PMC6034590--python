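"""Match annotated features against synonym tables and extract subsequences.

The matcher walks a record's feature table, compares feature keys and
qualifier values against the rows of a search-term table (row order =
priority), resolves the matched feature's location, and optionally
translates coding sequences under a numbered NCBI genetic code.  Every
requested (accession, locus) pair receives exactly one status in the
extraction report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from seqbust.genbank_records import (
    Feature,
    GenBankRecord,
    OutOfBoundsError,
    resolve_location,
)
from seqbust.search_terms import SearchTerm, SearchTermTable

# ---------------------------------------------------------------------------
# NCBI genetic codes
#
# Codon order: base1 cycles T,C,A,G slowest, base3 fastest.  The variant
# tables are stored as codon->amino-acid overrides of the standard code.

_BASE_ORDER = "tcag"
_STANDARD_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

_CODE_OVERRIDES: dict[int, dict[str, str]] = {
    1: {},
    2: {"aga": "*", "agg": "*", "ata": "M", "tga": "W"},
    3: {"ata": "M", "ctt": "T", "ctc": "T", "cta": "T", "ctg": "T", "tga": "W"},
    4: {"tga": "W"},
    5: {"aga": "S", "agg": "S", "ata": "M", "tga": "W"},
    9: {"aaa": "N", "aga": "S", "agg": "S", "tga": "W"},
    11: {},
    13: {"aga": "G", "agg": "G", "ata": "M", "tga": "W"},
    14: {"aaa": "N", "aga": "S", "agg": "S", "taa": "Y", "tga": "W"},
}


def _build_codes() -> dict[int, dict[str, str]]:
    standard = {}
    i = 0
    for b1 in _BASE_ORDER:
        for b2 in _BASE_ORDER:
            for b3 in _BASE_ORDER:
                standard[b1 + b2 + b3] = _STANDARD_AA[i]
                i += 1
    codes = {}
    for number, overrides in _CODE_OVERRIDES.items():
        table = dict(standard)
        table.update(overrides)
        codes[number] = table
    return codes


GENETIC_CODES: dict[int, dict[str, str]] = _build_codes()


@dataclass
class TranslationResult:
    peptide: str
    internal_stop: bool
    terminal_stop_removed: bool


def translate(dna: str, table_number: int, codon_start: int = 1) -> TranslationResult:
    """Translate a coding sequence, reporting stop-codon details.

    ``codon_start`` (1-3) gives the reading-frame offset; codon_start-1
    leading bases are skipped and an incomplete trailing codon dropped.
    Exactly one terminal stop is trimmed when present; internal stops
    are kept as ``*`` and flagged.  Codons containing ambiguity codes
    translate to ``X``.
    """
    if table_number not in GENETIC_CODES:
        raise ValueError(
            f"undefined translation table {table_number}; supported codes: "
            + ", ".join(str(k) for k in sorted(GENETIC_CODES))
        )
    if codon_start not in (1, 2, 3):
        raise ValueError(f"codon_start must be 1, 2 or 3, got {codon_start}")
    code = GENETIC_CODES[table_number]
    seq = dna.lower()[codon_start - 1 :]
    aas: list[str] = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(code.get(seq[i : i + 3], "X"))
    terminal_removed = False
    if aas and aas[-1] == "*":
        aas.pop()
        terminal_removed = True
    peptide = "".join(aas)
    return TranslationResult(
        peptide=peptide,
        internal_stop="*" in peptide,
        terminal_stop_removed=terminal_removed,
    )


def translate_cds(dna: str, table_number: int, codon_start: int = 1) -> str:
    """Peptide translation of ``dna`` under an NCBI genetic-code number."""
    if not dna:
        raise ValueError("cannot translate an empty sequence")
    return translate(dna, table_number, codon_start).peptide


# ---------------------------------------------------------------------------
# configuration and result types

DEFAULT_QUALIFIER_ORDER = ("gene", "product", "standard_name", "note")

STATUS_FOUND = "found"
STATUS_NOT_FOUND = "not_found"
STATUS_UNPARSEABLE = "unparseable_location"
STATUS_OUT_OF_BOUNDS = "out_of_bounds"
ALL_STATUSES = (
    STATUS_FOUND,
    STATUS_NOT_FOUND,
    STATUS_UNPARSEABLE,
    STATUS_OUT_OF_BOUNDS,
)


@dataclass
class ExtractionConfig:
    loci_filter: set[str] | None = None
    duplicates: bool = False
    translate: bool = False
    default_translation_table: int = 1
    qualifier_search_order: tuple[str, ...] = DEFAULT_QUALIFIER_ORDER
    match_mode: str = "exact_full_value"

    def __post_init__(self) -> None:
        if self.default_translation_table not in GENETIC_CODES:
            raise ValueError(
                f"undefined translation table {self.default_translation_table}"
            )
        if not self.qualifier_search_order:
            raise ValueError("qualifier_search_order must be nonempty")
        if self.match_mode not in ("exact_full_value", "word_boundary"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")


@dataclass
class ExtractedSequence:
    locus: str
    accession: str
    organism: str
    sequence: str
    copy_index: int = 1
    was_translated: bool = False
    feature_key: str = ""
    matched_synonym: str = ""
    matched_qualifier: str = ""
    partial: bool = False


@dataclass
class ExtractionReport:
    """Per-(accession, locus) statuses plus free-form notes."""

    statuses: dict[tuple[str, str], str] = field(default_factory=dict)
    notes: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def set_status(self, accession: str, locus: str, status: str) -> None:
        if status not in ALL_STATUSES:
            raise ValueError(f"unknown status {status!r}")
        self.statuses[(accession, locus)] = status

    def add_note(self, accession: str, locus: str, note: str) -> None:
        self.notes.setdefault((accession, locus), []).append(note)

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in ALL_STATUSES}
        for status in self.statuses.values():
            out[status] += 1
        return out

    def merge(self, other: "ExtractionReport") -> None:
        self.statuses.update(other.statuses)
        for key, msgs in other.notes.items():
            self.notes.setdefault(key, []).extend(msgs)


@dataclass(frozen=True)
class MatchResult:
    locus: str
    matched_synonym: str
    matched_qualifier: str
    row: SearchTerm


# ---------------------------------------------------------------------------
# matching

_NON_MATCHABLE_KEYS = frozenset({"source"})


def _value_matches(value: str, synonym: str, mode: str) -> bool:
    if mode == "exact_full_value":
        return value.strip().lower() == synonym.strip().lower()
    return (
        re.search(
            r"(?<!\w)" + re.escape(synonym.strip()) + r"(?!\w)", value, re.IGNORECASE
        )
        is not None
    )


def _row_matches(
    feature: Feature,
    row: SearchTerm,
    config: ExtractionConfig,
    allow_gene_key: bool = False,
) -> tuple[str, str] | None:
    """Return (matched_synonym, matched_qualifier) or None."""
    ftype = row.feature_type.lower()
    key = feature.key.lower()
    key_ok = key == ftype
    if allow_gene_key and key == "gene" and ftype in ("cds", "trna", "rrna", "misc_rna"):
        key_ok = True
    if not key_ok:
        return None
    if ftype in ("intron", "exon"):
        number = feature.first_qualifier("number")
        if number is None or number.strip() != str(row.intron_exon_number):
            return None
        if not row.name:
            return ("", "number")
    elif ftype == "d-loop" and not row.name:
        return ("", "key")
    if row.name:
        for qual in config.qualifier_search_order:
            for value in feature.qualifier_values(qual):
                if _value_matches(value, row.name, config.match_mode):
                    return (row.name, qual)
        if ftype == "d-loop":
            # D-loop rows also match on feature key alone
            return (row.name, "key")
        return None
    return ("", "key")


def match_feature(
    feature: Feature,
    table: SearchTermTable,
    config: ExtractionConfig | None = None,
    allow_gene_key: bool = False,
) -> MatchResult | None:
    """First search-term row the feature satisfies, or None.

    A row matches when the feature key equals the row's feature type
    (case-insensitive) and, for named rows, the synonym matches a
    qualifier value in the configured search order.  D-loop rows also
    match D-loop features by key alone; intron/exon rows additionally
    require the ``number`` qualifier to equal the row's ordinal.
    """
    config = config or ExtractionConfig()
    if feature.key.lower() in _NON_MATCHABLE_KEYS:
        return None
    for row in table.rows:
        if config.loci_filter is not None and row.locus not in config.loci_filter:
            continue
        hit = _row_matches(feature, row, config, allow_gene_key=allow_gene_key)
        if hit is not None:
            synonym, qualifier = hit
            return MatchResult(
                locus=row.locus,
                matched_synonym=synonym,
                matched_qualifier=qualifier,
                row=row,
            )
    return None


def extract_intron_exon(
    record: GenBankRecord,
    row: SearchTerm,
    config: ExtractionConfig | None = None,
) -> ExtractedSequence | None:
    """Extract the intron/exon a single search-term row describes."""
    if row.feature_type.lower() not in ("intron", "exon"):
        raise ValueError("row must have feature type intron or exon")
    if row.intron_exon_number is None:
        raise ValueError("intron/exon row lacks IntronExonNumber")
    config = config or ExtractionConfig()
    for feature in record.features:
        hit = _row_matches(feature, row, config)
        if hit is None or feature.location is None:
            continue
        try:
            seq = resolve_location(record, feature.location)
        except OutOfBoundsError:
            continue
        return ExtractedSequence(
            locus=row.locus,
            accession=record.label,
            organism=record.organism,
            sequence=seq,
            feature_key=feature.key,
            matched_synonym=hit[0],
            matched_qualifier=hit[1],
            partial=feature.location.is_partial,
        )
    return None


# ---------------------------------------------------------------------------
# record extraction

def requested_loci(table: SearchTermTable, config: ExtractionConfig) -> list[str]:
    """The loci a run asks for: the table's loci, optionally filtered.

    Filter names absent from the table are still requested (and will
    report ``not_found``), appended in sorted order.
    """
    loci = table.loci()
    if config.loci_filter is None:
        return loci
    requested = [l for l in loci if l in config.loci_filter]
    requested.extend(sorted(config.loci_filter - set(loci)))
    return requested


def extract_record(
    record: GenBankRecord,
    table: SearchTermTable,
    config: ExtractionConfig | None = None,
) -> tuple[list[ExtractedSequence], ExtractionReport]:
    """Extract every requested locus from one record.

    Features are matched in record order; with ``duplicates`` disabled
    only the first match per locus is kept.  Features with key ``gene``
    are consulted only for loci no CDS/tRNA/rRNA/misc_RNA feature
    matched, so a CDS and its enclosing gene never extract twice.
    """
    config = config or ExtractionConfig()
    requested = requested_loci(table, config)
    report = ExtractionReport()
    acc = record.label

    matched: dict[str, list[tuple[Feature, MatchResult]]] = {l: [] for l in requested}
    for feature in record.features:
        if feature.key.lower() == "gene":
            continue
        m = match_feature(feature, table, config)
        if m is not None and m.locus in matched:
            matched[m.locus].append((feature, m))
    # fallback: bare gene features for loci nothing else matched
    empty_loci = {l for l, hits in matched.items() if not hits}
    if empty_loci:
        for feature in record.features:
            if feature.key.lower() != "gene":
                continue
            m = match_feature(feature, table, config, allow_gene_key=True)
            if m is not None and m.locus in empty_loci:
                matched[m.locus].append((feature, m))

    extracted: list[ExtractedSequence] = []
    for locus in requested:
        hits = matched[locus]
        if not config.duplicates:
            hits = hits[:1]
        status = STATUS_NOT_FOUND
        copy_index = 0
        for feature, m in hits:
            if feature.location is None:
                if status != STATUS_FOUND:
                    status = STATUS_UNPARSEABLE
                report.add_note(
                    acc, locus, f"feature {feature.key} has unparseable location "
                    f"{feature.location_text!r}"
                )
                continue
            try:
                seq = resolve_location(record, feature.location)
            except OutOfBoundsError as exc:
                if status != STATUS_FOUND:
                    status = STATUS_OUT_OF_BOUNDS
                report.add_note(acc, locus, f"feature {feature.key}: {exc}")
                continue
            was_translated = False
            if (
                config.translate
                and m.row.feature_type.lower() == "cds"
                and feature.key.lower() in ("cds", "gene")
            ):
                table_number = config.default_translation_table
                tt = feature.first_qualifier("transl_table")
                if tt and tt.strip().isdigit() and int(tt) in GENETIC_CODES:
                    table_number = int(tt)
                cs_raw = feature.first_qualifier("codon_start")
                codon_start = (
                    int(cs_raw) if cs_raw and cs_raw.strip() in ("1", "2", "3") else 1
                )
                result = translate(seq, table_number, codon_start)
                if result.peptide:
                    if result.internal_stop:
                        report.add_note(
                            acc, locus, "internal stop codon(s) in translation"
                        )
                    seq = result.peptide
                    was_translated = True
                else:
                    report.add_note(
                        acc, locus, "translation produced empty peptide; "
                        "emitting untranslated sequence"
                    )
            copy_index += 1
            status = STATUS_FOUND
            extracted.append(
                ExtractedSequence(
                    locus=locus,
                    accession=acc,
                    organism=record.organism,
                    sequence=seq,
                    copy_index=copy_index,
                    was_translated=was_translated,
                    feature_key=feature.key,
                    matched_synonym=m.matched_synonym,
                    matched_qualifier=m.matched_qualifier,
                    partial=feature.location.is_partial,
                )
            )
        report.set_status(acc, locus, status)
    return extracted, report


def extract_records(
    records: list[GenBankRecord],
    table: SearchTermTable,
    config: ExtractionConfig | None = None,
) -> tuple[list[ExtractedSequence], ExtractionReport]:
    """Extract all requested loci from many records; statuses are merged."""
    config = config or ExtractionConfig()
    all_extracted: list[ExtractedSequence] = []
    report = ExtractionReport()
    for record in records:
        extracted, rec_report = extract_record(record, table, config)
        all_extracted.extend(extracted)
        report.merge(rec_report)
    return all_extracted, report
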