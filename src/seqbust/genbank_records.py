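"""GenBank flat-file records: parsing, writing, and feature-location resolution.

Coordinates follow the GenBank convention throughout: 1-based, inclusive
on both ends.  Sequences are canonicalized to lowercase on parse.

The feature-location grammar supported here is the INSDC subset needed
for gene extraction::

    467
    340..565
    <1..206            (partial on the low end)
    4821..>5028        (partial on the high end)
    complement(30..60)
    join(12..78,134..202)
    order(1..10,20..30)             -- treated as join
    complement(join(...)), join(complement(...),...)

Between-base positions (``122^123``) and remote references
(``J00194.1:100..202``) are rejected with an explicit error rather than
silently skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class GenBankError(Exception):
    """Base class for errors raised by this module."""


class LocationParseError(GenBankError):
    """A feature-location string could not be decoded."""


class UnsupportedLocationError(LocationParseError):
    """The location uses a grammar form that is deliberately unsupported."""


class OutOfBoundsError(GenBankError):
    """A location interval falls outside the record's sequence."""


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive span, with partial-end markers kept as flags."""

    start: int
    end: int
    partial_start: bool = False
    partial_end: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}..{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


PLUS = "+"
MINUS = "-"


@dataclass
class Location:
    """An ordered, strand-aware segment list decoded from a location string.

    ``segments`` are listed in assembly order: resolving the location
    means extracting each segment (reverse-complementing minus-strand
    segments) and concatenating in list order.  ``complement(join(...))``
    is normalized at parse time into reversed, strand-flipped segments,
    which yields the same resolved sequence.
    """

    segments: list[tuple[Interval, str]]
    is_order: bool = False
    raw_text: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("Location must have at least one segment")

    @property
    def span(self) -> int:
        return sum(iv.span for iv, _ in self.segments)

    @property
    def is_partial(self) -> bool:
        return any(iv.partial_start or iv.partial_end for iv, _ in self.segments)

    @property
    def max_end(self) -> int:
        return max(iv.end for iv, _ in self.segments)


@dataclass
class Feature:
    """One entry of a FEATURES table.

    ``location`` is ``None`` when the location string could not be
    decoded; ``location_text`` always holds the raw string.  Qualifier
    names are stored without the leading slash, in file order, repeats
    permitted.
    """

    key: str
    location: Location | None
    qualifiers: list[tuple[str, str]] = field(default_factory=list)
    location_text: str = ""

    def qualifier_values(self, name: str) -> list[str]:
        return [v for n, v in self.qualifiers if n == name]

    def first_qualifier(self, name: str) -> str | None:
        for n, v in self.qualifiers:
            if n == name:
                return v
        return None


@dataclass
class GenBankRecord:
    accession: str
    version: str = ""
    definition: str = ""
    organism: str = ""
    sequence: str = ""
    declared_length: int = 0
    features: list[Feature] = field(default_factory=list)

    @property
    def label(self) -> str:
        """Versioned accession when available, else bare accession."""
        return self.version or self.accession


@dataclass(frozen=True)
class ParseIssue:
    severity: str  # "warning" | "error"
    message: str
    line: int = 1

    def __post_init__(self) -> None:
        if self.severity not in ("warning", "error"):
            raise ValueError(f"bad severity {self.severity!r}")
        if self.line < 1:
            raise ValueError("line must be >= 1")


# ---------------------------------------------------------------------------
# reverse complement

_COMPLEMENT = "tgcaakywsrmbdhvn"
_BASES = "acgtumrwsykvhdbn"
_COMP_TABLE = str.maketrans(
    _BASES + _BASES.upper(), _COMPLEMENT + _COMPLEMENT.upper()
)
_IUPAC = frozenset(_BASES + _BASES.upper())


def reverse_complement(seq: str) -> str:
    """Reverse-complement a IUPAC nucleotide string (case preserved)."""
    for i, ch in enumerate(seq):
        if ch not in _IUPAC:
            raise ValueError(
                f"non-IUPAC character {ch!r} at offset {i} in sequence"
            )
    return seq.translate(_COMP_TABLE)[::-1]


# ---------------------------------------------------------------------------
# location grammar

_SPAN_RE = re.compile(r"(<?)(\d+)(?:\.\.(>?)(\d+))?$")


def parse_location(text: str) -> Location:
    """Decode an INSDC feature-location string into a :class:`Location`.

    Raises :class:`LocationParseError` on unrecognized tokens and
    :class:`UnsupportedLocationError` for between-base (``^``) and
    remote-accession forms.
    """
    raw = text.strip()
    if not raw:
        raise LocationParseError("empty location string")
    # whitespace inside multi-line locations is insignificant
    compact = re.sub(r"\s+", "", raw)
    segments, is_order = _parse_expr(compact)
    return Location(segments=segments, is_order=is_order, raw_text=raw)


def _split_args(text: str) -> list[str]:
    """Split a join/order argument list on top-level commas."""
    parts: list[str] = []
    depth = 0
    cur: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise LocationParseError(f"unbalanced parentheses in {text!r}")
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise LocationParseError(f"unbalanced parentheses in {text!r}")
    parts.append("".join(cur))
    return parts


def _parse_expr(text: str) -> tuple[list[tuple[Interval, str]], bool]:
    if text.startswith("complement(") and text.endswith(")"):
        inner, is_order = _parse_expr(text[len("complement(") : -1])
        # complement of an assembly = reverse segment order, flip strands
        flipped = [
            (iv, MINUS if strand == PLUS else PLUS)
            for iv, strand in reversed(inner)
        ]
        return flipped, is_order
    for op in ("join", "order"):
        prefix = op + "("
        if text.startswith(prefix) and text.endswith(")"):
            segments: list[tuple[Interval, str]] = []
            any_order = op == "order"
            args = _split_args(text[len(prefix) : -1])
            if args == [""]:
                raise LocationParseError(f"empty {op}() in location")
            for arg in args:
                sub, sub_order = _parse_expr(arg)
                segments.extend(sub)
                any_order = any_order or sub_order
            return segments, any_order
    return [(_parse_span(text), PLUS)], False


def _parse_span(text: str) -> Interval:
    if "^" in text:
        raise UnsupportedLocationError(
            f"between-base location {text!r} is not supported"
        )
    if ":" in text:
        raise UnsupportedLocationError(
            f"remote-accession location {text!r} is not supported"
        )
    m = _SPAN_RE.match(text)
    if not m:
        raise LocationParseError(f"unrecognized location token {text!r}")
    lt, start_s, gt, end_s = m.groups()
    start = int(start_s)
    if end_s is None:
        return Interval(start, start, partial_start=bool(lt))
    end = int(end_s)
    if start > end:
        raise LocationParseError(
            f"interval start exceeds end in {text!r}"
        )
    return Interval(start, end, partial_start=bool(lt), partial_end=bool(gt))


def resolve_location(record: "GenBankRecord | str", loc: Location) -> str:
    """Extract the subsequence a location describes.

    ``record`` may be a :class:`GenBankRecord` or a plain sequence
    string.  Each segment is sliced 1-based inclusive, minus-strand
    segments are reverse-complemented, and the pieces are concatenated
    in assembly order.
    """
    seq = record.sequence if isinstance(record, GenBankRecord) else record
    n = len(seq)
    pieces: list[str] = []
    for iv, strand in loc.segments:
        if iv.end > n:
            raise OutOfBoundsError(
                f"interval {iv.start}..{iv.end} exceeds sequence length {n}"
            )
        piece = seq[iv.start - 1 : iv.end]
        if strand == MINUS:
            piece = reverse_complement(piece)
        pieces.append(piece)
    return "".join(pieces)


# ---------------------------------------------------------------------------
# flat-file parsing

_LOCUS_LEN_RE = re.compile(r"\s(\d+)\s+bp\b")
_FEATURE_KEY_RE = re.compile(r"^ {5}(\S+)\s+(\S.*)$")
_QUAL_RE = re.compile(r"^/([\w'\-*]+)(?:=(.*))?$", re.S)


def parse_flatfile(stream: str) -> tuple[list[GenBankRecord], list[ParseIssue]]:
    """Parse GenBank flat-file text into records plus a list of issues.

    Malformed content never silently drops a record or feature: every
    problem surfaces as a :class:`ParseIssue` (severity ``error`` for
    structural problems, ``warning`` for recoverable oddities).
    """
    records: list[GenBankRecord] = []
    issues: list[ParseIssue] = []
    lines = stream.splitlines()
    chunk: list[tuple[int, str]] = []
    terminated = True
    for lineno, line in enumerate(lines, start=1):
        if line.strip() == "//":
            if chunk:
                rec = _parse_entry(chunk, issues)
                if rec is not None:
                    records.append(rec)
            chunk = []
            terminated = True
        else:
            if line.strip():
                terminated = False
            chunk.append((lineno, line))
    if not terminated and any(l.strip() for _, l in chunk):
        issues.append(
            ParseIssue(
                "error",
                "record not terminated by '//'; parsed best-effort",
                chunk[0][0],
            )
        )
        rec = _parse_entry(chunk, issues)
        if rec is not None:
            records.append(rec)
    return records, issues


def _parse_entry(
    chunk: list[tuple[int, str]], issues: list[ParseIssue]
) -> GenBankRecord | None:
    first_line = chunk[0][0]
    rec = GenBankRecord(accession="")
    i = 0
    n = len(chunk)
    in_features = False
    in_origin = False
    seq_parts: list[str] = []
    pending_definition: list[str] = []
    section = ""
    while i < n:
        lineno, line = chunk[i]
        if not line.strip():
            i += 1
            continue
        if not in_features and not in_origin:
            keyword = line[:12].strip()
            rest = line[12:].strip()
            if keyword:
                section = keyword
            if keyword == "LOCUS":
                m = _LOCUS_LEN_RE.search(line)
                if m:
                    rec.declared_length = int(m.group(1))
                else:
                    issues.append(
                        ParseIssue("warning", "LOCUS line lacks a length", lineno)
                    )
                if not rec.accession:
                    toks = line.split()
                    if len(toks) > 1:
                        rec.accession = toks[1]
            elif keyword == "DEFINITION":
                pending_definition = [rest]
            elif keyword == "ACCESSION":
                rec.accession = rest.split()[0] if rest else rec.accession
            elif keyword == "VERSION":
                rec.version = rest.split()[0] if rest else ""
            elif keyword == "FEATURES":
                in_features = True
                i += 1
                continue
            elif keyword == "ORIGIN":
                in_origin = True
                i += 1
                continue
            elif keyword == "" and section == "DEFINITION":
                pending_definition.append(rest)
            elif line.startswith("  ORGANISM"):
                rec.organism = line[12:].strip()
                section = "ORGANISM"
            i += 1
            continue
        if in_features:
            if line[:5].strip():  # a new top-level keyword ends FEATURES
                in_features = False
                continue
            m = _FEATURE_KEY_RE.match(line)
            if m:
                key, loc_start = m.groups()
                loc_lines = [loc_start.strip()]
                i += 1
                # location continuations: lines at qualifier indent that
                # do not begin a qualifier
                while i < n:
                    _, nxt = chunk[i]
                    body = nxt[21:] if len(nxt) > 21 else nxt.strip()
                    if (
                        nxt.startswith(" " * 21)
                        and body
                        and not body.startswith("/")
                        and not _FEATURE_KEY_RE.match(nxt)
                    ):
                        loc_lines.append(body.strip())
                        i += 1
                    else:
                        break
                feature = Feature(
                    key=key, location=None, location_text="".join(loc_lines)
                )
                try:
                    feature.location = parse_location(feature.location_text)
                    if feature.location.is_order:
                        issues.append(
                            ParseIssue(
                                "warning",
                                f"order(...) location treated as join for "
                                f"feature {key} at line {lineno}",
                                lineno,
                            )
                        )
                except LocationParseError as exc:
                    issues.append(
                        ParseIssue(
                            "error",
                            f"unparseable location for feature {key}: {exc}",
                            lineno,
                        )
                    )
                i = _parse_qualifiers(chunk, i, feature, issues)
                rec.features.append(feature)
                continue
            issues.append(
                ParseIssue("error", f"malformed feature line: {line.strip()!r}", lineno)
            )
            i += 1
            continue
        if in_origin:
            stripped = line.strip()
            if stripped and stripped[0].isdigit():
                seq_parts.append(re.sub(r"[\d\s]", "", line))
            elif stripped:
                issues.append(
                    ParseIssue("error", f"unexpected line in ORIGIN: {stripped!r}", lineno)
                )
            i += 1
            continue
    rec.definition = " ".join(p for p in pending_definition if p).strip()
    rec.sequence = "".join(seq_parts).lower()
    if not rec.accession:
        issues.append(ParseIssue("error", "record has no accession", first_line))
        rec.accession = f"UNKNOWN_L{first_line}"
    if rec.declared_length and rec.declared_length != len(rec.sequence):
        issues.append(
            ParseIssue(
                "error",
                f"declared length {rec.declared_length} != sequence length "
                f"{len(rec.sequence)} in {rec.accession}",
                first_line,
            )
        )
    if not rec.declared_length:
        rec.declared_length = len(rec.sequence)
    for feat in rec.features:
        if feat.location is not None and rec.sequence:
            if feat.location.max_end > len(rec.sequence):
                issues.append(
                    ParseIssue(
                        "error",
                        f"feature {feat.key} at {feat.location_text} exceeds "
                        f"sequence length {len(rec.sequence)} in {rec.accession}",
                        first_line,
                    )
                )
    return rec


def _parse_qualifiers(
    chunk: list[tuple[int, str]],
    i: int,
    feature: Feature,
    issues: list[ParseIssue],
) -> int:
    """Consume qualifier lines for one feature; return the next index."""
    n = len(chunk)
    while i < n:
        lineno, line = chunk[i]
        if not line.startswith(" " * 21) or _FEATURE_KEY_RE.match(line):
            break
        body = line[21:]
        if not body.startswith("/"):
            break
        # accumulate continuation lines until quotes balance
        text = body
        while text.count('"') % 2 == 1:
            i += 1
            if i >= n:
                issues.append(
                    ParseIssue("error", "unterminated quoted qualifier value", lineno)
                )
                break
            _, cont = chunk[i]
            cont_body = cont[21:]
            joiner = "" if text.startswith("/translation") else " "
            text = text + joiner + cont_body.strip()
        m = _QUAL_RE.match(text)
        if not m:
            issues.append(
                ParseIssue("error", f"malformed qualifier: {text!r}", lineno)
            )
            i += 1
            continue
        name, value = m.groups()
        if value is None:
            value = ""
        else:
            value = value.strip()
            if value.startswith('"') and value.endswith('"') and len(value) >= 2:
                value = value[1:-1]
        feature.qualifiers.append((name, value))
        i += 1
    return i


# ---------------------------------------------------------------------------
# flat-file writing

_ORIGIN_LINE_BASES = 60


def write_flatfile(records: list[GenBankRecord]) -> str:
    """Serialize records to canonical GenBank flat-file text.

    The output round-trips through :func:`parse_flatfile` with zero
    issues.  Records violating their invariants (length mismatch,
    out-of-bounds or unparsed locations, empty feature keys) are
    refused.
    """
    out: list[str] = []
    for rec in records:
        _check_writable(rec)
        seq = rec.sequence.lower()
        out.append(
            f"LOCUS       {rec.accession:<17} {len(seq)} bp    DNA     "
            "linear   UNK 01-JAN-1980"
        )
        if rec.definition:
            out.append(f"DEFINITION  {rec.definition}")
        out.append(f"ACCESSION   {rec.accession}")
        if rec.version:
            out.append(f"VERSION     {rec.version}")
        if rec.organism:
            out.append(f"SOURCE      {rec.organism}")
            out.append(f"  ORGANISM  {rec.organism}")
        out.append("FEATURES             Location/Qualifiers")
        for feat in rec.features:
            out.append(f"     {feat.key:<16}{feat.location_text or feat.location.raw_text}")
            for name, value in feat.qualifiers:
                if value == "":
                    out.append(" " * 21 + f"/{name}")
                else:
                    out.append(" " * 21 + f'/{name}="{value}"')
        out.append("ORIGIN")
        for start in range(0, len(seq), _ORIGIN_LINE_BASES):
            blocks = [
                seq[j : j + 10]
                for j in range(start, min(start + _ORIGIN_LINE_BASES, len(seq)), 10)
            ]
            out.append(f"{start + 1:>9} " + " ".join(blocks))
        out.append("//")
    if not records:
        return ""
    return "\n".join(out) + "\n"


def _check_writable(rec: GenBankRecord) -> None:
    if not rec.accession:
        raise ValueError("record has no accession")
    if rec.declared_length and rec.declared_length != len(rec.sequence):
        raise ValueError(
            f"{rec.accession}: declared length {rec.declared_length} != "
            f"sequence length {len(rec.sequence)}"
        )
    for feat in rec.features:
        if not feat.key:
            raise ValueError(f"{rec.accession}: feature with empty key")
        if feat.location is None:
            raise ValueError(
                f"{rec.accession}: feature {feat.key} has no parsed location"
            )
        if feat.location.max_end > len(rec.sequence):
            raise ValueError(
                f"{rec.accession}: feature {feat.key} at "
                f"{feat.location_text} exceeds sequence bounds"
            )
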