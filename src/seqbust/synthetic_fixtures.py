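"""Deterministic GenBank fixture generation with a ground-truth manifest.

Given a search-term table, :func:`generate_fixture` emits flat-file
records that plant one feature per locus (plus optional duplicates and
near-miss decoys) across both strands, spliced and trans-spliced
locations, and partial coordinates.  The manifest records, for every
planted feature, the exact subsequence a correct extractor must
recover, so recovery can be checked byte-for-byte with no downloads.

All randomness flows from one seeded ``random.Random``; the same spec
and seed always produce byte-identical output.
"""

from __future__ import annotations

import json
import random
from collections import defaultdict
from dataclasses import dataclass, field, asdict

from seqbust.extraction import GENETIC_CODES, ExtractionConfig, match_feature
from seqbust.genbank_records import (
    Feature,
    GenBankRecord,
    parse_flatfile,
    parse_location,
    resolve_location,
    reverse_complement,
    write_flatfile,
)
from seqbust.search_terms import SearchTerm, SearchTermTable, _TYPE_BY_FOLD

DEGRADE_MODES = ("strip_positions", "drop_feature", "drop_dloop")

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    loci: SearchTermTable
    seed: int = 0
    n_records: int = 1
    sequence_length_range: tuple[int, int] = (400, 6000)
    minus_strand_fraction: float = 0.0
    join_fraction: float = 0.0
    trans_splice_fraction: float = 0.0
    partial_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    decoy_fraction: float = 0.0
    synonym_choice: str = "random"  # "random" | "first" | "cycle"
    transl_table: int = 1
    n_species: int | None = None

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        for name in (
            "minus_strand_fraction",
            "join_fraction",
            "trans_splice_fraction",
            "partial_fraction",
            "duplicate_fraction",
            "decoy_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.trans_splice_fraction + self.join_fraction > 1.0:
            raise ValueError("join_fraction + trans_splice_fraction exceeds 1")
        if self.synonym_choice not in ("random", "first", "cycle"):
            raise ValueError(f"unknown synonym_choice {self.synonym_choice!r}")
        if self.transl_table not in GENETIC_CODES:
            raise ValueError(f"undefined translation table {self.transl_table}")
        lo, hi = self.sequence_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad sequence_length_range")


@dataclass
class PlantedFeature:
    accession: str
    locus: str
    location: str
    strands: list[str]
    synonym: str
    qualifier: str
    subsequence: str
    feature_key: str
    copy_index: int = 1
    peptide: str | None = None
    transl_table: int | None = None


@dataclass
class GroundTruthManifest:
    entries: list[PlantedFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def by_accession_locus(self) -> dict[tuple[str, str], list[PlantedFeature]]:
        out: dict[tuple[str, str], list[PlantedFeature]] = defaultdict(list)
        for entry in self.entries:
            out[(entry.accession, entry.locus)].append(entry)
        return dict(out)

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.entries], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(entries=[PlantedFeature(**d) for d in json.loads(text)])


def _safe_rows(table: SearchTermTable) -> dict[str, list[SearchTerm]]:
    """Per locus, the rows whose synonym first-matches back to that locus.

    Planting a feature annotated with an ambiguous synonym (one an
    earlier row of a different locus would claim first) would make exact
    recovery untestable, so such rows are never used for planting.
    """
    config = ExtractionConfig()
    safe: dict[str, list[SearchTerm]] = defaultdict(list)
    for row in table.rows:
        key = _TYPE_BY_FOLD.get(row.feature_type.lower(), row.feature_type)
        quals: list[tuple[str, str]] = []
        if row.intron_exon_number is not None:
            quals.append(("number", str(row.intron_exon_number)))
        if row.name:
            quals.append(("gene", row.name))
        probe = Feature(key=key, location=None, qualifiers=quals)
        m = match_feature(probe, table, config)
        if m is not None and m.locus == row.locus:
            safe[row.locus].append(row)
    return dict(safe)


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("acgt") for _ in range(n))


def _random_cds(
    rng: random.Random, table_number: int, n_codons: int
) -> tuple[str, str]:
    """A CDS starting atg and ending in a stop valid under the code."""
    code = GENETIC_CODES[table_number]
    by_aa: dict[str, list[str]] = defaultdict(list)
    for codon, aa in sorted(code.items()):
        by_aa[aa].append(codon)
    aas = ["M"] + [rng.choice(_AA_ALPHABET) for _ in range(n_codons)]
    codons = [rng.choice(by_aa[aa]) for aa in aas]
    codons[0] = "atg"
    codons.append(rng.choice(by_aa["*"]))
    return "".join(codons), "".join(aas)


@dataclass
class _Placement:
    """One planted feature before genome assembly."""

    row: SearchTerm
    gene_seq: str
    peptide: str | None
    transl_table: int | None
    assembly: list[tuple[str, str]]  # (assembly-order content, strand)
    genome_order: list[int]  # permutation: genome slot -> assembly index
    complement_join: bool  # emit complement(join(...)) form
    partial_start: bool
    partial_end: bool
    qualifier: str


def _plan_feature(
    rng: random.Random, row: SearchTerm, spec: FixtureSpec
) -> _Placement:
    ftype = row.feature_type.lower()
    peptide: str | None = None
    transl_table: int | None = None
    if ftype == "cds":
        transl_table = spec.transl_table
        gene_seq, peptide = _random_cds(rng, transl_table, rng.randint(8, 24))
    elif ftype in ("trna",):
        gene_seq = _random_dna(rng, rng.randint(24, 60))
    else:
        gene_seq = _random_dna(rng, rng.randint(40, 120))

    u = rng.random()
    trans_spliced = u < spec.trans_splice_fraction
    joined = trans_spliced or u < spec.trans_splice_fraction + spec.join_fraction
    minus = rng.random() < spec.minus_strand_fraction

    if joined and len(gene_seq) >= 6:
        cut = rng.randint(2, len(gene_seq) - 2)
        parts = [gene_seq[:cut], gene_seq[cut:]]
    else:
        joined = False
        trans_spliced = False
        parts = [gene_seq]

    if trans_spliced:
        strands = ["+", "-"] if rng.random() < 0.5 else ["-", "+"]
    else:
        strands = ["-" if minus else "+"] * len(parts)

    assembly = list(zip(parts, strands))
    complement_join = joined and all(s == "-" for s in strands) and rng.random() < 0.5
    if complement_join:
        # genome order is the reverse of assembly order for this form
        genome_order = list(range(len(parts) - 1, -1, -1))
    elif trans_spliced and rng.random() < 0.5:
        genome_order = list(range(len(parts) - 1, -1, -1))
    else:
        genome_order = list(range(len(parts)))

    partial = rng.random() < spec.partial_fraction
    partial_start = partial and rng.random() < 0.75
    partial_end = partial and not partial_start or (partial and rng.random() < 0.3)

    qualifier = "gene"
    if row.name and ftype not in ("intron", "exon"):
        qualifier = rng.choice(("gene", "product"))
    return _Placement(
        row=row,
        gene_seq=gene_seq,
        peptide=peptide,
        transl_table=transl_table,
        assembly=assembly,
        genome_order=genome_order,
        complement_join=complement_join,
        partial_start=partial_start,
        partial_end=partial_end,
        qualifier=qualifier,
    )


def _realize(
    placement: _Placement, cursor: int, rng: random.Random
) -> tuple[list[str], list[tuple[int, int]], str, int]:
    """Lay a planned feature into the genome starting after ``cursor``.

    Returns (genome chunks, intervals in genome order, location string,
    new cursor).
    """
    chunks: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = cursor
    n_parts = len(placement.assembly)
    if placement.complement_join:
        whole = reverse_complement(placement.gene_seq)
        cut = len(placement.assembly[1][0])  # genome slot 0 holds part 2's bases
        genome_contents = [whole[:cut], whole[cut:]]
    else:
        genome_contents = [None] * n_parts
        for slot, idx in enumerate(placement.genome_order):
            content, strand = placement.assembly[idx]
            genome_contents[slot] = (
                content if strand == "+" else reverse_complement(content)
            )
    for content in genome_contents:
        gap = rng.randint(5, 15)
        chunks.append(_random_dna(rng, gap))
        pos += gap
        start = pos + 1
        chunks.append(content)
        pos += len(content)
        intervals.append((start, pos))
    # interval for each assembly index
    if placement.complement_join:
        inner = [
            f"{s}..{e}" for s, e in intervals
        ]
        inner = _apply_partials(inner, placement)
        loc = f"complement(join({','.join(inner)}))"
    else:
        slot_of = {idx: slot for slot, idx in enumerate(placement.genome_order)}
        spans: list[str] = []
        wraps: list[bool] = []
        for idx, (_, strand) in enumerate(placement.assembly):
            s, e = intervals[slot_of[idx]]
            spans.append(f"{s}..{e}")
            wraps.append(strand == "-")
        elems = _apply_partials(spans, placement, wrap=wraps)
        if len(elems) == 1:
            loc = elems[0]
        else:
            loc = f"join({','.join(elems)})"
    return chunks, intervals, loc, pos


def _apply_partials(
    spans: list[str], placement: _Placement, wrap: list[bool] | None = None
) -> list[str]:
    out = list(spans)
    if placement.partial_start:
        out[0] = "<" + out[0]
    if placement.partial_end:
        a, _, b = out[-1].rpartition("..")
        out[-1] = f"{a}..>{b}" if a else out[-1]
    if wrap is not None:
        out = [f"complement({s})" if w else s for s, w in zip(out, wrap)]
    return out


def _decoy_name(rng: random.Random, table: SearchTermTable, taken: set[str]) -> str:
    """A near-miss name: a superstring of a real synonym, never equal to one."""
    names = [r.name for r in table.rows if r.name]
    for _ in range(100):
        base = rng.choice(names)
        suffix = rng.choice(("I", "X", "2-like", " pseudogene", "-like", "B"))
        candidate = base + suffix
        if candidate.strip().lower() not in taken:
            return candidate
    raise RuntimeError("could not synthesize a decoy name")


def generate_fixture(spec: FixtureSpec) -> tuple[str, GroundTruthManifest]:
    """Emit flat-file text plus the manifest of every planted feature."""
    rng = random.Random(spec.seed)
    table = spec.loci
    safe = _safe_rows(table)
    loci = [l for l in table.loci() if safe.get(l)]
    unplantable = [l for l in table.loci() if not safe.get(l)]
    if unplantable:
        raise ValueError(
            "no unambiguous synonym row to plant for loci: " + ", ".join(unplantable)
        )
    synonym_names = {
        r.name.strip().lower() for r in table.rows if r.name
    }
    n_species = spec.n_species or max(1, (spec.n_records * 3) // 4)
    species = [
        f"Genus_{(j % 7) + 1} species_{j + 1}" for j in range(n_species)
    ]
    cycle_counters: dict[str, int] = defaultdict(int)

    records: list[GenBankRecord] = []
    manifest = GroundTruthManifest()
    min_len, max_len = spec.sequence_length_range
    for i in range(spec.n_records):
        accession = f"SB{i + 1:06d}"
        version = f"{accession}.1"
        organism = species[i % n_species]
        chunks: list[str] = []
        cursor = 0
        planted: list[tuple[int, Feature, PlantedFeature]] = []
        for locus in loci:
            rows = safe[locus]
            n_copies = 1 + (1 if rng.random() < spec.duplicate_fraction else 0)
            for _ in range(n_copies):
                if spec.synonym_choice == "first":
                    row = rows[0]
                elif spec.synonym_choice == "cycle":
                    row = rows[cycle_counters[locus] % len(rows)]
                    cycle_counters[locus] += 1
                else:
                    row = rng.choice(rows)
                placement = _plan_feature(rng, row, spec)
                new_chunks, intervals, loc_text, cursor = _realize(
                    placement, cursor, rng
                )
                chunks.extend(new_chunks)
                key = _TYPE_BY_FOLD.get(
                    row.feature_type.lower(), row.feature_type
                )
                quals: list[tuple[str, str]] = []
                if row.intron_exon_number is not None:
                    quals.append(("number", str(row.intron_exon_number)))
                if row.name:
                    quals.append((placement.qualifier, row.name))
                if placement.transl_table is not None:
                    quals.append(("transl_table", str(placement.transl_table)))
                    quals.append(("codon_start", "1"))
                feature = Feature(
                    key=key,
                    location=parse_location(loc_text),
                    qualifiers=quals,
                    location_text=loc_text,
                )
                entry = PlantedFeature(
                    accession=version,
                    locus=locus,
                    location=loc_text,
                    strands=[s for _, s in placement.assembly],
                    synonym=row.name,
                    qualifier=placement.qualifier if row.name else (
                        "number" if row.intron_exon_number is not None else "key"
                    ),
                    subsequence=placement.gene_seq,
                    feature_key=key,
                    peptide=placement.peptide,
                    transl_table=placement.transl_table,
                )
                planted.append((intervals[0][0], feature, entry))
        # decoys: near-miss names that must never be extracted
        n_decoys = sum(
            1 for _ in loci if rng.random() < spec.decoy_fraction
        )
        for _ in range(n_decoys):
            name = _decoy_name(rng, table, synonym_names)
            decoy_key = rng.choice(("CDS", "misc_feature", "gene"))
            gap = rng.randint(5, 15)
            chunks.append(_random_dna(rng, gap))
            cursor += gap
            length = rng.randint(24, 60)
            start = cursor + 1
            chunks.append(_random_dna(rng, length))
            cursor += length
            loc_text = f"{start}..{cursor}"
            feature = Feature(
                key=decoy_key,
                location=parse_location(loc_text),
                qualifiers=[(rng.choice(("gene", "product")), name)],
                location_text=loc_text,
            )
            planted.append((start, feature, None))
        if cursor > max_len:
            raise ValueError(
                f"planted features need {cursor} bases but "
                f"sequence_length_range caps at {max_len}"
            )
        total = rng.randint(max(min_len, cursor), max_len)
        chunks.append(_random_dna(rng, total - cursor))
        sequence = "".join(chunks)
        assert len(sequence) == total

        planted.sort(key=lambda t: t[0])
        features = [
            Feature(
                key="source",
                location=parse_location(f"1..{total}"),
                qualifiers=[("organism", organism)],
                location_text=f"1..{total}",
            )
        ]
        copy_counter: dict[str, int] = defaultdict(int)
        for _, feature, entry in planted:
            features.append(feature)
            if entry is not None:
                copy_counter[entry.locus] += 1
                entry.copy_index = copy_counter[entry.locus]
                manifest.entries.append(entry)
        record = GenBankRecord(
            accession=accession,
            version=version,
            definition=f"{organism} synthetic fixture record",
            organism=organism,
            sequence=sequence,
            declared_length=total,
            features=features,
        )
        # self-consistency: each planted subsequence must re-resolve exactly
        for _, feature, entry in planted:
            if entry is None:
                continue
            resolved = resolve_location(record, feature.location)
            if resolved != entry.subsequence:
                raise RuntimeError(
                    f"fixture self-check failed for {entry.locus} at "
                    f"{entry.location} in {version}"
                )
        records.append(record)
    return write_flatfile(records), manifest


def degrade_fixture(
    flatfile: str, mode: str, feature_key: str | None = None
) -> str:
    """Rewrite a fixture emulating real-world annotation deficits.

    ``strip_positions`` drops every per-gene feature, leaving a single
    source-spanning feature whose note merely names the genes;
    ``drop_dloop`` removes D-loop features; ``drop_feature`` removes
    features whose key equals ``feature_key``.
    """
    if mode not in DEGRADE_MODES:
        raise ValueError(
            f"unknown degrade mode {mode!r}; valid: " + ", ".join(DEGRADE_MODES)
        )
    if mode == "drop_feature" and not feature_key:
        raise ValueError("drop_feature mode requires feature_key")
    records, issues = parse_flatfile(flatfile)
    if any(i.severity == "error" for i in issues):
        raise ValueError("input flat file has parse errors; refusing to degrade")
    for rec in records:
        if mode == "strip_positions":
            names: list[str] = []
            for feat in rec.features:
                if feat.key.lower() == "source":
                    continue
                for qual in ("gene", "product"):
                    v = feat.first_qualifier(qual)
                    if v and v not in names:
                        names.append(v)
                        break
            source = Feature(
                key="source",
                location=parse_location(f"1..{len(rec.sequence)}"),
                qualifiers=[
                    ("organism", rec.organism),
                    ("note", "contains the genes " + "; ".join(names)),
                ],
                location_text=f"1..{len(rec.sequence)}",
            )
            rec.features = [source]
        elif mode == "drop_dloop":
            control_names = {"d-loop", "control region"}
            rec.features = [
                f
                for f in rec.features
                if f.key.lower() != "d-loop"
                and not any(
                    v.strip().lower() in control_names for _, v in f.qualifiers
                )
            ]
        else:
            rec.features = [
                f
                for f in rec.features
                if f.key.lower() != feature_key.lower()
            ]
    return write_flatfile(records)
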