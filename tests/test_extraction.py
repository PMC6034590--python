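import random

import pytest
from Bio.Data import CodonTable

from seqbust.extraction import (
    GENETIC_CODES,
    ExtractionConfig,
    extract_intron_exon,
    extract_record,
    extract_records,
    match_feature,
    requested_loci,
    translate,
    translate_cds,
)
from seqbust.genbank_records import (
    Feature,
    GenBankRecord,
    parse_location,
    reverse_complement,
)
from seqbust.search_terms import SearchTerm, SearchTermTable

# NCBI genetic-code amino-acid strings, transcribed from the NCBI
# "Genetic Codes" page; codon order TTT,TTC,TTA,TTG,TCT,... (base1
# slowest, bases cycling T,C,A,G).
NCBI_AA_STRINGS = {
    1: "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    2: "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG",
    5: "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG",
    11: "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
}


def all_codons():
    return [
        b1 + b2 + b3 for b1 in "tcag" for b2 in "tcag" for b3 in "tcag"
    ]


class TestGeneticCodes:
    @pytest.mark.parametrize("table_number", [1, 2, 5, 11])
    def test_full_64_codon_agreement_with_ncbi(self, table_number):
        expected = NCBI_AA_STRINGS[table_number]
        for codon, aa in zip(all_codons(), expected):
            assert GENETIC_CODES[table_number][codon] == aa, (table_number, codon)

    @pytest.mark.parametrize("table_number", sorted(GENETIC_CODES))
    def test_agreement_with_biopython(self, table_number):
        bio = CodonTable.unambiguous_dna_by_id[table_number]
        for codon in all_codons():
            upper = codon.upper()
            ours = GENETIC_CODES[table_number][codon]
            theirs = "*" if upper in bio.stop_codons else bio.forward_table[upper]
            assert ours == theirs, (table_number, codon)


class TestTranslateCds:
    def test_standard_code_terminal_stop_removed(self):
        assert translate_cds("atgaaacgataa", 1) == "MKR"

    def test_vertebrate_mito_aga_stop(self):
        result = translate("atgaga", 2)
        assert result.peptide == "M"
        assert result.terminal_stop_removed

    def test_codon_start_two(self):
        assert translate_cds("catgaaa", 1, codon_start=2) == "MK"

    def test_codon_start_three(self):
        assert translate_cds("ccatgaaa", 1, codon_start=3) == "MK"

    def test_only_one_terminal_stop_removed(self):
        assert translate_cds("atgtaataa", 1) == "M*"

    def test_internal_stop_flagged(self):
        result = translate("atgtaaaaa", 1)
        assert result.peptide == "M*K"
        assert result.internal_stop

    def test_ambiguity_codes_become_x(self):
        assert translate_cds("atgnnnacr", 1) == "MXX"

    def test_undefined_table_errors_with_supported_codes(self):
        with pytest.raises(ValueError, match="supported codes"):
            translate_cds("atg", 7)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            translate_cds("", 1)

    def test_incomplete_trailing_codon_dropped(self):
        assert translate_cds("atgaaacg", 1) == "MK"


def _record(features, sequence="acgt" * 30, accession="R1", organism="Genus sp"):
    return GenBankRecord(
        accession=accession,
        version=accession + ".1",
        organism=organism,
        sequence=sequence,
        declared_length=len(sequence),
        features=features,
    )


def _feat(key, loc, **quals):
    return Feature(
        key=key,
        location=parse_location(loc),
        qualifiers=[(k.rstrip("_"), v) for k, v in quals.items()],
        location_text=loc,
    )


@pytest.fixture
def coi_table(animal_table):
    return animal_table


class TestMatchFeature:
    def test_product_synonym_matches_coi(self, coi_table):
        feat = _feat("CDS", "1..12", product="cytochrome c oxidase subunit I")
        m = match_feature(feat, coi_table)
        assert m is not None and m.locus == "COI"
        assert m.matched_qualifier == "product"

    def test_exact_full_value_excludes_prefixes(self):
        table = SearchTermTable(rows=[SearchTerm("COI", "CDS", "COI")])
        feat = _feat("CDS", "1..12", gene="COIII")
        assert match_feature(feat, table) is None

    def test_match_is_case_insensitive_and_trimmed(self):
        table = SearchTermTable(rows=[SearchTerm("COI", "CDS", "COX1")])
        feat = _feat("CDS", "1..12", gene="  cox1 ")
        assert match_feature(feat, table).locus == "COI"

    def test_dloop_key_only_match(self, coi_table):
        feat = _feat("D-loop", "1..40")
        m = match_feature(feat, coi_table)
        assert m is not None and m.locus == "D-loop"
        assert m.matched_qualifier == "key"

    def test_feature_key_mismatch_no_match(self):
        table = SearchTermTable(rows=[SearchTerm("COI", "CDS", "COI")])
        assert match_feature(_feat("tRNA", "1..12", gene="COI"), table) is None

    def test_first_row_wins_across_loci(self):
        table = SearchTermTable(
            rows=[
                SearchTerm("first", "CDS", "shared"),
                SearchTerm("second", "CDS", "shared"),
            ]
        )
        assert match_feature(_feat("CDS", "1..6", gene="shared"), table).locus == "first"

    def test_qualifier_search_order_respected(self):
        table = SearchTermTable(
            rows=[SearchTerm("A", "CDS", "geneName"), SearchTerm("B", "CDS", "prodName")]
        )
        feat = _feat("CDS", "1..6", gene="geneName", product="prodName")
        # row order is priority; gene qualifier matches row A first
        assert match_feature(feat, table).locus == "A"

    def test_word_boundary_mode(self):
        table = SearchTermTable(rows=[SearchTerm("COI", "CDS", "COI")])
        config = ExtractionConfig(match_mode="word_boundary")
        hit = _feat("CDS", "1..6", product="mitochondrial COI gene")
        miss = _feat("CDS", "1..6", product="COIII gene")
        assert match_feature(hit, table, config) is not None
        assert match_feature(miss, table, config) is None

    def test_source_features_never_match(self, coi_table):
        feat = _feat("source", "1..100", note="COI")
        assert match_feature(feat, coi_table) is None


class TestExtractRecord:
    def test_minus_strand_planted_sequence_recovered(self, coi_table):
        rng = random.Random(0)
        gene = "".join(rng.choice("acgt") for _ in range(30))
        flank = "".join(rng.choice("acgt") for _ in range(10))
        seq = flank + reverse_complement(gene) + flank
        rec = _record(
            [_feat("CDS", "complement(11..40)", gene="COI")], sequence=seq
        )
        extracted, report = extract_record(rec, coi_table)
        (entry,) = extracted
        assert entry.sequence == gene
        assert report.statuses[("R1.1", "COI")] == "found"

    def test_missing_dloop_reports_not_found(self, coi_table):
        rec = _record([_feat("CDS", "1..12", gene="COI")])
        _, report = extract_record(rec, coi_table)
        assert report.statuses[("R1.1", "D-loop")] == "not_found"

    def test_duplicates_flag_extracts_all_copies(self, coi_table):
        rec = _record(
            [
                _feat("tRNA", "1..24", product="tRNA-Met"),
                _feat("tRNA", "31..54", product="tRNA-Met"),
            ]
        )
        extracted, _ = extract_record(
            rec, coi_table, ExtractionConfig(duplicates=True)
        )
        met = [e for e in extracted if e.locus == "tRNA_Met"]
        assert [e.copy_index for e in met] == [1, 2]

    def test_without_duplicates_first_match_only(self, coi_table):
        rec = _record(
            [
                _feat("tRNA", "1..24", product="tRNA-Met"),
                _feat("tRNA", "31..54", product="tRNA-Met"),
            ]
        )
        extracted, _ = extract_record(rec, coi_table)
        met = [e for e in extracted if e.locus == "tRNA_Met"]
        assert len(met) == 1 and met[0].copy_index == 1

    def test_unparseable_location_status(self, coi_table):
        feat = Feature(
            key="CDS",
            location=None,
            qualifiers=[("gene", "COI")],
            location_text="5^16",
        )
        _, report = extract_record(_record([feat]), coi_table)
        assert report.statuses[("R1.1", "COI")] == "unparseable_location"

    def test_out_of_bounds_status_isolated_per_locus(self, coi_table):
        rec = _record(
            [
                _feat("CDS", "900..950", gene="COI"),
                _feat("CDS", "1..12", gene="CYTB"),
            ]
        )
        _, report = extract_record(rec, coi_table)
        assert report.statuses[("R1.1", "COI")] == "out_of_bounds"
        assert report.statuses[("R1.1", "CYTB")] == "found"

    def test_report_complete_over_all_requested_loci(self, coi_table):
        rec = _record([_feat("CDS", "1..12", gene="COI")])
        _, report = extract_record(rec, coi_table)
        assert len(report.statuses) == len(coi_table.loci())
        assert sum(report.counts().values()) == len(coi_table.loci())

    def test_loci_filter_restricts_and_reports_unknown(self, coi_table):
        config = ExtractionConfig(loci_filter={"COI", "NoSuchLocus"})
        rec = _record([_feat("CDS", "1..12", gene="COI")])
        extracted, report = extract_record(rec, coi_table, config)
        assert {e.locus for e in extracted} == {"COI"}
        assert report.statuses[("R1.1", "NoSuchLocus")] == "not_found"
        assert set(report.statuses) == {("R1.1", "COI"), ("R1.1", "NoSuchLocus")}
        assert requested_loci(coi_table, config) == ["COI", "NoSuchLocus"]

    def test_untranslated_output_is_pure_location_resolution(self, coi_table):
        rec = _record([_feat("CDS", "join(1..6,13..18)", gene="COI")])
        extracted, _ = extract_record(rec, coi_table)
        assert extracted[0].sequence == rec.sequence[0:6] + rec.sequence[12:18]

    def test_translation_uses_transl_table_qualifier(self, animal_table):
        # aga is a stop under table 2 but R under the configured default 1
        seq = "atgaaaaga" + "acgt" * 10
        rec = _record(
            [_feat("CDS", "1..9", gene="COI", transl_table="2")], sequence=seq
        )
        config = ExtractionConfig(translate=True, default_translation_table=1)
        extracted, report = extract_record(rec, animal_table, config)
        assert extracted[0].sequence == "MK"
        assert extracted[0].was_translated

    def test_translation_respects_codon_start_qualifier(self, animal_table):
        seq = "catgaaa" + "acgt" * 10
        rec = _record(
            [_feat("CDS", "1..7", gene="COI", codon_start="2")], sequence=seq
        )
        config = ExtractionConfig(translate=True)
        extracted, _ = extract_record(rec, animal_table, config)
        assert extracted[0].sequence == "MK"

    def test_internal_stop_noted(self, animal_table):
        seq = "atgtaaaaatag" + "acgt" * 10
        rec = _record([_feat("CDS", "1..12", gene="COI")], sequence=seq)
        config = ExtractionConfig(translate=True)
        extracted, report = extract_record(rec, animal_table, config)
        assert extracted[0].sequence == "M*K"
        assert any(
            "internal stop" in n for n in report.notes[("R1.1", "COI")]
        )

    def test_trna_not_translated(self, animal_table):
        rec = _record([_feat("tRNA", "1..24", product="tRNA-Met")])
        extracted, _ = extract_record(
            rec, animal_table, ExtractionConfig(translate=True)
        )
        met = [e for e in extracted if e.locus == "tRNA_Met"]
        assert not met[0].was_translated

    def test_gene_feature_is_fallback_only(self, coi_table):
        rec = _record(
            [
                _feat("gene", "1..16", gene="COI"),
                _feat("CDS", "5..16", gene="COI"),
            ]
        )
        extracted, _ = extract_record(
            rec, coi_table, ExtractionConfig(duplicates=True)
        )
        coi = [e for e in extracted if e.locus == "COI"]
        assert len(coi) == 1 and coi[0].feature_key == "CDS"

    def test_gene_feature_used_when_no_cds(self, coi_table):
        rec = _record([_feat("gene", "5..16", gene="COI")])
        extracted, report = extract_record(rec, coi_table)
        coi = [e for e in extracted if e.locus == "COI"]
        assert len(coi) == 1 and coi[0].feature_key == "gene"

    def test_partial_flag_propagates(self, coi_table):
        rec = _record([_feat("CDS", "<5..16", gene="COI")])
        extracted, _ = extract_record(rec, coi_table)
        assert extracted[0].partial

    def test_extract_records_merges_reports(self, coi_table):
        recs = [
            _record([_feat("CDS", "1..12", gene="COI")], accession="A1"),
            _record([_feat("CDS", "1..12", gene="CYTB")], accession="A2"),
        ]
        _, report = extract_records(recs, coi_table)
        n_loci = len(coi_table.loci())
        assert len(report.statuses) == 2 * n_loci


class TestIntronExon:
    @pytest.fixture
    def intron_row(self):
        return SearchTerm("trnL_intron", "intron", "trnL", 1)

    def test_matching_number_extracted(self, intron_row):
        rec = _record([_feat("intron", "5..24", gene="trnL", number="1")])
        entry = extract_intron_exon(rec, intron_row)
        assert entry is not None
        assert entry.sequence == rec.sequence[4:24]

    def test_wrong_number_no_match(self, intron_row):
        rec = _record([_feat("intron", "5..24", gene="trnL", number="3")])
        assert extract_intron_exon(rec, intron_row) is None

    def test_gene_without_intron_annotation_not_found(self, intron_row):
        rec = _record([_feat("gene", "5..24", gene="trnL")])
        assert extract_intron_exon(rec, intron_row) is None

    def test_exon_number_dispatch(self):
        row = SearchTerm("x_exon2", "exon", "geneX", 2)
        rec = _record(
            [
                _feat("exon", "1..10", gene="geneX", number="1"),
                _feat("exon", "21..30", gene="geneX", number="2"),
            ]
        )
        entry = extract_intron_exon(rec, row)
        assert entry.sequence == rec.sequence[20:30]

    def test_non_intron_row_rejected(self):
        with pytest.raises(ValueError):
            extract_intron_exon(_record([]), SearchTerm("x", "CDS", "a"))

    def test_extract_record_dispatches_intron_rows(self):
        table = SearchTermTable(
            rows=[SearchTerm("trnL_intron", "intron", "trnL", 1)]
        )
        rec = _record([_feat("intron", "5..24", gene="trnL", number="1")])
        extracted, report = extract_record(rec, table)
        assert len(extracted) == 1
        assert report.statuses[("R1.1", "trnL_intron")] == "found"
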