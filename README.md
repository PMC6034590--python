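# seqbust

Extract gene subsequences from GenBank flat files by matching annotated
features against tables of gene-name synonyms.

Many GenBank records are whole organelle genomes or concatenated
multi-gene sequences, and the same gene is annotated under wildly
different names (`COI`, `COX1`, `cox1`, `cytochrome c oxidase subunit
I`, ...). `seqbust` reads local GenBank flat files, finds the features
whose names match any synonym in a search-term table, resolves their
locations (strand, `join(...)` splicing, trans-spliced mixed-strand
joins, `<`/`>` partial markers), and writes one FASTA file per locus
plus a species-by-locus accession table. Coding sequences can
optionally be translated under any supported NCBI genetic code.

Four synonym dictionaries ship with the package: `mtDNA-animal`
(13 protein-coding loci, 22 tRNAs, 2 rRNAs, D-loop), `mtDNA-plant`,
`cpDNA` (including `matK` and `rbcL`), and `rDNA` (18S, 5.8S, 28S,
ITS1, ITS2). User tables are CSVs with columns
`Locus,Type,Name,IntronExonNumber` and can be merged with the bundled
sets.

No network access is used anywhere: records are plain local files, and
the test fixtures are generated deterministically by the
`synthetic_fixtures` module, which also emits a ground-truth manifest so
extraction can be verified byte-for-byte.

## CLI

```sh
# extract all animal mitochondrial loci from one or more flat files
seqbust bust --in records.gb --terms mtDNA-animal --out out/ \
    --duplicates --translate --transl-table 2

# restrict to specific loci, accession-only FASTA headers
seqbust bust --in records.gb --terms myterms.csv --out out/ \
    --loci COI,CYTB --header accession

# inspect / merge / validate search-term tables
seqbust terms --list
seqbust terms --show cpDNA > cpdna.csv
seqbust terms --merge mtDNA-animal --merge extra.csv --out merged.csv
seqbust terms --validate myterms.csv

# longest accession per species (from a CSV or from flat files)
seqbust longest --in lengths.csv --out longest.csv

# deterministic synthetic fixtures with a ground-truth manifest
seqbust fixtures --seed 7 --n-records 50 --terms mtDNA-animal --out fx/
seqbust fixtures --degrade drop_dloop --in fx/fixture.gb --out fx/
```

`bust` writes `{locus}.fasta` files, `accession_table.csv`,
`report.json` (per-accession/locus statuses: `found`, `not_found`,
`unparseable_location`, `out_of_bounds`), and `run_manifest.json`.
Exit status is 0 on success (partial per-record failures are recorded
in the report), 1 on usage errors, and 2 on data errors.

## Library

```python
import seqbust as sb

records, issues = sb.parse_flatfile(open("records.gb").read())
table = sb.load_bundled("mtDNA-animal")
extracted, report = sb.extract_records(
    records, table, sb.ExtractionConfig(duplicates=True, translate=True,
                                        default_translation_table=2)
)
sb.write_fasta(extracted, "out/")
```

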