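import random

import pytest

from seqbust import (
    ExtractionConfig,
    FixtureSpec,
    load_bundled,
    generate_fixture,
    parse_flatfile,
)

MINIMAL_RECORD = """\
LOCUS       TEST01              40 bp    DNA     linear   UNK 01-JAN-1980
DEFINITION  toy record
ACCESSION   TEST01
VERSION     TEST01.1
SOURCE      Danio rerio
  ORGANISM  Danio rerio
FEATURES             Location/Qualifiers
     source          1..40
                     /organism="Danio rerio"
     CDS             5..16
                     /gene="COI"
                     /transl_table="2"
ORIGIN
        1 aaaaatggtg aaattccagg acgtacgtac gtacgtacgt
//
"""


@pytest.fixture(scope="session")
def animal_table():
    return load_bundled("mtDNA-animal")


@pytest.fixture(scope="session")
def rdna_table():
    return load_bundled("rDNA")


@pytest.fixture
def minimal_record():
    records, issues = parse_flatfile(MINIMAL_RECORD)
    assert not issues
    return records[0]


@pytest.fixture(scope="session")
def mixed_fixture(animal_table):
    """A small, feature-rich fixture exercising every location form."""
    spec = FixtureSpec(
        loci=animal_table,
        seed=42,
        n_records=6,
        minus_strand_fraction=0.5,
        join_fraction=0.2,
        trans_splice_fraction=0.05,
        partial_fraction=0.15,
        duplicate_fraction=0.15,
        decoy_fraction=0.3,
        transl_table=2,
    )
    flatfile, manifest = generate_fixture(spec)
    records, issues = parse_flatfile(flatfile)
    assert not [i for i in issues if i.severity == "error"]
    return flatfile, manifest, records


@pytest.fixture
def duplicates_config():
    return ExtractionConfig(duplicates=True)


def random_location_string(rng: random.Random, seq_len: int, depth: int = 0) -> str:
    """A random location string within [1, seq_len], for oracle testing."""
    roll = rng.random()
    if depth < 3 and roll < 0.25:
        return f"complement({random_location_string(rng, seq_len, depth + 1)})"
    if depth < 3 and roll < 0.45:
        n = rng.randint(2, 4)
        parts = ",".join(
            random_location_string(rng, seq_len, depth + 1) for _ in range(n)
        )
        return f"join({parts})"
    start = rng.randint(1, seq_len)
    if rng.random() < 0.15:
        return str(start)
    end = rng.randint(start, seq_len)
    lt = "<" if rng.random() < 0.1 else ""
    gt = ">" if rng.random() < 0.1 else ""
    return f"{lt}{start}..{gt}{end}"
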