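import numpy as np
import pandas as pd
import pytest

from recurmut.genome import Genome
from recurmut.synthetic import (
    ReferenceSpec,
    default_archetypes,
    generate_cohort,
    generate_reference,
)


@pytest.fixture
def toy_genome():
    # ctg1 laid out for indel/context cases: A-run (6-10), C-run, G-run of 8, etc.
    return Genome({
        "ctg1": "GGCTAAAAATCCCCCCCTAGGGGGGGGTACGTACGTAGCTTCTTTACGT",
        "ctg2": "ACGTACGTACGTACGTACGT",
    })


@pytest.fixture(scope="session")
def small_reference():
    """A 2 Mb synthetic reference shared across tests (read-only)."""
    spec = ReferenceSpec.default(2_000_000)
    spec.motif_occurrences = {"TTTCCT": 600}
    spec.homopolymer_tracts = {(b, l): 50 for b in "ACGT" for l in (8, 9, 10)}
    genome, element_map = generate_reference(spec, seed=11)
    return genome, element_map


@pytest.fixture(scope="session")
def small_cohort(small_reference):
    """A 48-sample, 4-archetype cohort with its normalized mutation table."""
    genome, element_map = small_reference
    cohort = generate_cohort(
        [(a, 12) for a in default_archetypes()], genome, element_map, seed=23
    )
    return cohort, cohort.normalized(genome)


def make_mutation_table(rows):
    """Build a normalized-format mutation table from terse tuples.

    Each row: (sample_id, chrom, pos, ref, alt, kind, subtype[, is_1bp,
    homopolymer_category, run_length]).
    """
    recs = []
    for r in rows:
        recs.append(dict(
            sample_id=r[0], chrom=r[1], pos=r[2], ref=r[3], alt=r[4],
            kind=r[5], subtype=r[6], was_complemented=False, allele="",
            is_1bp=bool(r[7]) if len(r) > 7 else False,
            homopolymer_category=r[8] if len(r) > 8 else "",
            run_length=r[9] if len(r) > 9 else 0,
        ))
    columns = ["sample_id", "chrom", "pos", "ref", "alt", "kind", "subtype",
               "was_complemented", "allele", "is_1bp", "homopolymer_category",
               "run_length"]
    return pd.DataFrame(recs, columns=columns)
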