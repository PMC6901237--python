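"""Reading and normalizing somatic mutation calls.

A cancer genome's somatic calls arrive as VCF records.  This module turns them
into a normalized table of single events:

* somatic single-base mutations (SSMs) are collapsed onto the pyrimidine of
  the mutated base pair, so a G>T call and a C>A call denote the same subtype
  (six subtypes: C>A, C>G, C>T, T>A, T>C, T>G);
* multi-base substitutions of equal length are split into their constituent
  single-base events;
* somatic insertion/deletion mutations (SIMs) are left-aligned to their
  5'-most equivalent representation so identical indels are comparable across
  samples, and 1 bp SIMs are classified into the strand-collapsed subtypes
  A/T del, C/G del, A/T ins, C/G ins together with the homopolymer context of
  the altered base (none <=1, short 2-4, midsize 5-7, long >=8 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional

import pandas as pd

from .genome import Genome, revcomp

log = logging.getLogger(__name__)

SSM_SUBTYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SIM_SUBTYPES = ("A/T del", "C/G del", "A/T ins", "C/G ins")
HOMOPOLYMER_CATEGORIES = ("none", "short", "midsize", "long")

_PYRIMIDINE_PARTNER = {"A": "T", "G": "C"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic call (one alternate allele) before normalization.

    ``pos`` is the 1-based VCF position; for SIMs, ``ref``/``alt`` use the
    anchored VCF representation (one of them is the single anchor base).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str  # "SSM" or "SIM"


@dataclass(frozen=True)
class NormalizedSSM:
    source: MutationRecord
    subtype: str  # one of SSM_SUBTYPES
    was_complemented: bool


@dataclass(frozen=True)
class NormalizedSIM:
    source: MutationRecord
    sim_class: str  # "deletion" or "insertion"
    allele: str  # inserted/deleted bases, anchor removed
    is_1bp: bool
    subtype_1bp: Optional[str]  # one of SIM_SUBTYPES iff is_1bp


@dataclass(frozen=True)
class HomopolymerContext:
    run_length: int
    category: str


def classify_homopolymer_run(run_length: int) -> str:
    """Map a mononucleotide-run length to its context class.

    Boundaries: none (<=1), short (2-4), midsize (5-7), long (>=8).
    """
    if run_length <= 1:
        return "none"
    if run_length <= 4:
        return "short"
    if run_length <= 7:
        return "midsize"
    return "long"


def _is_pure_indel(ref: str, alt: str) -> bool:
    if len(ref) == 1 and len(alt) > 1:
        return alt[0] == ref
    if len(alt) == 1 and len(ref) > 1:
        return ref[0] == alt
    return False


def split_adjacent_substitutions(
    records: Iterable[MutationRecord],
) -> Iterator[MutationRecord]:
    """Split equal-length multi-base substitutions into single-base SSMs.

    Adjacent substitutions are treated as separate single-base events: a
    record with \\|ref| = |alt| = n > 1 becomes up to n SSMs at consecutive
    positions, emitting only positions where the ref and alt base differ.
    Single-base records pass through unchanged.
    """
    for rec in records:
        if rec.kind != "SSM" or len(rec.ref) == 1:
            yield rec
            continue
        for offset, (rb, ab) in enumerate(zip(rec.ref, rec.alt)):
            if rb != ab:
                yield replace(rec, pos=rec.pos + offset, ref=rb, alt=ab)


def read_vcf(path, sample_id: str) -> list[MutationRecord]:
    """Read one sample's somatic calls from a VCF (plain or bgzipped).

    Multi-allelic records are split per alternate allele.  Single-base and
    equal-length multi-base substitutions become SSM records (the latter are
    split into single-base events); pure anchored insertions/deletions become
    SIM records.  Anything else (complex substitutions, symbolic alleles,
    non-ACGT alleles) is skipped and counted in a logged warning.
    """
    from cyvcf2 import VCF

    raw: list[MutationRecord] = []
    n_skipped = 0
    for variant in VCF(str(path)):
        ref = variant.REF.upper()
        for alt in variant.ALT:
            alt = alt.upper()
            if not (_VALID.issuperset(ref) and _VALID.issuperset(alt)) or ref == alt:
                n_skipped += 1
                continue
            if len(ref) == len(alt):
                kind = "SSM"
            elif _is_pure_indel(ref, alt):
                kind = "SIM"
            else:
                n_skipped += 1
                continue
            raw.append(
                MutationRecord(sample_id, variant.CHROM, variant.POS, ref, alt, kind)
            )
    if n_skipped:
        log.warning("%s: skipped %d records that are neither SSM nor pure indel",
                    sample_id, n_skipped)
    return list(split_adjacent_substitutions(raw))


def classify_ssm(record: MutationRecord) -> NormalizedSSM:
    """Collapse an SSM onto the pyrimidine of the mutated base pair.

    A purine reference (A or G) is reported via the reverse complement, e.g.
    G>T becomes C>A and A>C becomes T>G.
    """
    if record.kind != "SSM" or len(record.ref) != 1 or len(record.alt) != 1:
        raise ValueError(f"not a single-base substitution: {record}")
    ref, alt = record.ref, record.alt
    if ref == alt or ref not in _VALID or alt not in _VALID:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in _PYRIMIDINE_PARTNER:
        return NormalizedSSM(record, f"{_COMP[ref]}>{_COMP[alt]}", True)
    return NormalizedSSM(record, f"{ref}>{alt}", False)


def classify_sim(record: MutationRecord) -> NormalizedSIM:
    """Classify an anchored indel; 1 bp alleles collapse reverse complements."""
    if record.kind != "SIM":
        raise ValueError(f"not a SIM: {record}")
    ref, alt = record.ref, record.alt
    if not _is_pure_indel(ref, alt):
        raise ValueError(f"not an anchored pure indel: {ref}>{alt}")
    if len(ref) > len(alt):
        sim_class, allele = "deletion", ref[1:]
    else:
        sim_class, allele = "insertion", alt[1:]
    if not _VALID.issuperset(allele):
        raise ValueError(f"non-ACGT indel allele {allele!r}")
    is_1bp = len(allele) == 1
    subtype = None
    if is_1bp:
        pair = "A/T" if allele in "AT" else "C/G"
        subtype = f"{pair} {'del' if sim_class == 'deletion' else 'ins'}"
    return NormalizedSIM(record, sim_class, allele, is_1bp, subtype)


def left_align_sim(sim: NormalizedSIM, genome: Genome) -> NormalizedSIM:
    """Shift an indel to its 5'-most equivalent placement (idempotent).

    The anchored representation at anchor position ``a`` with variant allele
    ``S`` can shift one base left whenever the reference base at ``a`` equals
    the last base of ``S`` (the allele rotates).  Applies identically to
    insertions and deletions.
    """
    rec = sim.source
    a, allele = rec.pos, sim.allele
    if sim.sim_class == "deletion":
        observed = genome.fetch(rec.chrom, a, a + len(rec.ref) - 1)
        if observed != rec.ref:
            raise ValueError(
                f"reference mismatch at {rec.chrom}:{a}: VCF says {rec.ref}, "
                f"genome has {observed}"
            )
    elif genome.base(rec.chrom, a) != rec.ref:
        raise ValueError(f"reference mismatch at {rec.chrom}:{a}")
    while a >= 2 and genome.base(rec.chrom, a) == allele[-1]:
        allele = genome.base(rec.chrom, a) + allele[:-1]
        a -= 1
    if a == rec.pos:
        return sim
    anchor = genome.base(rec.chrom, a)
    if sim.sim_class == "deletion":
        new_rec = replace(rec, pos=a, ref=anchor + allele, alt=anchor)
    else:
        new_rec = replace(rec, pos=a, ref=anchor, alt=anchor + allele)
    return NormalizedSIM(new_rec, sim.sim_class, allele, sim.is_1bp, sim.subtype_1bp)


def homopolymer_context(sim: NormalizedSIM, genome: Genome) -> HomopolymerContext:
    """Homopolymer context of a left-aligned 1 bp SIM.

    For a deletion the run counts reference bases identical to the deleted
    base starting at the deleted position and extending 3' (so it includes
    the deleted base itself); for an insertion it counts reference bases
    identical to the inserted base starting immediately 3' of the insertion
    point.  "Same type" means the identical base character.  Left alignment
    guarantees no matching bases 5' of the event.
    """
    if not sim.is_1bp:
        raise ValueError("homopolymer context is defined for 1 bp SIMs only")
    rec = sim.source
    base = sim.allele
    if rec.pos + 1 > genome.length(rec.chrom):
        raise ValueError(f"locus {rec.chrom}:{rec.pos} at contig end")
    start = rec.pos + 1  # first deleted base / first base 3' of insertion point
    seq = genome.sequence(rec.chrom)
    i = start - 1
    n = len(seq)
    while i < n and seq[i] == base:
        i += 1
    run = i - (start - 1)
    return HomopolymerContext(run, classify_homopolymer_run(run))


NORMALIZED_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "kind", "subtype",
    "was_complemented", "allele", "is_1bp", "homopolymer_category", "run_length",
]


def normalize_mutations(
    records: Iterable[MutationRecord], genome: Genome
) -> pd.DataFrame:
    """Normalize a stream of calls into the package's canonical mutation table.

    Columns: sample_id, chrom, pos, ref, alt, kind, subtype (SSM subtype or
    1 bp SIM subtype; empty for multi-bp SIMs), was_complemented, allele,
    is_1bp, homopolymer_category, run_length.  Positions/alleles of SIMs are
    the left-aligned representation.  Records failing validation are dropped
    with a logged count.
    """
    rows = []
    n_rejected = 0
    for rec in split_adjacent_substitutions(records):
        try:
            if rec.kind == "SSM":
                ssm = classify_ssm(rec)
                rows.append((rec.sample_id, rec.chrom, rec.pos, rec.ref, rec.alt,
                             "SSM", ssm.subtype, ssm.was_complemented, "", False,
                             "", 0))
            else:
                sim = left_align_sim(classify_sim(rec), genome)
                if sim.is_1bp:
                    ctx = homopolymer_context(sim, genome)
                    cat, run = ctx.category, ctx.run_length
                else:
                    cat, run = "", 0
                src = sim.source
                rows.append((src.sample_id, src.chrom, src.pos, src.ref, src.alt,
                             "SIM", sim.subtype_1bp or "", False, sim.allele,
                             sim.is_1bp, cat, run))
        except ValueError:
            n_rejected += 1
    if n_rejected:
        log.warning("normalize_mutations: rejected %d invalid records", n_rejected)
    return pd.DataFrame(rows, columns=NORMALIZED_COLUMNS)


def read_cohort(manifest: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Read and normalize every sample of a manifest (sample_id, path[, tumour_type])."""
    frames = [
        normalize_mutations(read_vcf(row.path, row.sample_id), genome)
        for row in manifest.itertuples()
    ]
    return pd.concat(frames, ignore_index=True)
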